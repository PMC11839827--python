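# German unit costs for post-PE healthcare resource utilisation, 2021 Euros.
# Ambulatory visit fees are a configurable per-specialty map (statutory health
# insurance reimburses per specialty); the two-tier default below is calibrated
# so that a cohort with the default visit mix implies a mean fee of
# ~115.33 €/visit overall and ~76.45 €/visit for PE-related visits.
reference_year: 2021
reference_country: DE
items:
  - {item_id: rivaroxaban_day,            value: 3.10,   unit: per_day,            price_year: 2021, country: DE}
  - {item_id: enoxaparin_day,             value: 14.49,  unit: per_day,            price_year: 2021, country: DE}
  - {item_id: tinzaparin_day,             value: 15.10,  unit: per_day,            price_year: 2021, country: DE}
  - {item_id: fondaparinux_day,           value: 18.58,  unit: per_day,            price_year: 2021, country: DE}
  - {item_id: hospital_day,               value: 658.27, unit: per_day,            price_year: 2021, country: DE}
  - {item_id: chest_xray,                 value: 9.10,   unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: ct,                         value: 65.19,  unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: mrt,                        value: 117.14, unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: endoscopy_bronchoscopy,     value: 127.04, unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: lung_scintigraphy,          value: 44.61,  unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: echocardiography,           value: 27.30,  unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: compression_ultrasound,     value: 8.12,   unit: per_examination,    price_year: 2021, country: DE}
  - {item_id: rehab_day,                  value: 135.25, unit: per_day,            price_year: 2021, country: DE}
  - {item_id: help_visit,                 value: 15.00,  unit: per_visit,          price_year: 2021, country: DE}
  - {item_id: breathing_training,         value: 20.00,  unit: per_item,           price_year: 2021, country: DE}
  - {item_id: compression_stockings,      value: 15.00,  unit: per_item,           price_year: 2021, country: DE}
  - {item_id: physiotherapy,              value: 26.70,  unit: per_item,           price_year: 2021, country: DE}
  - {item_id: productivity_day,           value: 343.95, unit: per_day_of_absence, price_year: 2021, country: DE}
  - {item_id: ambulatory_visit_general_practitioner, value: 63.49,  unit: per_visit, price_year: 2021, country: DE}
  - {item_id: ambulatory_visit_specialist,           value: 193.09, unit: per_visit, price_year: 2021, country: DE}
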