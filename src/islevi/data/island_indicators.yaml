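# Default indicator hierarchy for island ecological vulnerability assessment
# (23 indicators, expert-survey within-element weights). Standard values that
# depend on local regulations or case-specific computation ship as
# regional_mean or fixed placeholders; override them for a real assessment.
class_breaks: [0.6, 0.7, 0.9, 1.0]
indicators:
  # --- Exposure / B1 natural pressure ---
  - {id: C1, name: Impact of typical natural disasters, element: B1, polarity: negative, weight: 0.34, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C2, name: Island area change rate, element: B1, polarity: negative, weight: 0.24, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C3, name: Change rate of island shoreline, element: B1, polarity: negative, weight: 0.23, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C4, name: Proportion of steep slope area, element: B1, polarity: negative, weight: 0.20, spatial_mode: heterogeneous, standard_rule: fixed, standard_value: 0.4}  # stepwise by island area; 0.4 applies to islands > 5 km^2
  # --- Exposure / B2 human interference ---
  - {id: C5, name: Population density of residents, element: B2, polarity: negative, weight: 0.14, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C6, name: Tourism population pressure, element: B2, polarity: negative, weight: 0.15, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C7, name: Impact of typical man-made environmental disturbance, element: B2, polarity: negative, weight: 0.17, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C8, name: Island land development impact, element: B2, polarity: negative, weight: 0.20, spatial_mode: heterogeneous, standard_rule: regional_mean}
  - {id: C9, name: Shoreline development impact, element: B2, polarity: negative, weight: 0.18, spatial_mode: heterogeneous, standard_rule: regional_mean}
  - {id: C10, name: Impact of surrounding sea area development, element: B2, polarity: negative, weight: 0.15, spatial_mode: heterogeneous, standard_rule: regional_mean}
  # --- Sensitivity / B3 ecological status ---
  - {id: C11, name: Net primary productivity of vegetation, element: B3, polarity: negative, weight: 0.56, spatial_mode: heterogeneous, standard_rule: regional_mean}
  - {id: C12, name: Primary productivity of surrounding sea area, element: B3, polarity: negative, weight: 0.44, spatial_mode: heterogeneous, standard_rule: regional_mean}
  # --- Sensitivity / B4 environmental conditions ---
  - {id: C13, name: Groundwater environmental quality, element: B4, polarity: negative, weight: 0.25, spatial_mode: heterogeneous, standard_rule: fixed, standard_value: 1.0}  # placeholder: national environmental quality standard
  - {id: C14, name: Soil environmental quality, element: B4, polarity: negative, weight: 0.29, spatial_mode: heterogeneous, standard_rule: fixed, standard_value: 1.0}
  - {id: C15, name: Sea water environmental quality, element: B4, polarity: negative, weight: 0.28, spatial_mode: heterogeneous, standard_rule: fixed, standard_value: 1.0}
  - {id: C16, name: Marine sediments environmental quality, element: B4, polarity: negative, weight: 0.19, spatial_mode: heterogeneous, standard_rule: fixed, standard_value: 1.0}
  # --- Adaptability / B5 self-regulation ability ---
  - {id: C17, name: Island area, element: B5, polarity: positive, weight: 0.54, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C18, name: Island shape complexity, element: B5, polarity: negative, weight: 0.46, spatial_mode: uniform, standard_rule: regional_mean}
  # --- Adaptability / B6 social support conditions ---
  - {id: C19, name: Income level of residents, element: B6, polarity: positive, weight: 0.28, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C20, name: Science and technology support capacity, element: B6, polarity: positive, weight: 0.37, spatial_mode: uniform, standard_rule: regional_mean}
  - {id: C21, name: Education level of residents, element: B6, polarity: positive, weight: 0.35, spatial_mode: uniform, standard_rule: regional_mean}
  # --- Adaptability / B7 environmental protection ---
  - {id: C22, name: Treatment capacity of main pollutants, element: B7, polarity: positive, weight: 1.00, spatial_mode: uniform, standard_rule: fixed, standard_value: 0.9}
  # --- Adaptability / B8 comprehensive management level ---
  - {id: C23, name: Management effectiveness, element: B8, polarity: positive, weight: 1.00, spatial_mode: uniform, standard_rule: regional_mean}
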