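# Lung-RADS v2022 category rules for baseline/follow-up subsolid and solid
# nodules, reconstructed from the published two-dimensional diameter and
# growth criteria. Editable, versioned configuration: rules are evaluated
# top-to-bottom within the nodule-type block; the first match wins.
version: "lungrads-v2022/reconstruction-1"
citation: "ACR Lung-RADS v2022 assessment categories (diameter/growth criteria)"
growth_definition:
  diameter_increase_mm: 1.5
  max_interval_days: 365
rules:
  ggn:
    - {max_total_mm: 30.0, category: "2"}
    - {growing: true, category: "3"}
    - {category: "2"}            # >= 30 mm, stable
  part_solid:
    - {max_solid_mm: 6.0, max_total_mm: 6.0, category: "2"}
    - {max_solid_mm: 6.0, category: "3"}
    - {max_solid_mm: 8.0, category: "4A"}
    - {category: "4B"}
  solid:
    - {max_total_mm: 6.0, category: "2"}
    - {max_total_mm: 8.0, category: "3"}
    - {max_total_mm: 15.0, category: "4A"}
    - {category: "4B"}
tier_map:
  "1": low
  "2": low
  "3": intermediate
  "4A": high
  "4B": high
  "4X": high
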