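# 2017 Fleischner Society recommendations collapsed to three risk tiers,
# reconstructed from the published size/growth criteria for subsolid
# nodules. Editable, versioned configuration; first match wins.
version: "fleischner-2017/reconstruction-1"
citation: "MacMahon et al., Fleischner Society 2017 incidental nodule guidelines"
growth_definition:
  diameter_increase_mm: 1.5
  max_interval_days: 365
rules:
  ggn:
    - {growing: true, min_total_mm: 6.0, tier: high}
    - {max_total_mm: 6.0, tier: low}
    - {tier: intermediate}       # >= 6 mm, stable
  part_solid:
    - {min_solid_mm: 6.0, tier: high}
    - {growing: true, tier: high}
    - {max_total_mm: 6.0, tier: low}
    - {tier: intermediate}
  solid:
    - {max_total_mm: 6.0, tier: low}
    - {growing: true, tier: high}
    - {max_total_mm: 8.0, tier: intermediate}
    - {tier: high}
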