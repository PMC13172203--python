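# Brock-lite logistic coefficient set: a parsimonious subset of the
# Brock/PanCan malignancy model restricted to the six covariates available
# in this pipeline. Values are a reconstruction from the commonly cited
# parsimonious-model coefficients (McWilliams et al., NEJM 2013); they are
# configuration, not a verbatim reprint of the source table.
version: "brock-lite/reconstruction-1"
citation: "McWilliams et al. 2013 (Brock/PanCan model), parsimonious subset"
intercept: -6.7892
age_centre_years: 62.0
coefficients:
  age_per_year: 0.0287
  sex_female: 0.6011
  spiculation: 0.7729
  upper_lobe: 0.6581
  nodule_type_ggn: -0.1276
  nodule_type_part_solid: 0.3770
# size enters through the PanCan transform: beta * ((d_mm/10)^-0.5 - c0)
size_beta: -5.3854
size_offset: 1.58113883
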