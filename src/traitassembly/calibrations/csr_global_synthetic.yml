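# Synthetic global CSR calibration (version 1).
#
# Maps the three establishment leaf traits onto Grime's C-S-R simplex the
# way global leaf-trait calibrations do: a size axis (square-root leaf
# area) carries the competitive (C) component, and a leaf-economics axis
# (conservative LDMC vs acquisitive SLA) separates stress-tolerance (S)
# from ruderality (R). The transform centers/scales and the linear mapping
# coefficients here are SYNTHETIC: they were constructed for this package
# from typical herbaceous/woody leaf-trait distributions, not transcribed
# from any published calibration, and are intended for direction-level
# inference only. Supply your own calibration file for absolute scores.
version: 1
name: csr-global-synthetic
units:
  la: mm^2
  sla: mm^2/g
  ldmc: fraction (dry weight / fresh weight)
transforms:
  # z = (f(trait) - center) / scale
  la: {type: sqrt, center: 28.0, scale: 15.0}
  sla: {type: log, center: 9.6158, scale: 0.45}     # ln(15000 mm^2/g)
  ldmc: {type: logit, center: -0.8473, scale: 0.55} # logit(0.30)
axes:
  # size axis = z_la; economy axis = (z_ldmc - z_sla) / 2 (conservative > 0)
  economy: {ldmc: 0.5, sla: -0.5}
mapping:
  # raw component = intercept + size * z_la + economy * e + abs_economy * |e|
  C: {intercept: 40.0, size: 45.0, economy: 0.0, abs_economy: -10.0}
  S: {intercept: 30.0, size: -15.0, economy: 40.0, abs_economy: 0.0}
  R: {intercept: 30.0, size: -15.0, economy: -40.0, abs_economy: 0.0}
domain:
  z_clip: 3.5  # |z| beyond this is clamped and flagged out-of-domain
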