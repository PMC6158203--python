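# Per-region isotropic elastic constants (E in MPa, nu dimensionless).
#
# Immature (near-joint) cartilage moduli are the AFM means for each genotype:
# 4.15 MPa (wt) and 7.4 MPa (mutant). Hypertrophic moduli were reported only
# through a relation — the wt-mutant difference in mature regions is about four
# times the immature difference — so the values below are ASSUMPTIONS encoding
# that relation: 19.0 - 6.0 = 4 x (7.4 - 4.15). Poisson's ratio was never
# measured; 0.3 is the package default and is surfaced here deliberately.
wt:
  immature: {E: 4.15, nu: 0.3}
  hypertrophic: {E: 6.0, nu: 0.3}
mutant:
  immature: {E: 7.4, nu: 0.3}
  hypertrophic: {E: 19.0, nu: 0.3}
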