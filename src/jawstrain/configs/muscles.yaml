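# Muscle load magnitudes (uN) and the solve step each muscle is active in.
#
# Magnitudes are PLACEHOLDERS: the real forces and attachment coordinates live
# in prior kinematic work and are not recoverable here. Attachment points are
# derived from the generated geometry's own landmarks (see jawmodel). All
# shipped comparisons are invariant to the absolute magnitude.
adductor_mandibulae:
  magnitude: 2.0
  active_step: closure
jaw_opener:
  magnitude: 2.0
  active_step: opening
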