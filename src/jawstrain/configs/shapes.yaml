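# Parametric jaw-shape presets (micrometres, isotropic voxels).
#
# Absolute 7 dpf dimensions are not tabulated anywhere; these values are scaled
# study conditions chosen once for this package (see docs/methods.md). The
# wt/mutant contrasts carry the observed directions: the mutant joint neck and
# head are broader and the joint space is reduced. Widths are even multiples of
# the voxel size so morphometric recovery is exact on the voxel grid.
wt:
  element_length: 48.0
  element_radius: 4.0
  neck_width: 6.0
  head_width: 10.0
  joint_space: 6.0
  ceratohyal_length: 56.0
  voxel_size: 1.0
mutant:
  element_length: 48.0
  element_radius: 4.0
  neck_width: 10.0
  head_width: 14.0
  joint_space: 2.0
  ceratohyal_length: 56.0
  voxel_size: 1.0
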