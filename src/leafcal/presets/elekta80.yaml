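# Elekta Synergy-style 80-leaf MLC (40 pairs x 1.0 cm at isocenter).
# Effective head geometry for the rounded-tip engine: tip_radius and
# source_to_leaf_plane are effective parameters chosen so the tip-induced
# 50%-edge offset varies weakly with position (slope ~R*e/(z_l*SAD), about
# 0.02 cm/cm at e = 18 cm), matching the behavior of commercial beam models
# and making the one-pass table correction converge.  All configurable.
machine:
  source_to_iso_distance: 100.0   # cm (SAD)
  source_to_leaf_plane: 38.0      # cm, source to leaf mid-plane
  tip_radius: 4.0                 # cm, effective rounded leaf end radius
  leaf_thickness: 7.5             # cm along the beam
  mu: 0.9                         # 1/cm effective attenuation
  transmission_floor: 0.017       # relative leakage under a full leaf
  blur_sigma: 0.10                # cm at isocenter (source size + scatter)
  travel_min: -12.5               # cm, displayed-position travel limits
  travel_max: 20.0
  layout:
    groups:
      - {count: 40, width: 1.0}
phantom:
  ssd: 98.0                       # cm
  calc_depth: 2.0                 # cm; ssd + depth = SAD
  grid_spacing: 0.05              # cm (0.5 mm planar dose resolution)
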