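# Varian Millennium-style 120-leaf MLC: 60 pairs per bank, central 40 leaves
# 0.5 cm wide at isocenter, 10 outer 1.0 cm leaves on each side.
# Physics values are plausible defaults for this head geometry.
machine:
  source_to_iso_distance: 100.0
  source_to_leaf_plane: 50.9      # cm, source to leaf mid-plane
  tip_radius: 8.0                 # cm rounded leaf end radius
  leaf_thickness: 6.7             # cm along the beam
  mu: 0.9
  transmission_floor: 0.017
  blur_sigma: 0.10
  travel_min: -20.0
  travel_max: 20.0
  layout:
    groups:
      - {count: 10, width: 1.0}
      - {count: 40, width: 0.5}
      - {count: 10, width: 1.0}
phantom:
  ssd: 98.0
  calc_depth: 2.0
  grid_spacing: 0.05
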