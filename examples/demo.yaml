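# Demo pipeline configuration: a mid-size synthetic population with
# positive size effects on both diversity layers.
simulation:
  seed: 1
  n_areas: 24
  area_size_range: [250, 1600]
  n_songs: 2000
  n_genres: 12
  embed_dim: 32
  breadth_size_slope: 0.08
  taste_concentration_by_size: {base: 1.8, slope: 2.0}
analysis_seed: 0
out_dir: runs/demo
# diversity
n_draw: 1000
bid_reps: 500
# embedding / WID / dispersion
embed_d: 32
wid_n_users: 100
wid_reps: 500
dispersion_pairs: 500
dispersion_reps: 300
# scaling
age_traj_reps: 300
# causal
causal_reps: 100
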