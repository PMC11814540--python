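# Demo pipeline configuration: small grid and reduced ensembles so the full
# run completes in a few minutes on one CPU while exercising every stage.
seed: 0
landscape:
  n_rows: 256
  n_cols: 256
  cell_size: 100.0
  patchiness: 1200.0
  n_presences: 60
  min_spacing: 1000.0
  n_sightings: 400
  border_band: 2000.0
  town_count: 3
  town_radius: 1000.0
  preference:
    focal_class: 5
    focal_radius: 1000.0
    strength: 5.0
pseudoabsence:
  min_sighting_dist: 800.0
  n_candidates: 300
  n_draw: 60
  n_reps: 1
model:
  radii_km: [0.5, 1, 2, 3, 4, 5, 6, 8, 10]
  n_models: 20
  n_trees: 100
screen:
  rings_km: [[1, 2], [6, 8]]
  deletion_counts: [1, 5, 10]
  reps_per_k: 3
  n_models: 10
  n_trees: 60
stats:
  nmds_scale_km: 1.0
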