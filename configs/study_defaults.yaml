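# Study-scale defaults: 5 km accuracy bound, 10 km / 1000-iteration
# thinning, 2.5-degree buffer, 0.8 correlation threshold, 5 pseudoabsence
# sets x 5000 points, 10 replicates, 70/30 split, AUC gate 0.8, algorithm
# pre-selection by mean ROC over 5 runs. Point occurrences_csv /
# predictors_dir / scenario_dirs at real rasters to run on observed data.
species: Virtualis montana
seed: 1
input_mode: synthetic
n_rows: 100
n_cols: 100
n_presences: 300
n_gcms: 3
max_uncertainty_km: 5
thin_min_dist_km: 10
thin_iterations: 1000
buffer_deg: 2.5
cor_threshold: 0.8
keep_list: []
gcm_variables: [bio_10, bio_12]
gcm_k: 3
n_pseudoabsence: 5000
n_pa_sets: 5
replicates: 10
split: 0.7
algorithms: [GBM, RF, GLM, ANN]
preselect_runs: 5
model_params: {}
auc_gate: 0.8
n_perm: 1
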