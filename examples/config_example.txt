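# Example pipeline configuration (flat key = value format).
# Run with:  dynoc run --config examples/config_example.txt
# Unknown keys are ignored; omitted keys take the defaults shown in
# dynoc.pipeline.PipelineConfig.

# directory of per-subject T x N delimited time-series files (.tsv/.csv/.txt)
input_dir = data/cohort_nc
output_dir = results/cohort_nc
cohort = NC

# number of communities; set to "none" to select k (and beta) by 2-fold
# cross-validation over the grids below
k = 8
k_grid = 2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20
beta = 0.1
beta_grid = 0.1

# optimization
n_init = 20
tol = 1e-6
max_sweeps = 500

# stability analysis (expensive: n_stability_runs single-restart fits per k)
run_stability = false
n_stability_runs = 100

# initial frames dropped from every scan (signal equilibration)
discard_initial = 10

seed = 1
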