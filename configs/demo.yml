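# Demo run: simulate a 40x40 synthetic landscape and push it through every
# stage. Sized to finish in well under a minute; the gate is set for the
# synthetic landscape's attainable skill (pseudo-absence prevalence 1:2 caps
# TSS below the levels reachable on strongly clustered real data).
out_dir: run_demo
seed: 20250922
simulate: {}          # defaults: 40x40 grid, 6 covariates, 150 presences
r_threshold: 0.8
vif_threshold: 10
n_pseudoabsences: 300
k_folds: 5
repetitions: 2
holdout: 0.2
gate_auc: 0.85
gate_tss: 0.6
weight_metric: TSS
k_min: 3
k_max: 7
alpha: 0.05
min_stratum: 10
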