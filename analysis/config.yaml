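# Study conditions for the synthetic analysis (see docs/methods.md):
# 12 subjects, 2 scene + 1 scrambled encoding runs, observation noise at
# the pooled signal level (SNR ~ 1), behavior coupled to the PPA/HPC
# self-modulations at r = 0.6 (memory) and 0.5 (gaze).
outdir: results/study
seed: 1
n_subjects: 12
n_scene_runs: 2
n_scrambled_runs: 1
noise_sd: 0.15
between_sd: 0.25
behavior_corr: 0.6
gaze_corr: 0.5
n_perm: 1999
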