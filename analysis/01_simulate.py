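#!/usr/bin/env python
"""Generate the synthetic study: task schedule, subject connectivity with
planted group structure, noisy BOLD for both encoding conditions, fixation
reports with plantable encoding-retrieval overlap, and recognition
responses coupled to the PPA/HPC self-modulations.

Writes everything under <outdir>/data/ in the pipeline's plain-text
formats (events.tsv, *_bold.tsv + JSON sidecars, fixations.csv,
responses.csv, planted_truth.json)."""

import argparse

from _common import load_config
from gazedcm.pipeline import stage_simulate

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=None)
args = ap.parse_args()

cfg = load_config(args.seed)
info = stage_simulate(cfg)
print(f"simulated {info['n_subjects']} subjects into {info['data_dir']}")
print("conditions: scene (free/fixed viewing) and scrambled control; "
      "ground truth stored alongside for downstream comparison")
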