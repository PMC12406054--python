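#!/usr/bin/env python
"""Invert the generative model for every subject and condition by
variational Laplace, writing labelled posterior JSONs under
<outdir>/posteriors/.

Each fit reports its free energy F (the model-evidence bound used for all
later model comparison) and convergence diagnostics."""

import argparse
import logging

from _common import load_config
from gazedcm.pipeline import stage_invert

logging.basicConfig(level=logging.INFO, format="%(message)s")

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=None)
args = ap.parse_args()

cfg = load_config(args.seed)
info = stage_invert(cfg)
print(f"completed {info['n_inversions']} inversions "
      f"({cfg.n_subjects} subjects x 2 conditions)")
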