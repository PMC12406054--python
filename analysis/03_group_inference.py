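#!/usr/bin/env python
"""Group-level inference per condition: PEB over subject posteriors,
automatic (BMR) search over the endogenous and driving parameters, the
128-model / 7-family comparison for the free-viewing modulations, BMA
within the winning family, and empirical updates of subject parameters.

Writes bma_<condition>.csv, families_<condition>.csv and
subject_modulatory_<condition>.csv under <outdir>/results/."""

import argparse

import pandas as pd

from _common import load_config
from gazedcm.pipeline import stage_peb

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=None)
args = ap.parse_args()

cfg = load_config(args.seed)
out = stage_peb(cfg)
for cond, res in out.items():
    print(f"[{cond}] winning modulatory family: {res['winning_family']} "
          f"(Pp = {res['family_Pp'][res['winning_family']]:.3f})")
    bma = pd.read_csv(cfg.out / "results" / f"bma_{cond}.csv")
    strong = bma[bma["strong_evidence"]]
    print(f"  parameters with Pp >= 95%: "
          f"{', '.join(strong['parameter'])}")
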