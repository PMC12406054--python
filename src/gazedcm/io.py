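"""Readers and writers for the pipeline's plain-text interchange formats.

Time series travel as TSV (header row = region labels, one row per scan)
with a JSON sidecar carrying the TR and run boundaries; task events as
BIDS-style events.tsv (onset, duration, trial_type); fixations and
recognition responses as CSV; inversion results as labelled JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import BOLDTimeSeries
from .inversion import PosteriorEstimate, PriorSpec

EVENT_COLUMNS = ("onset", "duration", "trial_type")
FIXATION_COLUMNS = ("subject", "image", "phase", "condition",
                    "x", "y", "duration")
RESPONSE_COLUMNS = ("subject", "image", "truth", "response", "confidence")


def write_timeseries(path: str | Path, bold: BOLDTimeSeries) -> None:
    path = Path(path)
    df = pd.DataFrame(bold.values, columns=list(bold.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"TR": bold.TR, "run_index": bold.run_index.tolist(),
               "labels": list(bold.labels)}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_timeseries(path: str | Path) -> BOLDTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return BOLDTimeSeries(df.to_numpy(float), float(sidecar["TR"]),
                          np.asarray(sidecar["run_index"], int),
                          tuple(df.columns))


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    extra = [c for c in events.columns if c not in cols]
    events[cols + extra].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns "
                         f"{sorted(missing)}")
    return df


def write_posterior(path: str | Path, post: PosteriorEstimate) -> None:
    d = post.to_dict()
    if post.prior is not None:
        d["prior"] = {"mean": post.prior.mean.tolist(),
                      "cov_diag": np.diag(post.prior.cov).tolist(),
                      "hyper_mean": post.prior.hyper_mean,
                      "hyper_var": post.prior.hyper_var}
    Path(path).write_text(json.dumps(d))


def read_posterior(path: str | Path) -> PosteriorEstimate:
    d = json.loads(Path(path).read_text())
    prior = None
    if "prior" in d:
        prior = PriorSpec(np.asarray(d["prior"]["mean"]),
                          np.diag(d["prior"]["cov_diag"]),
                          d["prior"]["hyper_mean"], d["prior"]["hyper_var"])
    return PosteriorEstimate(
        np.asarray(d["Ep"]), np.asarray(d["Cp"]), float(d["F"]),
        np.asarray(d["lambda"]), int(d["n_iter"]), bool(d["converged"]),
        tuple(d["names"]), prior)


def _checked_read_csv(path, required, name):
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{name} file {path} missing columns "
                         f"{sorted(missing)}")
    return df


def read_fixations(path: str | Path) -> pd.DataFrame:
    return _checked_read_csv(path, FIXATION_COLUMNS, "fixations")


def read_responses(path: str | Path) -> pd.DataFrame:
    return _checked_read_csv(path, RESPONSE_COLUMNS, "responses")
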