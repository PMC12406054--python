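"""Memory-strength scoring and gaze-reinstatement similarity.

Recognition responses for previously viewed images are scored on a 4-level
confidence-graded scale (2 = high-confidence hit ... -1 = high-confidence
miss).  Gaze reinstatement is the Fisher-z Pearson similarity between a
participant's duration-weighted fixation density maps at encoding and
retrieval of the same image, corrected by the mean similarity to a random
sample of the participant's other encoding maps from the same condition
(which absorbs idiosyncratic viewing biases such as a centre or
left-to-right tendency).  Both measures are aggregated to per-subject
free-minus-fixed differences and mean-centered across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "DensityMap", "memory_strength_score", "density_map",
    "similarity_fisher_z", "control_similarity", "reinstatement_score",
    "behavior_differences", "reinstatement_table", "CORR_CLIP",
]

CORR_CLIP = 0.999           # keeps Fisher z finite for identical maps
DEFAULT_SIGMA = 63.0        # px; ~1 degree of visual angle at 500 px ~ 7.95 deg

MEMORY_POINTS = {           # (response, confidence) for truth == "old"
    ("old", "high"): 2,
    ("old", "low"): 1,
    ("new", "low"): 0,
    ("new", "high"): -1,
}


@dataclass
class DensityMap:
    """Duration-weighted fixation density map for one image x phase."""

    grid: np.ndarray
    sigma: float
    image: str = ""
    phase: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid < 0):
            raise ValueError("density map must be finite and non-negative")


def memory_strength_score(truth: str, response: str, confidence: str) -> int:
    """Confidence-graded recognition score for a previously viewed image.

    2 = correctly recognized with high confidence, 1 = with low confidence,
    0 = endorsed new with low confidence, -1 = endorsed new with high
    confidence.  Lures (truth == "new") are not scoreable.
    """
    if truth != "old":
        raise ValueError("memory strength is scored only for previously "
                         "viewed (old) images")
    key = (response, confidence)
    if key not in MEMORY_POINTS:
        raise ValueError(f"unknown response/confidence pair {key!r}")
    return MEMORY_POINTS[key]


def density_map(fixations: pd.DataFrame, width: int, height: int,
                sigma: float = DEFAULT_SIGMA, image: str = "",
                phase: str = "") -> DensityMap:
    """Sum of isotropic Gaussian bumps at fixation locations, each weighted
    by its duration; grid resolution 1 px over the image extent."""
    if len(fixations) == 0:
        raise ValueError("density map needs at least one fixation")
    x = np.asarray(fixations["x"], float)
    y = np.asarray(fixations["y"], float)
    dur = np.asarray(fixations["duration"], float)
    if np.any(dur <= 0):
        raise ValueError("fixation durations must be positive")
    if np.any((x < 0) | (x >= width) | (y < 0) | (y >= height)):
        raise ValueError("fixation outside the image extent")
    grid = np.zeros((height, width))
    np.add.at(grid, (np.round(y).astype(int).clip(0, height - 1),
                     np.round(x).astype(int).clip(0, width - 1)), dur)
    # mirrored boundaries keep the expected map flat for spatially uniform
    # scanpaths, so similarity between unrelated maps is centered on zero
    grid = gaussian_filter(grid, sigma=sigma, mode="mirror")
    return DensityMap(grid, sigma, image, phase)


def similarity_fisher_z(map_a: DensityMap | np.ndarray,
                        map_b: DensityMap | np.ndarray) -> float:
    """Fisher z-transformed Pearson correlation of two flattened maps.

    The correlation is clipped to +/-0.999 so identical maps map to a
    finite z (atanh(0.999) ~ 3.80).
    """
    a = (map_a.grid if isinstance(map_a, DensityMap) else np.asarray(map_a))
    b = (map_b.grid if isinstance(map_b, DensityMap) else np.asarray(map_b))
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate scanpath: density map has zero variance")
    r = float(np.corrcoef(a, b)[0, 1])
    r = float(np.clip(r, -CORR_CLIP, CORR_CLIP))
    return float(np.arctanh(r))


def control_similarity(retrieval_map: DensityMap,
                       encoding_maps: dict[str, DensityMap],
                       exclude_image: str | None = None, k: int = 50,
                       seed: int | np.random.Generator | None = None
                       ) -> float:
    """Mean similarity of a retrieval map to ``k`` randomly drawn encoding
    maps of the same participant and condition (matching image excluded).

    If the pool is smaller than ``k`` the whole pool is used, with a
    warning.  Draws are without replacement and seeded.
    """
    pool = [img for img in encoding_maps if img != exclude_image]
    if len(pool) == 0:
        raise ValueError("empty control pool")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if len(pool) < k:
        warnings.warn(
            f"control pool ({len(pool)}) smaller than k={k}; using whole "
            "pool", stacklevel=2)
        chosen = pool
    else:
        chosen = list(rng.choice(np.asarray(pool, object), size=k,
                                 replace=False))
    zs = [similarity_fisher_z(retrieval_map, encoding_maps[img])
          for img in chosen]
    return float(np.mean(zs))


def reinstatement_score(matched_z: float, control_z: float) -> float:
    """Gaze reinstatement: matched minus control similarity."""
    if not (np.isfinite(matched_z) and np.isfinite(control_z)):
        raise ValueError("similarities must be finite")
    return float(matched_z - control_z)


def reinstatement_table(fixations: pd.DataFrame, width: int, height: int,
                        sigma: float = DEFAULT_SIGMA, k: int = 50,
                        seed: int | None = 0) -> pd.DataFrame:
    """Per subject x condition x image reinstatement scores from a fixation
    report (columns: subject, image, phase, condition, x, y, duration).

    Encoding and retrieval maps are built per image; each retrieval map is
    scored against its matching encoding map minus the seeded control score.
    Images lacking either phase are skipped.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for (subj, cond), grp in fixations.groupby(["subject", "condition"],
                                               sort=True):
        enc_maps = {}
        for img, g in grp[grp["phase"] == "encoding"].groupby("image"):
            enc_maps[img] = density_map(g, width, height, sigma,
                                        image=img, phase="encoding")
        for img, g in grp[grp["phase"] == "retrieval"].groupby("image"):
            if img not in enc_maps:
                continue
            rmap = density_map(g, width, height, sigma, image=img,
                               phase="retrieval")
            matched = similarity_fisher_z(rmap, enc_maps[img])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                control = control_similarity(rmap, enc_maps, img, k=k,
                                             seed=rng)
            rows.append({"subject": subj, "condition": cond, "image": img,
                         "matched_z": matched, "control_z": control,
                         "reinstatement": reinstatement_score(matched,
                                                              control)})
    return pd.DataFrame(rows)


def behavior_differences(memory_scores: pd.DataFrame,
                         reinstatement: pd.DataFrame) -> pd.DataFrame:
    """Per-subject free-minus-fixed differences, mean-centered across
    subjects.

    ``memory_scores`` needs columns (subject, condition, score);
    ``reinstatement`` needs (subject, condition, reinstatement).  Subjects
    missing a condition on either measure are dropped with a warning.
    Returns a table indexed by subject with columns d_memory, d_gaze.
    """
    def per_subject_delta(df, col):
        wide = (df.groupby(["subject", "condition"])[col].mean()
                  .unstack("condition"))
        return wide

    mem = per_subject_delta(memory_scores, "score")
    gz = per_subject_delta(reinstatement, "reinstatement")
    out = {}
    for subj in sorted(set(mem.index) | set(gz.index)):
        ok = (subj in mem.index and subj in gz.index
              and not mem.loc[subj].isna().any()
              and not gz.loc[subj].isna().any())
        if not ok:
            warnings.warn(f"subject {subj!r} missing a condition; dropped",
                          stacklevel=2)
            continue
        out[subj] = {"d_memory": mem.loc[subj, "free"] - mem.loc[subj, "fixed"],
                     "d_gaze": gz.loc[subj, "free"] - gz.loc[subj, "fixed"]}
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "subject"
    if len(table):
        table = table - table.mean(axis=0)
    return table
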