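"""Inferential stage: canonical variate analysis linking modulatory
connectivity to behavior, and per-connection scene-vs-scrambled contrasts.

CVA finds linear combinations of the connectivity parameters (X) and the
retrieval-related measures (Y) that maximize their correlation.  Canonical
correlations come from the SVD of the cross-covariance whitened by the
within-set covariances; loadings are the correlations of each original
variable with its set's canonical variate; the shared variance of function
i is 100 r_i^2.  Significance is assessed both by Bartlett's chi-square
approximation on Wilks' Lambda and by a seeded permutation test (the latter
is the authoritative one at small N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["CVAResult", "canonical_variate_analysis", "shared_variance",
           "connection_contrasts"]


@dataclass
class CVAResult:
    """Canonical correlations, weights, loadings and significance."""

    correlations: np.ndarray          # descending canonical correlations
    x_weights: np.ndarray             # (p, m) canonical weight vectors
    y_weights: np.ndarray             # (q, m)
    x_loadings: np.ndarray            # (p, m) corr(X_j, X variate)
    y_loadings: np.ndarray            # (q, m)
    shared_variance_pct: np.ndarray   # 100 r^2 per function
    chi2: np.ndarray                  # Bartlett statistic per function
    chi2_df: np.ndarray
    chi2_p: np.ndarray
    perm_p: np.ndarray                # permutation p per function
    n_perm: int
    x_names: tuple[str, ...] = ()
    y_names: tuple[str, ...] = ()
    x_scores: np.ndarray = field(default=None, repr=False)
    y_scores: np.ndarray = field(default=None, repr=False)


def _whitener(S: np.ndarray, label: str) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    if w.min() < 1e-10 * max(w.max(), 1.0):
        raise np.linalg.LinAlgError(
            f"singular within-set covariance for {label}; remove collinear "
            "columns or regularize before CVA")
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def _canonical_correlations(Xc: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """Canonical correlations of two column-centered matrices (fast path
    used inside the permutation loop)."""
    n = Xc.shape[0]
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    K = _whitener(Sxx, "X") @ Sxy @ _whitener(Syy, "Y")
    return np.clip(np.linalg.svd(K, compute_uv=False), 0.0, 1.0)


def canonical_variate_analysis(X: np.ndarray, Y: np.ndarray,
                               x_names: tuple[str, ...] = (),
                               y_names: tuple[str, ...] = (),
                               n_perm: int = 1999,
                               seed: int | None = 0) -> CVAResult:
    """Canonical variate analysis of connectivity (X) against behavior (Y).

    X columns are z-standardized (so weights are comparable across
    parameters on different scales; loadings are unaffected), Y columns are
    centered.  Requires more observations than total variables.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= p + q:
        raise ValueError(f"need more observations ({n}) than variables "
                         f"({p}+{q}) for CVA")
    Xc = X - X.mean(0)
    sd = Xc.std(0, ddof=1)
    if np.any(sd == 0):
        raise np.linalg.LinAlgError("constant X column; remove it before CVA")
    Xc = Xc / sd
    Yc = Y - Y.mean(0)

    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Wx = _whitener(Sxx, "X")
    Wy = _whitener(Syy, "Y")
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    m = min(p, q)
    r = np.clip(s[:m], 0.0, 1.0)
    a = Wx @ U[:, :m]           # X weights
    b = Wy @ Vt.T[:, :m]        # Y weights
    xs = Xc @ a
    ys = Yc @ b

    def loadings(Z, scores):
        out = np.empty((Z.shape[1], scores.shape[1]))
        for j in range(Z.shape[1]):
            for i in range(scores.shape[1]):
                out[j, i] = np.corrcoef(Z[:, j], scores[:, i])[0, 1]
        return out

    x_load = loadings(Xc, xs)
    y_load = loadings(Yc, ys)

    # Bartlett's chi-square on Wilks' Lambda, sequentially per function
    chi2 = np.empty(m); dfs = np.empty(m, int); pvals = np.empty(m)
    for i in range(m):
        lam = np.prod(1.0 - r[i:] ** 2)
        chi2[i] = -(n - 1 - (p + q + 1) / 2.0) * np.log(max(lam, 1e-300))
        dfs[i] = (p - i) * (q - i)
        pvals[i] = sps.chi2.sf(chi2[i], dfs[i])

    # seeded permutation test on the canonical correlations
    rng = np.random.default_rng(seed)
    exceed = np.zeros(m)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _canonical_correlations(Xc, Yc[perm])
        exceed += rp[:m] >= r - 1e-12
    perm_p = (exceed + 1.0) / (n_perm + 1.0)

    return CVAResult(r, a, b, x_load, y_load, 100.0 * r ** 2,
                     chi2, dfs, pvals, perm_p, n_perm,
                     tuple(x_names), tuple(y_names), xs, ys)


def shared_variance(r: float) -> float:
    """Percent shared variance explained by a canonical function: 100 r^2,
    reported to one decimal (r = 0.62 -> 38.4)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("canonical correlation must lie in [0, 1]")
    return round(100.0 * r * r, 1)


def connection_contrasts(Ep_scene: np.ndarray, Ep_scrambled: np.ndarray,
                         connection_names: tuple[str, ...] | None = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Scene-minus-scrambled contrasts of modulatory strength per connection.

    Paired t tests per connection with Benjamini–Hochberg FDR adjustment,
    plus the omnibus image-type x connection repeated-measures ANOVA with
    Greenhouse–Geisser correction.  Returns (contrast table, omnibus dict).
    """
    A = np.atleast_2d(np.asarray(Ep_scene, float))
    B = np.atleast_2d(np.asarray(Ep_scrambled, float))
    if A.shape != B.shape:
        raise ValueError("paired subject matrices must have equal shape")
    N, p = A.shape
    if N < 3:
        raise ValueError("need at least 3 paired subjects")
    if connection_names is None:
        connection_names = tuple(f"conn{i}" for i in range(p))

    rows = []
    for j in range(p):
        d = A[:, j] - B[:, j]
        if np.allclose(d, 0):
            t, praw = 0.0, 1.0
        else:
            t, praw = sps.ttest_rel(A[:, j], B[:, j])
        rows.append({"connection": connection_names[j],
                     "estimate": float(d.mean()),
                     "t": float(t), "p_raw": float(praw)})
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p_raw"], method="fdr_bh")[1]

    # omnibus 2 x p repeated-measures ANOVA (GG-corrected), via pingouin
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(N), 2 * p),
        "image_type": np.tile(np.repeat(["scene", "scrambled"], p), N),
        "connection": np.tile(list(connection_names), 2 * N),
        "ep": np.concatenate([np.concatenate([A[s], B[s]])
                              for s in range(N)]),
    })
    import pingouin as pg  # deferred: heavy import
    aov = pg.rm_anova(data=long, dv="ep",
                      within=["image_type", "connection"],
                      subject="subject", correction=True, detailed=True)
    inter = aov[aov["Source"].str.contains("\\*")].iloc[0]
    main = aov[aov["Source"] == "image_type"].iloc[0]

    def gg_row(row):
        eps = row.get("eps", 1.0)
        eps = 1.0 if pd.isna(eps) else float(eps)
        pval = row.get("p_GG_corr", np.nan)
        if pd.isna(pval):
            pval = row["p_unc"]
        return {"F": float(row["F"]), "df1": float(row["ddof1"]) * eps,
                "df2": float(row["ddof2"]) * eps, "eps_gg": eps,
                "p": float(pval)}

    omnibus = {"image_type": gg_row(main), "interaction": gg_row(inter)}
    return table, omnibus
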