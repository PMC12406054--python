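"""Group-level hierarchy: Parametric Empirical Bayes, Bayesian Model
Reduction, the 128-model / 7-family modulatory space, and Bayesian Model
Averaging.

PEB models subject parameters as ``theta_s ~ N(X_s beta, Sigma_b)`` where
``X`` is a between-subject design (column 1 = group mean) and
``Sigma_b = exp(gamma) V0`` a between-subject covariance with a free
log-scale ``gamma``; each subject contributes the likelihood implicit in
its posterior (mean and covariance with the known subject-level prior
removed).  Model comparison over priors
(pruning parameters, switching modulatory connections off) is done in closed
form with BMR, without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inversion import PosteriorEstimate

__all__ = [
    "PEBModel", "ModelSpace", "FamilyPartition", "BMAResult",
    "fit_peb", "bmr_reduce", "gaussian_evidence_shift", "automatic_prune",
    "enumerate_model_space", "assign_families", "model_space_table",
    "family_posteriors",
    "bma_within_family", "empirical_update_subjects", "family_analysis",
]

# the 7 modulatory entries of the full design, in canonical order
MODULATORY_ENTRIES = (
    "B1:OCP self", "B1:PPA self", "B1:HPC self",
    "B1:PPA<-OCP", "B1:OCP<-PPA", "B1:HPC<-PPA", "B1:PPA<-HPC",
)
BOTTOM_UP = frozenset({"B1:PPA<-OCP", "B1:HPC<-PPA"})
TOP_DOWN = frozenset({"B1:OCP<-PPA", "B1:PPA<-HPC"})
SELF_SET = frozenset({"B1:OCP self", "B1:PPA self", "B1:HPC self"})

FAMILY_NAMES = ("null", "BU", "TD", "BIDIR", "SELF",
                "BU+SELF", "TD+SELF", "BIDIR+SELF")

PRUNE_VAR = 1e-8   # prior variance of a switched-off parameter
V0_BETWEEN = 1.0 / 16.0  # between-subject covariance scale (per parameter)
VAR_GAMMA = 4.0    # log-scale prior: between-subject variance may deviate
                   # from the reference scale by a factor ~e^{+-4}
VAR_BETA = 1.0     # prior variance of group-level effects (matches the
                   # subject-level connectivity priors)


@dataclass
class PEBModel:
    """Fitted group-level model over a subset of DCM parameters."""

    X: np.ndarray               # (N, k) between-subject design
    param_names: tuple[str, ...]
    beta_mean: np.ndarray       # (k, p) group effects
    beta_cov: np.ndarray        # (k*p, k*p), vec ordering beta[k, p] row-major
    gamma: float                # between-subject log-scale
    F: float                    # free energy of the group model
    prior_mean: np.ndarray      # (k*p,)
    prior_cov: np.ndarray       # (k*p, k*p)
    subject_means: np.ndarray = field(default=None, repr=False)   # (N, p)
    subject_covs: np.ndarray = field(default=None, repr=False)    # (N, p, p)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def between_cov(self) -> np.ndarray:
        return np.exp(self.gamma) * V0_BETWEEN * np.eye(self.n_params)


@dataclass(frozen=True)
class ModelSpace:
    """All on/off masks over the modulatory entries, binary-counting order."""

    masks: np.ndarray           # (n_models, n_entries) bool
    entry_names: tuple[str, ...] = MODULATORY_ENTRIES

    def __post_init__(self):
        masks = np.asarray(self.masks, bool)
        object.__setattr__(self, "masks", masks)
        if masks.shape[0] != np.unique(masks, axis=0).shape[0]:
            raise ValueError("duplicate masks in model space")

    @property
    def n_models(self) -> int:
        return self.masks.shape[0]


@dataclass(frozen=True)
class FamilyPartition:
    """Family label per model (each model in exactly one family)."""

    family: tuple[str, ...]

    def sizes(self) -> dict[str, int]:
        out = {name: 0 for name in FAMILY_NAMES}
        for f in self.family:
            out[f] += 1
        return out

    def members(self, name: str) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.family) if f == name],
                        int)


@dataclass
class BMAResult:
    """Bayesian model average over (a family of) reduced models."""

    param_names: tuple[str, ...]
    Ep: np.ndarray              # averaged posterior means
    Pp: np.ndarray              # model-mass probability each parameter is on
    Cp: np.ndarray              # mixture covariance
    family_post: dict[str, float] | None = None
    winning_family: str | None = None


def _vec(beta: np.ndarray) -> np.ndarray:
    return np.asarray(beta).ravel()  # row-major: covariate-major, then param


def fit_peb(subject_posteriors: list[PosteriorEstimate] | list[tuple],
            X: np.ndarray | None = None,
            which_params: str | list[str] | None = "B",
            max_iter: int = 32) -> PEBModel:
    """Fit the hierarchical Gaussian model over subject posteriors.

    ``which_params`` selects a block by kind prefix ("A", "B", "C") or an
    explicit list of parameter names.  Subjects may be PosteriorEstimate
    objects or (names, Ep, Cp) tuples.  The group design ``X`` defaults to a
    single column of ones (the group mean); its rows follow subject order.
    """
    if len(subject_posteriors) < 2:
        raise ValueError("PEB needs at least 2 subjects")
    first = subject_posteriors[0]
    names = tuple(first.names)
    if which_params is None:
        sel_names = list(names)
    elif isinstance(which_params, str):
        prefixes = tuple(which_params.split("+"))
        sel_names = [nm for nm in names if nm.startswith(prefixes)]
    else:
        sel_names = list(which_params)
    sel = np.array([names.index(nm) for nm in sel_names], int)
    p = sel.size
    if p == 0:
        raise ValueError("which_params selected no parameters")

    N = len(subject_posteriors)
    if X is None:
        X = np.ones((N, 1))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != N:
        raise ValueError("X must have one row per subject")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient between-subject design X")
    k = X.shape[1]

    M = np.stack([np.asarray(sp.Ep)[sel] for sp in subject_posteriors])
    S = np.stack([np.asarray(sp.Cp)[np.ix_(sel, sel)]
                  for sp in subject_posteriors])

    # Recover each subject's implicit likelihood (information form) by
    # removing the subject-level prior from the posterior; pooling raw
    # posteriors instead would count the shrinkage prior once per subject
    # and bias group means toward the prior mean.
    Pl = np.empty((N, p, p))      # likelihood precision
    bl = np.empty((N, p))         # likelihood information vector
    for s, sp in enumerate(subject_posteriors):
        C = S[s] + np.eye(p) * 1e-10
        P = np.linalg.inv(C)
        if sp.prior is not None:
            C0 = np.asarray(sp.prior.cov)[np.ix_(sel, sel)]
            P0s = np.linalg.inv(C0 + np.eye(p) * 1e-12)
            mu0s = np.asarray(sp.prior.mean)[sel]
        else:
            P0s = np.zeros((p, p))
            mu0s = np.zeros(p)
        Pli = P - P0s
        w, V = np.linalg.eigh((Pli + Pli.T) / 2)
        keep = w > 0
        Pl[s] = (V[:, keep] * w[keep]) @ V[:, keep].T
        b = P @ M[s] - P0s @ mu0s
        # keep only the information in the retained (PSD) subspace
        bl[s] = V[:, keep] @ (V[:, keep].T @ b)

    prior_mean = np.zeros(k * p)
    prior_cov = np.eye(k * p) * VAR_BETA
    P0 = np.linalg.inv(prior_cov)

    gamma = 0.0
    beta = np.zeros((k, p))

    def _subject_terms(gamma):
        """Marginal (over theta_s) precision and information for beta."""
        Pb = np.linalg.inv(np.exp(gamma) * V0_BETWEEN * np.eye(p))
        Peff = np.empty((N, p, p))
        beff = np.empty((N, p))
        lds = np.empty(N)
        quad = np.empty(N)
        for s in range(N):
            A = Pb + Pl[s]
            Ainv = np.linalg.inv(A)
            Peff[s] = Pb - Pb @ Ainv @ Pb          # inv(Sb + pinv(Pl))
            beff[s] = Pb @ Ainv @ bl[s]
            _, lds[s] = np.linalg.slogdet(
                np.exp(gamma) * V0_BETWEEN * A)    # logdet(I + Sb Pl)
            quad[s] = bl[s] @ Ainv @ bl[s]
        return Peff, beff, lds, quad

    def beta_update(gamma):
        Peff, beff, _, _ = _subject_terms(gamma)
        H = P0.copy()
        b = P0 @ prior_mean
        for s in range(N):
            H += np.kron(np.outer(X[s], X[s]), Peff[s])
            b += np.kron(X[s], beff[s])
        cov = np.linalg.inv(H)
        return (cov @ b).reshape(k, p), cov

    def free_energy(gamma, beta, beta_cov):
        Peff, beff, lds, quad = _subject_terms(gamma)
        F = 0.0
        for s in range(N):
            mus = X[s] @ beta
            F += (-0.5 * lds[s] - 0.5 * mus @ Peff[s] @ mus
                  + mus @ beff[s] + 0.5 * quad[s])
        d = _vec(beta) - prior_mean
        _, ld0 = np.linalg.slogdet(prior_cov)
        _, ldq = np.linalg.slogdet(beta_cov)
        kl_beta = 0.5 * (np.trace(P0 @ beta_cov) + d @ P0 @ d
                         - d.size + ld0 - ldq)
        kl_gamma = 0.5 * gamma * gamma / VAR_GAMMA
        return F - kl_beta - kl_gamma

    F_old = -np.inf
    beta, beta_cov = beta_update(gamma)
    for _ in range(max_iter):
        # scalar line search on the between-subject log-scale
        F_cur = free_energy(gamma, beta, beta_cov)
        best_g, best_F = gamma, F_cur
        for dg in (-0.5, -0.25, -0.1, 0.1, 0.25, 0.5):
            Fg = free_energy(gamma + dg, beta, beta_cov)
            if Fg > best_F:
                best_g, best_F = gamma + dg, Fg
        gamma = best_g
        beta, beta_cov = beta_update(gamma)
        F_new = free_energy(gamma, beta, beta_cov)
        if abs(F_new - F_old) < 1e-3:
            F_old = F_new
            break
        F_old = F_new

    return PEBModel(X, tuple(sel_names), beta, beta_cov, float(gamma),
                    float(F_old), prior_mean, prior_cov, M, S)


def gaussian_evidence_shift(mu0, C0, mu, C, mu0r, C0r):
    """Closed-form change in log evidence when swapping the prior.

    For an (approximately) Gaussian posterior q = N(mu, C) obtained under
    prior p0 = N(mu0, C0), the evidence under a new prior p0r = N(mu0r, C0r)
    satisfies  dF = log int q(t) p0r(t) / p0(t) dt,  a Gaussian integral.
    Returns (mu_r, C_r, dF).
    """
    P = np.linalg.inv(C)
    P0 = np.linalg.inv(C0)
    P0r = np.linalg.inv(C0r)
    Pr = P + P0r - P0
    sign, ld_r = np.linalg.slogdet(Pr)
    if sign <= 0:
        return None, None, -np.inf
    Cr = np.linalg.inv(Pr)
    b = P @ mu + P0r @ mu0r - P0 @ mu0
    mur = Cr @ b
    _, ldC = np.linalg.slogdet(C)
    _, ldC0 = np.linalg.slogdet(C0)
    _, ldC0r = np.linalg.slogdet(C0r)
    dF = 0.5 * (-ld_r - ldC + ldC0 - ldC0r) + 0.5 * (
        b @ mur - mu @ P @ mu - mu0r @ P0r @ mu0r + mu0 @ P0 @ mu0)
    return mur, Cr, float(dF)


def bmr_reduce(full_posterior, full_prior, reduced_prior):
    """Bayesian Model Reduction: posterior and evidence of a reduced model.

    Inputs are (mean, cov) pairs; the reduced prior may only *shrink*
    variances relative to the full prior (pruned entries: mean 0, variance
    ~1e-8).  Returns ((mean_r, cov_r), dF) with dF in nats relative to the
    full model.
    """
    mu, C = full_posterior
    mu0, C0 = full_prior
    mu0r, C0r = reduced_prior
    if np.any(np.diag(C0r) > np.diag(C0) + 1e-12):
        raise ValueError("reduced prior may not have larger variances "
                         "than the full prior")
    mur, Cr, dF = gaussian_evidence_shift(
        np.asarray(mu0, float), np.asarray(C0, float),
        np.asarray(mu, float), np.asarray(C, float),
        np.asarray(mu0r, float), np.asarray(C0r, float))
    return (mur, Cr), dF


def _reduced_prior_for(peb: PEBModel, off: np.ndarray):
    """Prior for a model in which the parameters flagged ``off`` are pruned
    (across every covariate column)."""
    k, p = peb.n_covariates, peb.n_params
    var = np.diag(peb.prior_cov).copy().reshape(k, p)
    var[:, off] = PRUNE_VAR
    mean = peb.prior_mean.copy().reshape(k, p)
    mean[:, off] = 0.0
    return mean.ravel(), np.diag(var.ravel())


def reduce_peb(peb: PEBModel, on_mask: np.ndarray):
    """BMR of the group model with a subset of parameters switched off."""
    off = ~np.asarray(on_mask, bool)
    mu0r, C0r = _reduced_prior_for(peb, off)
    (mur, Cr), dF = bmr_reduce(
        (_vec(peb.beta_mean), peb.beta_cov),
        (peb.prior_mean, peb.prior_cov),
        (mu0r, C0r))
    return mur, Cr, dF


def automatic_prune(peb: PEBModel) -> tuple[PEBModel, BMAResult]:
    """Greedy BMR search: prune single parameters while evidence increases.

    At each step the parameter whose removal most increases the reduced
    evidence is pruned; the search stops when no single pruning improves it.
    The reported parameters are the BMA over all models visited during the
    search, weighted by their (reduced) evidence.
    """
    p = peb.n_params
    on = np.ones(p, bool)
    visited = {}  # tuple(on) -> (mur, Cr, dF)
    mur, Cr, dF = reduce_peb(peb, on)
    visited[tuple(on)] = (mur, Cr, dF)
    improved = True
    while improved and on.any():
        improved = False
        best = None
        for i in np.where(on)[0]:
            cand = on.copy()
            cand[i] = False
            key = tuple(cand)
            if key not in visited:
                visited[key] = reduce_peb(peb, cand)
            d = visited[key][2]
            if best is None or d > best[1]:
                best = (cand, d)
        if best is not None and best[1] > visited[tuple(on)][2]:
            on = best[0]
            improved = True

    keys = list(visited)
    dFs = np.array([visited[k][2] for k in keys])
    w = np.exp(dFs - dFs.max())
    w /= w.sum()
    kcov = peb.n_covariates
    Ep = np.zeros(kcov * p)
    Cp = np.zeros((kcov * p, kcov * p))
    Pp = np.zeros(p)
    for key, wi in zip(keys, w):
        mui, Ci, _ = visited[key]
        Ep += wi * mui
        Cp += wi * (Ci + np.outer(mui, mui))
        Pp += wi * np.asarray(key, float)
    Cp -= np.outer(Ep, Ep)

    mur, Cr, dF = visited[tuple(on)]
    reduced = PEBModel(peb.X, peb.param_names, mur.reshape(kcov, p), Cr,
                       peb.gamma, peb.F + dF, peb.prior_mean,
                       _reduced_prior_for(peb, ~on)[1],
                       peb.subject_means, peb.subject_covs)
    bma = BMAResult(peb.param_names, Ep.reshape(kcov, p)[0],
                    Pp, Cp[:p, :p])
    return reduced, bma


def enumerate_model_space(entry_names: tuple[str, ...] = MODULATORY_ENTRIES
                          ) -> ModelSpace:
    """All 2^m on/off masks, in binary-counting order (model 0 = null,
    last = full); entry j corresponds to bit j."""
    m = len(entry_names)
    masks = np.array([[bool(i >> j & 1) for j in range(m)]
                      for i in range(2 ** m)], bool)
    return ModelSpace(masks, entry_names)


def assign_families(space: ModelSpace) -> FamilyPartition:
    """Classify each mask by which directional sets it engages.

    Bottom-up = {OCP->PPA, PPA->HPC}; top-down = {PPA->OCP, HPC->PPA};
    self = the three self-connections.  A family is the combination of
    non-empty sets; the empty model is the null family.
    """
    names = space.entry_names
    fams = []
    for mask in space.masks:
        on = {names[j] for j in range(len(names)) if mask[j]}
        bu = bool(on & BOTTOM_UP)
        td = bool(on & TOP_DOWN)
        sf = bool(on & SELF_SET)
        if not (bu or td or sf):
            fam = "null"
        elif bu and td:
            fam = "BIDIR+SELF" if sf else "BIDIR"
        elif bu:
            fam = "BU+SELF" if sf else "BU"
        elif td:
            fam = "TD+SELF" if sf else "TD"
        else:
            fam = "SELF"
        fams.append(fam)
    return FamilyPartition(tuple(fams))


def model_space_table(space: ModelSpace | None = None,
                      partition: FamilyPartition | None = None):
    """Tidy table of the model space: one row per model with its on/off
    mask bits and family label (exportable as CSV)."""
    import pandas as pd
    space = space or enumerate_model_space()
    partition = partition or assign_families(space)
    df = pd.DataFrame(space.masks.astype(int), columns=space.entry_names)
    df.insert(0, "model", np.arange(space.n_models))
    df["family"] = partition.family
    return df


def family_posteriors(model_F: np.ndarray, partition: FamilyPartition
                      ) -> dict[str, float]:
    """Family posterior probabilities under equal family prior mass.

    Each family receives prior mass 1/8 (the null model is its own
    singleton family), distributed uniformly over its members, so family
    inference is not biased by family size.
    """
    model_F = np.asarray(model_F, float)
    if not np.all(np.isfinite(model_F)):
        raise ValueError("non-finite model evidence")
    fams = partition.family
    sizes = partition.sizes()
    prior = np.array([1.0 / (len(FAMILY_NAMES) * sizes[f]) for f in fams])
    logpost = model_F - model_F.max() + np.log(prior)
    post = np.exp(logpost)
    post /= post.sum()
    return {name: float(post[partition.members(name)].sum())
            for name in FAMILY_NAMES if sizes[name] > 0}


def bma_within_family(posteriors: list[tuple[np.ndarray, np.ndarray]],
                      evidences: np.ndarray,
                      masks: np.ndarray,
                      param_names: tuple[str, ...] = MODULATORY_ENTRIES
                      ) -> BMAResult:
    """Evidence-weighted average over the members of one (winning) family.

    ``posteriors`` holds (mean, cov) per member (means of pruned entries are
    ~0 by construction); ``masks`` their on/off patterns.  Per-parameter Pp
    is the summed posterior model probability of members with the parameter
    switched on.
    """
    if len(posteriors) == 0:
        raise ValueError("empty family")
    F = np.asarray(evidences, float)
    w = np.exp(F - F.max())
    w /= w.sum()
    p = posteriors[0][0].shape[0]
    Ep = np.zeros(p)
    Cp = np.zeros((p, p))
    Pp = np.zeros(len(param_names))
    for (mu, C), wi, mask in zip(posteriors, w, np.asarray(masks, bool)):
        Ep += wi * mu
        Cp += wi * (C + np.outer(mu, mu))
        Pp[mask] += wi
    Cp -= np.outer(Ep, Ep)
    return BMAResult(param_names, Ep, Pp, Cp)


def family_analysis(peb: PEBModel,
                    space: ModelSpace | None = None) -> BMAResult:
    """Full modulatory-space analysis at the group level.

    BMR of every model in the space against the fitted PEB model, family
    posteriors under equal family priors, then BMA within the winning
    family.  The PEB model must cover exactly the space's entries (in
    order).
    """
    if space is None:
        space = enumerate_model_space(peb.param_names)
    if tuple(space.entry_names) != tuple(peb.param_names):
        raise ValueError("model space entries do not match the PEB "
                         "parameters")
    partition = assign_families(space)
    k, p = peb.n_covariates, peb.n_params
    results = []
    for mask in space.masks:
        mur, Cr, dF = reduce_peb(peb, mask)
        results.append((mur, Cr, dF))
    dFs = np.array([r[2] for r in results])
    fam_post = family_posteriors(dFs, partition)
    winner = max(fam_post, key=fam_post.get)
    members = partition.members(winner)
    # report the group-mean column of each member's posterior
    posts = [(results[i][0].reshape(k, p)[0],
              results[i][1][:p, :p]) for i in members]
    bma = bma_within_family(posts, dFs[members], space.masks[members],
                            peb.param_names)
    bma.family_post = fam_post
    bma.winning_family = winner
    return bma


def empirical_update_subjects(peb: PEBModel,
                              subject_posteriors: list[PosteriorEstimate]
                              ) -> np.ndarray:
    """Re-derive each subject's posterior with the group model as prior.

    The subject's likelihood is recovered by removing the original prior
    from the posterior (Gaussian division); it is then combined with the
    group prediction X_s beta (covariance = between-subject covariance) as
    the new prior.  Updated means shrink toward the group means.  Returns an
    (N, p) array over the PEB parameters, in subject order.
    """
    names = tuple(subject_posteriors[0].names)
    sel = np.array([names.index(nm) for nm in peb.param_names], int)
    Sb = peb.between_cov()
    out = np.empty((len(subject_posteriors), sel.size))
    Pb = np.linalg.inv(Sb)
    for s, sp in enumerate(subject_posteriors):
        mu = np.asarray(sp.Ep)[sel]
        C = np.asarray(sp.Cp)[np.ix_(sel, sel)]
        C = C + np.eye(sel.size) * 1e-10
        P = np.linalg.inv(C)
        P0 = np.linalg.inv(sp.prior.cov[np.ix_(sel, sel)]) \
            if sp.prior is not None else np.zeros_like(P)
        Plike = P - P0
        # guard against non-PSD likelihood precision from the Laplace fit
        w, V = np.linalg.eigh(Plike)
        Plike = (V * np.clip(w, 0.0, None)) @ V.T
        blike = P @ mu - (P0 @ sp.prior.mean[sel] if sp.prior is not None
                          else 0.0)
        m_new = peb.X[s] @ peb.beta_mean
        Pn = Plike + Pb
        out[s] = np.linalg.solve(Pn, blike + Pb @ m_new)
    return out
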