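"""Subject-level Bayesian inversion by variational Laplace.

The observation model is ``y = g(theta) + X0 beta + e`` where ``g`` is the
forward model (`forward.integrate_model`), ``X0`` are per-run confounds
(intercept + linear drift, projected out of both data and prediction), and
``e`` is zero-mean Gaussian noise, independent across scans, with one free
log-precision ``lambda_r`` per region.

The variational (Laplace) free energy

    F = accuracy - complexity
      = E_q[log p(y | theta, lambda)] - KL(q(theta) || p(theta))
                                      - KL(q(lambda) || p(lambda))

is maximized by Gauss–Newton updates on theta (with step-halving so accepted
steps never decrease F) alternating with expectation–maximization updates of
lambda.  F approximates the log model evidence and is the currency of all
downstream model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .forward import (BOLDTimeSeries, DCMParameters, IntegrationError,
                      StimulusDesign, SwitchSpec, build_stimulus_inputs,
                      integrate_model, N_HEMO)

__all__ = [
    "ParameterMap", "PriorSpec", "PosteriorEstimate", "default_priors",
    "variational_laplace", "log_evidence", "parameter_posterior_probability",
]

# default prior variances (this package's documented choices)
VAR_CONN = 1.0           # A, B, C entries (raw scale; SPM-scale shrinkage)
VAR_HEMO = 1.0 / 256.0   # log-scaling of hemodynamic constants
HYPER_MEAN = 0.0         # log noise precision (data normalized to unit sd)
HYPER_VAR = 16.0         # weakly informative: lets precision follow the data

CONVERGE_DF = 0.01       # nats
CONVERGE_RUNS = 4
MAX_ITER = 128
MAX_HALVINGS = 16
FD_STEP = 1e-4


@dataclass(frozen=True)
class ParameterMap:
    """Ordered mapping between the free-parameter vector and DCM matrices.

    Order: enabled A entries (row-major), enabled B entries per modulatory
    channel, enabled C entries, then per-region hemodynamic logs
    (transit, decay, epsilon).
    """

    switch: SwitchSpec
    names: tuple[str, ...]
    kinds: tuple[str, ...]          # "A" | "B" | "C" | "hemo"
    coords: tuple[tuple, ...]       # index into the corresponding array
    region_labels: tuple[str, ...]

    @classmethod
    def from_switch(cls, switch: SwitchSpec,
                    region_labels: tuple[str, ...] | None = None
                    ) -> "ParameterMap":
        n = switch.n
        if region_labels is None:
            region_labels = tuple(f"R{i}" for i in range(n))
        names, kinds, coords = [], [], []
        for r in range(n):
            for c in range(n):
                if switch.A_mask[r, c]:
                    lbl = (f"A:{region_labels[r]} self" if r == c
                           else f"A:{region_labels[r]}<-{region_labels[c]}")
                    names.append(lbl); kinds.append("A"); coords.append((r, c))
        for j in range(switch.B_masks.shape[0]):
            for r in range(n):
                for c in range(n):
                    if switch.B_masks[j, r, c]:
                        lbl = (f"B{j + 1}:{region_labels[r]} self" if r == c
                               else f"B{j + 1}:{region_labels[r]}"
                                    f"<-{region_labels[c]}")
                        names.append(lbl); kinds.append("B")
                        coords.append((j, r, c))
        for r in range(n):
            for k in range(switch.C_mask.shape[1]):
                if switch.C_mask[r, k]:
                    names.append(f"C:{region_labels[r]}<-u{k}")
                    kinds.append("C"); coords.append((r, k))
        for r in range(n):
            for h, hname in enumerate(("transit", "decay", "epsilon")):
                names.append(f"hemo:{region_labels[r]} {hname}")
                kinds.append("hemo"); coords.append((r, h))
        return cls(switch, tuple(names), tuple(kinds), tuple(coords),
                   tuple(region_labels))

    @property
    def size(self) -> int:
        return len(self.names)

    def block(self, kind: str) -> np.ndarray:
        """Indices of all parameters of one kind ("A", "B", "C", "hemo")."""
        return np.array([i for i, k in enumerate(self.kinds) if k == kind],
                        int)

    def unpack(self, theta: np.ndarray, n_channels: int) -> DCMParameters:
        n = self.switch.n
        A = np.zeros((n, n))
        B = np.zeros((self.switch.B_masks.shape[0], n, n))
        C = np.zeros((n, n_channels))
        hemo = np.zeros((n, N_HEMO))
        for val, kind, coord in zip(theta, self.kinds, self.coords):
            if kind == "A":
                A[coord] = val
            elif kind == "B":
                B[coord] = val
            elif kind == "C":
                C[coord] = val
            else:
                hemo[coord] = val
        return DCMParameters(A, B, C, hemo)

    def pack(self, params: DCMParameters) -> np.ndarray:
        theta = np.empty(self.size)
        arrays = {"A": params.A, "B": params.B, "C": params.C,
                  "hemo": params.hemo}
        for i, (kind, coord) in enumerate(zip(self.kinds, self.coords)):
            theta[i] = arrays[kind][coord]
        return theta


@dataclass
class PriorSpec:
    """Gaussian priors over the free parameters plus the noise hyperprior."""

    mean: np.ndarray
    cov: np.ndarray
    hyper_mean: float = HYPER_MEAN
    hyper_var: float = HYPER_VAR

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if self.cov.ndim == 1:
            self.cov = np.diag(self.cov)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("prior covariance must be symmetric")
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-10:
            raise ValueError("prior covariance must be positive semidefinite")

    @property
    def free(self) -> np.ndarray:
        """Boolean mask of parameters with nonzero prior variance."""
        return np.diag(self.cov) > 0


@dataclass
class PosteriorEstimate:
    """Variational posterior for one subject x condition."""

    Ep: np.ndarray
    Cp: np.ndarray
    F: float
    lam: np.ndarray
    n_iter: int
    converged: bool
    names: tuple[str, ...] = ()
    prior: PriorSpec | None = None
    F_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "Ep": self.Ep.tolist(),
            "Cp": self.Cp.tolist(),
            "F": float(self.F),
            "lambda": self.lam.tolist(),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }


def default_priors(switch: SwitchSpec,
                   region_labels: tuple[str, ...] | None = None
                   ) -> tuple[PriorSpec, ParameterMap]:
    """Zero-mean shrinkage priors: variance 1/16 on enabled connectivity
    entries, 1/256 on hemodynamic logs; noise log-precision hyperprior
    N(0, 1/128)."""
    pmap = ParameterMap.from_switch(switch, region_labels)
    var = np.empty(pmap.size)
    for i, kind in enumerate(pmap.kinds):
        var[i] = VAR_HEMO if kind == "hemo" else VAR_CONN
    return PriorSpec(np.zeros(pmap.size), np.diag(var)), pmap


def run_confounds(run_index: np.ndarray) -> np.ndarray:
    """Per-run intercept and linear-drift regressors."""
    run_index = np.asarray(run_index, int)
    T = run_index.shape[0]
    cols = []
    for r in np.unique(run_index):
        sel = run_index == r
        col = np.zeros(T); col[sel] = 1.0
        cols.append(col)
        drift = np.zeros(T)
        t = np.arange(sel.sum(), dtype=float)
        drift[sel] = (t - t.mean()) / max(t.max(), 1.0)
        cols.append(drift)
    return np.column_stack(cols)


def _projector(X0: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual-forming matrix of the confounds and its rank."""
    Q, R = np.linalg.qr(X0)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(abs(np.diag(R)))))
    P = np.eye(X0.shape[0]) - Q[:, :rank] @ Q[:, :rank].T
    return P, rank


class _Objective:
    """Free-energy machinery shared by the Gauss–Newton loop."""

    def __init__(self, y, design, TR, pmap, priors, n_channels,
                 run_index, fd_method="central", fd_step=FD_STEP):
        self.design = design
        self.TR = TR
        self.pmap = pmap
        self.priors = priors
        self.n_channels = n_channels
        self.fd_method = fd_method
        self.fd_step = fd_step
        self.U = build_stimulus_inputs(design)
        X0 = run_confounds(run_index)
        self.R, rank = _projector(X0)
        # effective scan count per region after projecting out confounds
        self.T_eff = y.shape[0] - rank
        yp = self.R @ y
        # normalize to unit pooled sd so the noise-precision hyperprior
        # (centered on precision 1) refers to the data's own scale; the
        # model prediction is scaled identically, leaving parameters
        # unchanged (a pure change of units)
        sd = float(yp.std())
        self.scale = 1.0 / sd if sd > 0 else 1.0
        self.y = self.scale * yp
        self.n_regions = y.shape[1]
        self.free = priors.free
        self.ifree = np.where(self.free)[0]
        self.P0 = np.linalg.inv(priors.cov[np.ix_(self.ifree, self.ifree)])
        self.mu0 = priors.mean[self.ifree]
        self.sign0, self.logdet0 = np.linalg.slogdet(
            priors.cov[np.ix_(self.ifree, self.ifree)])

    def full_theta(self, th_free: np.ndarray) -> np.ndarray:
        th = self.priors.mean.copy()
        th[self.ifree] = th_free
        return th

    def g(self, th_free: np.ndarray) -> np.ndarray | None:
        params = self.pmap.unpack(self.full_theta(th_free), self.n_channels)
        try:
            vals, _ = integrate_model(params, self.design, self.TR, self.U)
        except IntegrationError:
            return None
        if not np.all(np.isfinite(vals)):
            return None
        return self.scale * (self.R @ vals)

    def jacobian(self, th_free: np.ndarray, g0: np.ndarray) -> np.ndarray | None:
        p = th_free.shape[0]
        J = np.empty((self.y.size, p))
        h = self.fd_step
        for i in range(p):
            tp = th_free.copy(); tp[i] += h
            gp = self.g(tp)
            if gp is None:
                return None
            if self.fd_method == "central":
                tm = th_free.copy(); tm[i] -= h
                gm = self.g(tm)
                if gm is None:
                    return None
                J[:, i] = ((gp - gm) / (2 * h)).ravel()
            else:  # forward differences
                J[:, i] = ((gp - g0) / h).ravel()
        return J

    def _lambda_terms(self, lam, E):
        """Posterior variance of each lambda_r and its KL from the prior."""
        hv = self.priors.hyper_var
        curv = 0.5 * np.exp(lam) * E + 1.0 / hv
        clam = 1.0 / curv
        d = lam - self.priors.hyper_mean
        kl = 0.5 * (clam / hv + d * d / hv - 1.0 + np.log(hv / clam))
        return clam, kl

    def free_energy(self, th_free, lam, g0, J):
        """Laplace free energy with fresh curvature at (theta, lambda)."""
        e = self.y - g0
        sse = np.sum(e * e, axis=0)
        prec = np.exp(lam)
        acc = float(np.sum(-0.5 * prec * sse + 0.5 * self.T_eff * lam
                           - 0.5 * self.T_eff * np.log(2 * np.pi)))
        H = self._hessian(J, lam)
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, None
        Cp = np.linalg.inv(H)
        d = th_free - self.mu0
        kl_th = 0.5 * (np.trace(self.P0 @ Cp) + d @ self.P0 @ d
                       - d.shape[0] + self.logdet0 + logdetH)
        # E_q correction for theta uncertainty is absorbed in the Laplace
        # curvature term; lambda treated with its own Laplace marginal.
        clam, kl_lam = self._lambda_terms(lam, sse + self._trJCJ(J, Cp))
        F = acc - kl_th - float(np.sum(kl_lam))
        return F, Cp

    def _hessian(self, J, lam):
        prec = np.exp(lam)
        T = self.y.shape[0]
        H = self.P0.copy()
        # J rows are ordered scan-major: (T, n) raveled row-major
        Jv = J.reshape(T, self.n_regions, -1)
        for r in range(self.n_regions):
            Jr = Jv[:, r, :]
            H = H + prec[r] * (Jr.T @ Jr)
        return H

    def _trJCJ(self, J, Cp):
        T = self.y.shape[0]
        Jv = J.reshape(T, self.n_regions, -1)
        out = np.empty(self.n_regions)
        for r in range(self.n_regions):
            Jr = Jv[:, r, :]
            out[r] = float(np.einsum("ti,ij,tj->", Jr, Cp, Jr))
        return out

    def gradient(self, th_free, lam, g0, J):
        T = self.y.shape[0]
        e = self.y - g0
        prec = np.exp(lam)
        Jv = J.reshape(T, self.n_regions, -1)
        grad = -self.P0 @ (th_free - self.mu0)
        for r in range(self.n_regions):
            grad = grad + prec[r] * (Jv[:, r, :].T @ e[:, r])
        return grad

    def update_lambda(self, lam, g0, J, Cp):
        """EM / Newton ascent on each region's log precision."""
        e = self.y - g0
        sse = np.sum(e * e, axis=0)
        E = sse + self._trJCJ(J, Cp)
        hv = self.priors.hyper_var
        hm = self.priors.hyper_mean
        lam = lam.copy()
        for _ in range(8):
            grad = 0.5 * (self.T_eff - np.exp(lam) * E) - (lam - hm) / hv
            curv = 0.5 * np.exp(lam) * E + 1.0 / hv
            step = grad / curv
            step = np.clip(step, -2.0, 2.0)
            lam = lam + step
            if np.max(np.abs(step)) < 1e-6:
                break
        # physical window for unit-sd data; keeps exactly-zero residuals
        # (degenerate noise-free fits) from diverging
        return np.clip(lam, -8.0, 8.0)


def variational_laplace(bold: BOLDTimeSeries, design: StimulusDesign,
                        switch: SwitchSpec, priors: PriorSpec | None = None,
                        pmap: ParameterMap | None = None,
                        fd_method: str = "central",
                        max_iter: int = MAX_ITER,
                        verbose: bool = False) -> PosteriorEstimate:
    """Invert the generative model on one subject's time series.

    Gauss–Newton on the parameter mode with step-halving (up to 16 halvings;
    accepted steps never decrease F), EM updates of the per-region noise
    log-precisions, convergence when dF < 0.01 nats on 4 consecutive
    iterations (cap 128).  Returns posterior means, covariance (inverse
    curvature at the optimum), and the free energy F.
    """
    if priors is None or pmap is None:
        dpriors, dmap = default_priors(switch, bold.labels)
        priors = priors or dpriors
        pmap = pmap or dmap
    n_free = int(priors.free.sum())
    if bold.n_scans < n_free:
        raise ValueError(
            f"need at least as many scans ({bold.n_scans}) as free "
            f"parameters ({n_free})")

    obj = _Objective(bold.values, design, bold.TR, pmap, priors,
                     n_channels=design.n_channels, run_index=bold.run_index,
                     fd_method=fd_method)

    th = obj.mu0.copy()
    lam = np.full(obj.n_regions, priors.hyper_mean, float)

    g0 = obj.g(th)
    if g0 is None:
        raise FloatingPointError("forward model diverged at the prior mean")
    J = obj.jacobian(th, g0)
    if J is None or not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite gradient at the prior mean")
    F, Cp = obj.free_energy(th, lam, g0, J)

    F_trace = [F]
    n_converged = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step: noise precisions (coordinate ascent, checked against F)
        lam_new = obj.update_lambda(lam, g0, J, Cp)
        F_new, Cp_new = obj.free_energy(th, lam_new, g0, J)
        if F_new >= F:
            lam, F, Cp = lam_new, F_new, Cp_new

        # E-step: Gauss-Newton with step halving
        grad = obj.gradient(th, lam, g0, J)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient during inversion")
        H = obj._hessian(J, lam)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]

        accepted = False
        k = 0
        J_screen = J
        for k in range(MAX_HALVINGS + 1):
            th_c = th + delta / (2.0 ** k)
            g_c = obj.g(th_c)
            if g_c is None:
                continue
            # screen the candidate with the freshest available Jacobian
            # (cheap), then confirm with one computed at the candidate so
            # the recorded F is exact
            F_est, _ = obj.free_energy(th_c, lam, g_c, J_screen)
            if F_est < F:
                continue
            J_c = obj.jacobian(th_c, g_c)
            if J_c is None or not np.all(np.isfinite(J_c)):
                continue
            J_screen = J_c
            F_c, Cp_c = obj.free_energy(th_c, lam, g_c, J_c)
            if F_c >= F:
                th, g0, J, F, Cp = th_c, g_c, J_c, F_c, Cp_c
                accepted = True
                break
        dF = F - F_trace[-1]
        F_trace.append(F)
        if verbose:
            print(f"  VL iter {it:3d}: F = {F:.3f} (dF = {dF:.4f}, "
                  f"halvings = {k if accepted else 'stalled'})")
        if not np.isfinite(F):
            raise FloatingPointError("non-finite free energy")
        n_converged = n_converged + 1 if dF < CONVERGE_DF else 0
        if n_converged >= CONVERGE_RUNS:
            converged = True
            break
        if not accepted and dF < CONVERGE_DF:
            converged = True
            break

    Ep = priors.mean.copy()
    Ep[obj.ifree] = th
    Cp_full = np.zeros((priors.mean.size, priors.mean.size))
    Cp_full[np.ix_(obj.ifree, obj.ifree)] = Cp
    return PosteriorEstimate(Ep, Cp_full, float(F), lam, it, converged,
                             pmap.names, priors, np.asarray(F_trace))


def log_evidence(post: PosteriorEstimate) -> float:
    """Free energy as the variational approximation to log model evidence."""
    return float(post.F)


def parameter_posterior_probability(Ep_i: float, Cp_ii: float) -> float:
    """Posterior probability that a parameter keeps the sign of its mean.

    Under the marginal Gaussian this is Phi(|Ep| / sqrt(Cp)).  A
    zero-variance (fixed) parameter has probability 1 unless its mean is 0.
    """
    if Cp_ii < 0:
        raise ValueError("negative posterior variance")
    if Cp_ii == 0:
        return 1.0 if Ep_i != 0 else 0.5
    return float(norm.cdf(abs(Ep_i) / np.sqrt(Cp_ii)))
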