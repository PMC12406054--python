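"""Generative model: bilinear neuronal dynamics + balloon hemodynamics.

This module hosts the forward model used both to simulate synthetic BOLD and
inside Bayesian inversion.  Three regions are modelled by default — early
visual cortex (OCP), the parahippocampal place area (PPA), and the
hippocampus (HPC) — coupled by a bilinear state equation

    dz/dt = (A + sum_j u_j B_j) z + C u

where ``A`` is average (endogenous) coupling, ``B_j`` the modulation of
coupling by experimental input ``u_j`` (free-viewing trials), and ``C`` the
driving input (all encoding trials).  Self-connections live on a unitless log
scale: the effective diagonal is ``-0.5 * exp(raw)``, so raw 0 is the default
decay of -0.5 Hz, positive raw values mean stronger self-inhibition, and
negative modulatory raw values mean disinhibition.  Between-region entries
are rates in Hz.

Neuronal activity is observed through a per-region balloon–windkessel
cascade producing percent-signal-change BOLD sampled at the scanner TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _integrate
from ._integrate import E0, GAMMA0, KAPPA0, TAU0, V0  # re-exported constants

__all__ = [
    "RegionSet", "InputChannel", "StimulusDesign", "DCMParameters",
    "SwitchSpec", "BOLDTimeSeries", "build_stimulus_inputs",
    "effective_jacobian", "neuronal_derivative", "hemodynamic_bold",
    "simulate_bold", "DEFAULT_REGIONS",
]

N_HEMO = 3  # per-region free hemodynamic parameters: transit, decay, epsilon


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of modelled regions."""

    labels: tuple[str, ...] = ("OCP", "PPA", "HPC")

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("need at least two regions")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_REGIONS = RegionSet()


@dataclass(frozen=True)
class InputChannel:
    name: str
    onsets: np.ndarray      # seconds
    durations: np.ndarray   # seconds
    mean_center: bool = False


@dataclass(frozen=True)
class StimulusDesign:
    """Experimental inputs on a common microtime grid.

    Channel 0 is the driving input (all encoding trials); channels 1+ are
    modulators (free-viewing trials).  ``run_boundaries`` are run start times
    in seconds (first entry 0); neuronal and hemodynamic states reset there.
    """

    channels: tuple[InputChannel, ...]
    dt: float
    total_duration: float
    run_boundaries: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for ch in self.channels:
            if np.any(np.asarray(ch.onsets) + np.asarray(ch.durations)
                      > self.total_duration + 1e-9):
                raise ValueError(
                    f"channel {ch.name!r}: onset+duration beyond total_duration")
            if np.any(np.asarray(ch.onsets) < 0):
                raise ValueError(f"channel {ch.name!r}: negative onset")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.total_duration / self.dt - 1e-9))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_modulators(self) -> int:
        return len(self.channels) - 1


@dataclass
class DCMParameters:
    """Raw connectivity and hemodynamic parameters of one model instance.

    ``A`` and each ``B[j]`` are n x n; diagonals are unitless log-scale
    self-connection parameters, off-diagonals Hz.  ``C`` is n x n_channels in
    Hz per unit input.  ``hemo`` is n x 3 with per-region log-scaling of the
    canonical transit time, signal-decay rate, and BOLD gain epsilon.
    """

    A: np.ndarray
    B: np.ndarray           # (n_modulators, n, n)
    C: np.ndarray           # (n, n_channels)
    hemo: np.ndarray | None = None
    regions: RegionSet = DEFAULT_REGIONS

    def __post_init__(self):
        self.A = np.asarray(self.A, float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        self.B = np.asarray(self.B, float).reshape(-1, n, n)
        self.C = np.atleast_2d(np.asarray(self.C, float))
        if self.C.shape[0] != n:
            raise ValueError("C must have one row per region")
        if self.hemo is None:
            self.hemo = np.zeros((n, N_HEMO))
        self.hemo = np.asarray(self.hemo, float).reshape(n, N_HEMO)
        for name, arr in (("A", self.A), ("B", self.B), ("C", self.C),
                          ("hemo", self.hemo)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def copy(self) -> "DCMParameters":
        return DCMParameters(self.A.copy(), self.B.copy(), self.C.copy(),
                             self.hemo.copy(), self.regions)

    def masked(self, switch: "SwitchSpec") -> "DCMParameters":
        """Return a copy with switched-off entries forced to exactly 0."""
        p = self.copy()
        p.A = np.where(switch.A_mask, p.A, 0.0)
        p.B = np.where(switch.B_masks, p.B, 0.0)
        p.C = np.where(switch.C_mask, p.C, 0.0)
        return p


@dataclass(frozen=True)
class SwitchSpec:
    """Binary masks selecting which A/B/C entries are free (modelled)."""

    A_mask: np.ndarray
    B_masks: np.ndarray
    C_mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "A_mask", np.asarray(self.A_mask, bool))
        n = self.A_mask.shape[0]
        object.__setattr__(
            self, "B_masks", np.asarray(self.B_masks, bool).reshape(-1, n, n))
        object.__setattr__(
            self, "C_mask", np.atleast_2d(np.asarray(self.C_mask, bool)))
        if not np.all(np.diag(self.A_mask)):
            raise ValueError("A diagonal (self-connections) must stay on")

    @property
    def n(self) -> int:
        return self.A_mask.shape[0]

    @classmethod
    def full_design(cls, regions: RegionSet = DEFAULT_REGIONS,
                    n_channels: int = 2) -> "SwitchSpec":
        """The full 3-region design: all self-connections, reciprocal
        OCP<->PPA and PPA<->HPC coupling (same 7 entries modulated), driving
        input into OCP only."""
        n = regions.n
        i_ocp, i_ppa, i_hpc = (regions.index(l) for l in ("OCP", "PPA", "HPC"))
        a = np.eye(n, dtype=bool)
        for r, c in ((i_ppa, i_ocp), (i_ocp, i_ppa),
                     (i_hpc, i_ppa), (i_ppa, i_hpc)):
            a[r, c] = True
        b = a.copy()[None, :, :]
        cmask = np.zeros((n, n_channels), bool)
        cmask[i_ocp, 0] = True
        return cls(a, b, cmask)


@dataclass
class BOLDTimeSeries:
    """Sampled BOLD observations (percent signal change)."""

    values: np.ndarray       # (T, n)
    TR: float
    run_index: np.ndarray    # (T,) 0-based run label per scan
    labels: tuple[str, ...] = DEFAULT_REGIONS.labels

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        self.run_index = np.asarray(self.run_index, int)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite BOLD values")
        if self.run_index.shape[0] != self.values.shape[0]:
            raise ValueError("run_index length mismatch")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]


def build_stimulus_inputs(design: StimulusDesign) -> np.ndarray:
    """Discretize the stimulus channels onto the microtime grid.

    Each channel is a boxcar: 1 during each trial, 0 elsewhere.  Channels
    flagged ``mean_center`` have their temporal mean removed after
    discretization (the convention for the driving input, so that A
    represents average connectivity across conditions).  Overlapping trials
    within a channel are merged (with a warning); the boxcar never exceeds 1.
    """
    n_bins = design.n_bins
    U = np.zeros((n_bins, design.n_channels))
    for j, ch in enumerate(design.channels):
        onsets = np.asarray(ch.onsets, float)
        durations = np.asarray(ch.durations, float)
        order = np.argsort(onsets)
        prev_end = -np.inf
        for o, d in zip(onsets[order], durations[order]):
            if o < prev_end - 1e-9:
                warnings.warn(
                    f"channel {ch.name!r}: overlapping trials merged",
                    stacklevel=2)
            prev_end = max(prev_end, o + d)
            i0 = int(np.round(o / design.dt))
            i1 = int(np.round((o + d) / design.dt))
            U[i0:min(i1, n_bins), j] = 1.0
        if ch.mean_center:
            U[:, j] -= U[:, j].mean()
    return U


def effective_jacobian(params: DCMParameters, u: np.ndarray) -> np.ndarray:
    """Instantaneous coupling matrix (Hz) at input value ``u``.

    Off-diagonal: additive A + sum u_j B_j.  Diagonal: -0.5 exp(raw sum), so
    modulation enters inside the exponent and negative raw modulation is
    disinhibitory.
    """
    u = np.atleast_1d(np.asarray(u, float))
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite input u")
    um = u[1:1 + params.B.shape[0]] if u.size > 1 else np.zeros(params.B.shape[0])
    J = params.A + np.tensordot(um, params.B, axes=1)
    raw_diag = np.diag(params.A) + um @ np.diagonal(params.B, axis1=1, axis2=2)
    np.fill_diagonal(J, -0.5 * np.exp(raw_diag))
    return J


def neuronal_derivative(z: np.ndarray, u: np.ndarray,
                        params: DCMParameters) -> np.ndarray:
    """dz/dt of the bilinear state equation, in 1/s."""
    z = np.asarray(z, float)
    u = np.atleast_1d(np.asarray(u, float))
    if z.shape[0] != params.n:
        raise ValueError("state dimension mismatch")
    if u.shape[0] != params.C.shape[1]:
        raise ValueError("input dimension mismatch")
    return effective_jacobian(params, u) @ z + params.C @ u


def _hemo_constants(hemo: np.ndarray):
    kappa = KAPPA0 * np.exp(hemo[:, 1])
    tau = TAU0 * np.exp(hemo[:, 0])
    eps = np.exp(hemo[:, 2])
    return kappa, tau, eps


def hemodynamic_bold(z_trajectory: np.ndarray, hemo: np.ndarray,
                     dt: float) -> np.ndarray:
    """Pass a microtime neuronal trajectory through the balloon cascade.

    Returns the BOLD trajectory at the same microtime resolution (percent
    signal change).  At z == 0 the cascade stays at its fixed point and the
    output is identically 0.
    """
    z = np.atleast_2d(np.asarray(z_trajectory, float))
    n_steps, n = z.shape
    hemo = np.asarray(hemo, float).reshape(n, N_HEMO)
    kappa, tau, eps = _hemo_constants(hemo)

    # RK4 on (s, log f, log v, log q), driven by the neuronal trajectory;
    # log coordinates keep flow/volume/deoxyhemoglobin positive
    out = np.zeros((n_steps, n))
    s = np.zeros(n); lf = np.zeros(n); lv = np.zeros(n); lq = np.zeros(n)

    def deriv(s, lf, lv, lq, zr):
        f, v, q = (np.exp(np.clip(a, -20, 20)) for a in (lf, lv, lq))
        fv = v ** (1.0 / _integrate.ALPHA0)
        ef = 1.0 - (1.0 - E0) ** (1.0 / f)
        ds = zr - kappa * s - GAMMA0 * (f - 1.0)
        dlf = s / f
        dlv = (f - fv) / (tau * v)
        dlq = (f * ef / E0 - fv * q / v) / (tau * q)
        return np.array([ds, dlf, dlv, dlq])

    for i in range(n_steps):
        v, q = np.exp(lv), np.exp(lq)
        out[i] = 100.0 * V0 * eps * (
            _integrate.K1 * (1 - q) + _integrate.K2 * (1 - q / v)
            + _integrate.K3 * (1 - v))
        zr = z[i]
        x = np.array([s, lf, lv, lq])
        k1 = deriv(*x, zr)
        k2 = deriv(*(x + dt / 2 * k1), zr)
        k3 = deriv(*(x + dt / 2 * k2), zr)
        k4 = deriv(*(x + dt * k3), zr)
        s, lf, lv, lq = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(lq)) or np.any(np.abs(lv) > 20) \
                or np.any(np.abs(lq) > 20):
            raise FloatingPointError(
                f"hemodynamic integration left the physical domain at step "
                f"{i + 1}: dt={dt} too large or inputs too strong")
    return out


class IntegrationError(FloatingPointError):
    pass


def _scan_grid(design: StimulusDesign, TR: float):
    """Microtime indices of run resets and scan samples, plus run labels."""
    dt = design.dt
    n_bins = design.n_bins
    bins_per_scan = TR / dt
    if abs(bins_per_scan - round(bins_per_scan)) > 1e-9:
        raise ValueError("TR must be an integer multiple of the microtime dt")
    bins_per_scan = int(round(bins_per_scan))
    bounds = np.asarray(design.run_boundaries, float)
    reset = np.round(bounds / dt).astype(np.int64)
    ends = np.append(bounds, design.total_duration)
    sample, run_idx = [], []
    for r in range(len(bounds)):
        start = reset[r]
        stop = int(np.round(ends[r + 1] / dt))
        idx = np.arange(start, stop, bins_per_scan, dtype=np.int64)
        sample.append(idx)
        run_idx.append(np.full(idx.shape[0], r))
    return reset, np.concatenate(sample), np.concatenate(run_idx)


def integrate_model(params: DCMParameters, design: StimulusDesign, TR: float,
                    U: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free sampled BOLD for one parameter set (core of the likelihood).

    Returns (values (T, n), run_index (T,)).  Raises IntegrationError if the
    cascade diverges.
    """
    if U is None:
        U = build_stimulus_inputs(design)
    reset, sample, run_idx = _scan_grid(design, TR)
    n = params.n
    out = np.empty((sample.shape[0], n))
    kappa, tau, eps = _hemo_constants(params.hemo)
    code = _integrate.integrate_bold(
        np.ascontiguousarray(params.A), np.ascontiguousarray(params.B),
        np.ascontiguousarray(params.C), np.ascontiguousarray(np.diag(params.A)),
        np.ascontiguousarray(np.diagonal(params.B, axis1=1, axis2=2)),
        kappa, tau, eps, np.ascontiguousarray(U), design.dt,
        reset, sample, out)
    if code != 0:
        raise IntegrationError(
            f"hemodynamic states left the physical domain at microtime step "
            f"{code} (volume/deoxyhemoglobin non-positive or non-finite)")
    return out, run_idx


def simulate_bold(params: DCMParameters, switch: SwitchSpec,
                  design: StimulusDesign, TR: float = 2.0,
                  noise_sd: float | np.ndarray = 0.0,
                  seed: int | None = None,
                  regions: RegionSet = DEFAULT_REGIONS) -> BOLDTimeSeries:
    """Simulate an observed BOLD time series under the switched model.

    Disabled entries are forced to zero, the ODEs are integrated at the
    design's microtime step, sampled every TR within each run, and
    independent Gaussian observation noise is added per region
    (``noise_sd`` may be a scalar or one sd per region).  Deterministic
    given ``seed``.
    """
    p = params.masked(switch)
    values, run_idx = integrate_model(p, design, TR)
    noise_sd = np.broadcast_to(np.asarray(noise_sd, float),
                               (values.shape[1],))
    if np.any(noise_sd > 0):
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, 1.0, size=values.shape) * noise_sd
    return BOLDTimeSeries(values, TR, run_idx, regions.labels)
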