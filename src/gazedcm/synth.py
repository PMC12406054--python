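"""Synthetic-data generation with planted ground truth.

Every input the pipeline consumes can be generated here: the encoding task
schedule (8 runs of 500 s + 10 s lead-in / 12.4 s tail, 72 images per run,
36 free- + 36 fixed-viewing, 4 s images separated by 1.72-4.16 s fixation
crosses), group-structured connectivity with between-subject variability,
noisy BOLD, fixation reports with a plantable encoding-retrieval overlap,
and confidence-graded recognition responses whose free-minus-fixed
advantage is correlated with the planted self-modulation parameters.

Group-mean connectivity defaults are seeded from the study's published
group estimates so simulated cohorts live in a realistic regime.  All
generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import (BOLDTimeSeries, DCMParameters, InputChannel,
                      RegionSet, StimulusDesign, SwitchSpec,
                      effective_jacobian, simulate_bold, DEFAULT_REGIONS)

__all__ = ["GroundTruth", "TaskDesign", "make_task_design",
           "make_group_parameters", "make_bold_dataset", "make_fixations",
           "make_responses", "SCENE_MEANS", "SCRAMBLED_MEANS"]

RUN_TASK_S = 500.0
LEAD_IN_S = 10.0
TAIL_S = 12.4
RUN_TOTAL_S = RUN_TASK_S + LEAD_IN_S + TAIL_S
TRIAL_DUR_S = 4.0
GAP_RANGE_S = (1.72, 4.16)
TRIALS_PER_RUN = 72
IMG_W, IMG_H = 500, 500
CROSS_XY = (250.0, 250.0)

# region order OCP, PPA, HPC; entry [r, c] is the connection c -> r
SCENE_MEANS = {
    "A": np.array([[0.218, -0.657, 0.0],
                   [0.747, 0.407, -0.277],
                   [0.0, 0.0, 0.207]]),
    "B": np.array([[-1.277, 0.0, 0.0],
                   [0.346, -0.744, -2.44],
                   [0.0, 0.262, -0.867]]),
    "C": 0.638,
}
SCRAMBLED_MEANS = {
    "A": np.array([[0.264, 0.125, 0.0],
                   [0.0, -0.179, 0.247],
                   [0.0, 0.235, -0.156]]),
    "B": np.array([[-0.539, 0.0, 0.0],
                   [0.241, -2.003, -1.100],
                   [0.0, 0.0, -1.102]]),
    "C": 0.173,
}


@dataclass
class GroundTruth:
    """Planted generative conditions for one synthetic study."""

    A_mean: np.ndarray = field(
        default_factory=lambda: SCENE_MEANS["A"].copy())
    B_mean: np.ndarray = field(
        default_factory=lambda: SCENE_MEANS["B"].copy())
    C_mean: float = SCENE_MEANS["C"]
    between_sd: float = 0.25        # per-parameter between-subject sd
    hemo_sd: float = 0.05           # sd of hemodynamic log-scalings
    noise_sd: float = 0.15          # BOLD observation noise, % signal (SNR~1)
    behavior_corr: float = 0.6      # target corr(B-self latent, d_memory)
    gaze_corr: float = 0.5          # target corr(B-self latent, d_gaze)
    jitter_sd_px: float = 20.0      # encoding->retrieval fixation jitter
    reinstate_frac: float = 0.7     # fraction of free images reinstated
    free_fix_rate: float = 10.0     # mean fixations per 4 s free trial
    fixed_fix_max: int = 3          # 1..max fixations on a fixed trial
    master_seed: int = 0

    def __post_init__(self):
        self.A_mean = np.asarray(self.A_mean, float)
        self.B_mean = np.asarray(self.B_mean, float)
        if self.between_sd < 0 or self.hemo_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for c in (self.behavior_corr, self.gaze_corr):
            if not abs(c) < 1:
                raise ValueError("target correlations must satisfy |rho| < 1")

    def scrambled(self) -> "GroundTruth":
        """Variant with the scrambled-image group means planted."""
        out = GroundTruth(**{**self.__dict__})
        out.A_mean = SCRAMBLED_MEANS["A"].copy()
        out.B_mean = SCRAMBLED_MEANS["B"].copy()
        out.C_mean = SCRAMBLED_MEANS["C"]
        return out


@dataclass
class TaskDesign:
    """A realized task schedule: trial events plus per-condition designs."""

    events: pd.DataFrame            # onset, duration, trial_type, run, image
    TR: float
    dt: float

    def condition_design(self, condition: str) -> StimulusDesign:
        """Microtime design for one encoding condition ("scene" or
        "scrambled"), runs concatenated with state resets at boundaries.

        Channel 0: all encoding trials (mean-centered driving input);
        channel 1: free-viewing trials (uncentered modulator).
        """
        ev = self.events[self.events["trial_type"]
                         .str.startswith(condition)].copy()
        if len(ev) == 0:
            raise ValueError(f"no trials for condition {condition!r}")
        runs = sorted(ev["run"].unique())
        remap = {r: i for i, r in enumerate(runs)}
        onsets = (ev["onset_in_run"].to_numpy()
                  + ev["run"].map(remap).to_numpy() * RUN_TOTAL_S)
        total = RUN_TOTAL_S * len(runs)
        free = ev["trial_type"].str.endswith("free").to_numpy()
        dur = ev["duration"].to_numpy()
        chans = (
            InputChannel("all_trials", onsets, dur, mean_center=True),
            InputChannel("free_trials", onsets[free], dur[free],
                         mean_center=False),
        )
        bounds = np.arange(len(runs)) * RUN_TOTAL_S
        return StimulusDesign(chans, self.dt, total, bounds)

    def images(self, condition: str) -> pd.DataFrame:
        ev = self.events[self.events["trial_type"]
                         .str.startswith(condition)]
        return ev[["image", "trial_type"]].assign(
            condition=ev["trial_type"].str.rsplit("_", n=1).str[-1])


def _schedule_run(rng: np.random.Generator, n_trials: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Trial onsets within one run's 500 s task window (after lead-in)."""
    min_len = n_trials * (TRIAL_DUR_S + GAP_RANGE_S[0])
    if min_len > RUN_TASK_S:
        raise ValueError(
            f"{n_trials} trials cannot fit in {RUN_TASK_S:.0f} s")
    for _ in range(1000):
        gaps = rng.uniform(*GAP_RANGE_S, size=n_trials)
        onsets = LEAD_IN_S + np.cumsum(gaps) + TRIAL_DUR_S * np.arange(n_trials)
        if onsets[-1] + TRIAL_DUR_S <= LEAD_IN_S + RUN_TASK_S:
            return onsets, gaps
    raise ValueError(f"could not fit {n_trials} trials in "
                     f"{RUN_TASK_S:.0f} s after 1000 draws")


def make_task_design(n_scene_runs: int = 6, n_scrambled_runs: int = 2,
                     seed: int = 0, TR: float = 2.0,
                     trials_per_run: int = TRIALS_PER_RUN,
                     dt: float | None = None) -> TaskDesign:
    """Randomized task schedule in the study's geometry.

    Per run: ``trials_per_run`` images (half free-, half fixed-viewing, in
    seeded pseudo-random order), 4 s each, inter-trial fixation cross
    uniform on [1.72, 4.16] s, all within a 500 s task window preceded by a
    10 s lead-in and followed by a 12.4 s tail.
    """
    if trials_per_run % 2:
        raise ValueError("trials_per_run must be even (free/fixed split)")
    rng = np.random.default_rng(seed)
    dt = TR / 16.0 if dt is None else dt
    rows = []
    run_types = ["scene"] * n_scene_runs + ["scrambled"] * n_scrambled_runs
    for run, rtype in enumerate(run_types):
        onsets, _ = _schedule_run(rng, trials_per_run)
        half = trials_per_run // 2
        viewing = np.array(["free"] * half + ["fixed"] * half, object)
        rng.shuffle(viewing)
        for t, (onset, view) in enumerate(zip(onsets, viewing)):
            rows.append({
                "onset": onset + run * RUN_TOTAL_S,
                "onset_in_run": onset,
                "duration": TRIAL_DUR_S,
                "trial_type": f"{rtype}_{view}",
                "run": run,
                "image": f"{rtype}_r{run}_t{t:02d}",
            })
    events = pd.DataFrame(rows)
    return TaskDesign(events, TR, dt)


def crop_design(design: StimulusDesign, n_scans: int, TR: float = 2.0
                ) -> StimulusDesign:
    """Truncate a design to the window covered by the first ``n_scans``
    scans (trials extending past the window are dropped)."""
    total = n_scans * TR
    chans = []
    for ch in design.channels:
        on = np.asarray(ch.onsets, float)
        du = np.asarray(ch.durations, float)
        keep = on + du <= total
        chans.append(InputChannel(ch.name, on[keep], du[keep],
                                  ch.mean_center))
    bounds = np.asarray(design.run_boundaries, float)
    bounds = bounds[bounds < total]
    return StimulusDesign(tuple(chans), design.dt, total, bounds)


def make_group_parameters(truth: GroundTruth, N: int = 36, seed: int = 0,
                          regions: RegionSet = DEFAULT_REGIONS
                          ) -> list[DCMParameters]:
    """Per-subject parameters: group mean + truncated Gaussian deviations.

    Deviations are clipped at +/-2 sd, and draws whose neuronal system is
    not dynamically stable (spectral abscissa of the effective coupling
    with the modulator off or fully on above -0.02 Hz) are redrawn, so
    every simulated subject produces bounded dynamics.  The truncation can
    shift sample means from the nominal group means by a small fraction of
    the between-subject sd.  Only entries of the full design's switch
    receive deviations (others stay 0).
    """
    if N < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    switch = SwitchSpec.full_design(regions)
    out = []
    for _ in range(N):
        for attempt in range(200):
            dA = np.clip(rng.normal(0, 1, truth.A_mean.shape), -2, 2)
            dB = np.clip(rng.normal(0, 1, truth.B_mean.shape), -2, 2)
            dC = np.clip(rng.normal(0, 1), -2, 2)
            A = truth.A_mean + truth.between_sd * dA * switch.A_mask
            B = truth.B_mean + truth.between_sd * dB * switch.B_masks[0]
            C = np.zeros((regions.n, 2))
            C[regions.index("OCP"), 0] = truth.C_mean + truth.between_sd * dC
            hemo = np.clip(rng.normal(0, 1, (regions.n, 3)), -2,
                           2) * truth.hemo_sd
            params = DCMParameters(A, B[None], C, hemo, regions).masked(
                switch)
            if _dynamically_stable(params):
                break
        else:
            raise RuntimeError(
                "could not draw a dynamically stable subject; the group "
                "means or between-subject sd put the cohort outside the "
                "stable regime")
        out.append(params)
    return out


def _dynamically_stable(params: DCMParameters, margin: float = 0.02) -> bool:
    """Subjects are constrained to the regime where the neuronal system is
    stable with the modulator off and on (spectral abscissa below -margin)."""
    for u_free in (0.0, 1.0):
        J = effective_jacobian(params, np.array([0.0, u_free]))
        if np.max(np.linalg.eigvals(J).real) > -margin:
            return False
    return True


def make_bold_dataset(params_per_subject: list[DCMParameters],
                      design: StimulusDesign, TR: float = 2.0,
                      noise_sd: float | np.ndarray = 0.15, seed: int = 0,
                      regions: RegionSet = DEFAULT_REGIONS
                      ) -> list[BOLDTimeSeries]:
    """Simulate each subject's observed series under a common design
    (``noise_sd`` scalar or per region)."""
    switch = SwitchSpec.full_design(regions)
    seeds = np.random.SeedSequence(seed).generate_state(
        len(params_per_subject)) % (2 ** 31)
    return [simulate_bold(p, switch, design, TR, noise_sd, int(s), regions)
            for p, s in zip(params_per_subject, seeds)]


def _image_mixture(rng: np.random.Generator):
    """Image-specific 2-component spatial mixture (shared across subjects)."""
    centers = rng.uniform([80, 80], [IMG_W - 80, IMG_H - 80], size=(2, 2))
    weights = rng.dirichlet([2.0, 2.0])
    sd = rng.uniform(30, 60, size=2)
    return centers, weights, sd


def _draw_from_mixture(rng, centers, weights, sd, n):
    comp = rng.choice(2, size=n, p=weights)
    xy = centers[comp] + rng.normal(0, 1, (n, 2)) * sd[comp, None]
    return np.clip(xy, 1.0, [IMG_W - 2, IMG_H - 2])


def _latent(B_self: np.ndarray) -> np.ndarray:
    """Standardized subject latent from the PPA/HPC self-modulation values
    (higher = less disinhibition), the axis behavior is coupled to."""
    B_self = np.atleast_2d(np.asarray(B_self, float))
    lat = B_self.mean(axis=1) if B_self.shape[1] > 1 else B_self[:, 0]
    sd = lat.std()
    return (lat - lat.mean()) / sd if sd > 0 else np.zeros_like(lat)


def make_fixations(truth: GroundTruth, subjects: list[str],
                   images: pd.DataFrame, seed: int = 0,
                   B_self: np.ndarray | None = None) -> pd.DataFrame:
    """Fixation reports for encoding and retrieval phases.

    Free trials draw Poisson(free_fix_rate) fixations from an
    image-specific spatial mixture; fixed trials place 1..fixed_fix_max
    fixations within 25 px of the central cross.  At retrieval (always
    free viewing), a per-subject fraction of free-encoded images replays
    the encoding fixations plus Gaussian jitter; all other retrieval
    scanpaths are fresh draws.  If ``B_self`` (per-subject self-modulation
    values) is given, the replay fraction increases with the subject latent
    so the gaze-behavior coupling is planted.
    """
    rng = np.random.default_rng(seed)
    if B_self is not None:
        lat = _latent(B_self)
        gc = truth.gaze_corr
        mix = gc * lat + np.sqrt(1 - gc ** 2) * rng.normal(
            0, 1, len(subjects))
        frac = np.clip(truth.reinstate_frac + 0.25 * mix, 0.02, 0.98)
    else:
        frac = np.full(len(subjects), truth.reinstate_frac)

    mixtures = {img: _image_mixture(rng) for img in images["image"]}
    cond_of = dict(zip(images["image"], images["condition"]))
    rows = []

    def add(subj, img, phase, cond, xy, durs):
        for (x, y), d in zip(xy, durs):
            rows.append({"subject": subj, "image": img, "phase": phase,
                         "condition": cond, "x": float(x), "y": float(y),
                         "duration": float(d)})

    for si, subj in enumerate(subjects):
        for img, cond in cond_of.items():
            centers, weights, sd = mixtures[img]
            if cond == "free":
                n_enc = max(1, rng.poisson(truth.free_fix_rate))
                enc = _draw_from_mixture(rng, centers, weights, sd, n_enc)
            else:
                n_enc = rng.integers(1, truth.fixed_fix_max + 1)
                ang = rng.uniform(0, 2 * np.pi, n_enc)
                rad = rng.uniform(0, 25.0, n_enc)
                enc = np.column_stack([CROSS_XY[0] + rad * np.cos(ang),
                                       CROSS_XY[1] + rad * np.sin(ang)])
            durs_e = rng.lognormal(np.log(250), 0.35, n_enc)
            add(subj, img, "encoding", cond, enc, durs_e)

            # retrieval is always unrestricted viewing
            reinstated = (cond == "free" and rng.uniform() < frac[si])
            if reinstated:
                # replayed scanpath: encoding fixations (and durations)
                # plus spatial jitter
                ret = enc + rng.normal(0, truth.jitter_sd_px, enc.shape)
                ret = np.clip(ret, 1.0, [IMG_W - 2, IMG_H - 2])
                durs_r = durs_e
            else:
                n_ret = max(1, rng.poisson(truth.free_fix_rate))
                c2, w2, s2 = _image_mixture(rng)  # unrelated scanpath
                ret = _draw_from_mixture(rng, c2, w2, s2, n_ret)
                durs_r = rng.lognormal(np.log(250), 0.35, len(ret))
            add(subj, img, "retrieval", cond, ret, durs_r)
    return pd.DataFrame(rows)


def make_responses(truth: GroundTruth, B_self: np.ndarray,
                   subjects: list[str], images: pd.DataFrame, seed: int = 0,
                   n_lures: int = 20) -> pd.DataFrame:
    """Recognition responses planting the behavior-connectivity coupling.

    Each subject's free-minus-fixed memory advantage is drawn so that its
    correlation with the planted PPA/HPC self-modulation latent matches
    ``truth.behavior_corr`` in expectation; per-trial old/new and
    confidence outcomes are then realized binomially to hit each subject's
    condition means.  Lures (truth = "new") are appended with a fixed
    false-alarm rate; they carry no memory score.
    """
    rng = np.random.default_rng(seed)
    lat = _latent(B_self)
    N = len(subjects)
    rho = truth.behavior_corr
    adv = 0.35 * (rho * lat + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, N))
    base = rng.normal(0.9, 0.1, N)      # mean memory score, fixed condition

    cond_of = dict(zip(images["image"], images["condition"]))
    rows = []
    for si, subj in enumerate(subjects):
        mean_scores = {"fixed": base[si], "free": base[si] + adv[si]}
        for img, cond in cond_of.items():
            # with confidence independent of accuracy at P(high)=0.5,
            # E[score] = 2 h - 0.5 where h = P(correct old)
            h = np.clip((mean_scores[cond] + 0.5) / 2.0, 0.02, 0.98)
            hit = rng.uniform() < h
            conf = "high" if rng.uniform() < 0.5 else "low"
            rows.append({"subject": subj, "image": img, "truth": "old",
                         "response": "old" if hit else "new",
                         "confidence": conf, "condition": cond})
        for li in range(n_lures):
            fa = rng.uniform() < 0.2
            rows.append({"subject": subj, "image": f"lure_{li:03d}",
                         "truth": "new",
                         "response": "old" if fa else "new",
                         "confidence": "high" if rng.uniform() < 0.5
                         else "low", "condition": "lure"})
    return pd.DataFrame(rows)
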