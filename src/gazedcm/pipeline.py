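"""Stage sequencing: simulate/ingest -> invert -> PEB -> families -> BMA ->
behavior -> CVA, with file-based artifacts, a manifest, and tidy reports.

Each stage reads its inputs from, and writes its outputs under, the
configured output directory, so stages can be run individually (CLI) or as
one pipeline (`run_pipeline`).  All stochastic stages take their seeds from
the single configured master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, gaze, io, peb, stats, synth
from .forward import SwitchSpec, DEFAULT_REGIONS
from .inversion import variational_laplace
from .peb import MODULATORY_ENTRIES

log = logging.getLogger("gazedcm")

CONDITIONS = ("scene", "scrambled")


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    outdir: str = "gazedcm_out"
    seed: int = 0
    TR: float = 2.0
    n_subjects: int = 8
    n_scene_runs: int = 2
    n_scrambled_runs: int = 1
    noise_sd: float = 0.15
    between_sd: float = 0.25
    behavior_corr: float = 0.6
    gaze_corr: float = 0.5
    jitter_sd_px: float = 20.0
    grid_scale: float = 0.2     # density-map resolution relative to 500 px
    sigma_px: float = 63.0      # smoothing at full (500 px) resolution
    control_k: int = 50
    n_perm: int = 1999
    pp_threshold: float = 0.95
    crop_scans: int = 0         # truncate each condition to this many scans
    jobs: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if cfg.TR <= 0 or cfg.noise_sd < 0 or not 0 < cfg.grid_scale <= 1:
            raise ValueError("invalid config values")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = (json.loads(text) if str(path).endswith(".json")
             else yaml.safe_load(text))
        return cls.from_dict(d or {})

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    def subjects(self) -> list[str]:
        return [f"sub-{i:02d}" for i in range(self.n_subjects)]


def _seed(cfg: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig) -> dict:
    """Generate every pipeline input with planted ground truth."""
    t0 = time.time()
    data = cfg.out / "data"
    data.mkdir(parents=True, exist_ok=True)
    truth = synth.GroundTruth(
        between_sd=cfg.between_sd, noise_sd=cfg.noise_sd,
        behavior_corr=cfg.behavior_corr, gaze_corr=cfg.gaze_corr,
        jitter_sd_px=cfg.jitter_sd_px, master_seed=cfg.seed)
    td = synth.make_task_design(cfg.n_scene_runs, cfg.n_scrambled_runs,
                                seed=_seed(cfg, "design"), TR=cfg.TR)
    io.write_events(data / "events.tsv", td.events)

    subjects = cfg.subjects()
    planted = {}
    for cond in CONDITIONS:
        tc = truth if cond == "scene" else truth.scrambled()
        design = td.condition_design(cond)
        if cfg.crop_scans:
            design = synth.crop_design(design, cfg.crop_scans, cfg.TR)
        params = synth.make_group_parameters(
            tc, cfg.n_subjects, seed=_seed(cfg, f"params:{cond}"))
        bolds = synth.make_bold_dataset(
            params, design, cfg.TR, tc.noise_sd,
            seed=_seed(cfg, f"bold:{cond}"))
        for subj, b in zip(subjects, bolds):
            io.write_timeseries(data / f"{subj}_{cond}_bold.tsv", b)
        planted[cond] = params

    # behavior planted on the scene-condition B self-modulations (PPA, HPC)
    i_ppa, i_hpc = (DEFAULT_REGIONS.index(l) for l in ("PPA", "HPC"))
    B_self = np.stack([[p.B[0, i_ppa, i_ppa], p.B[0, i_hpc, i_hpc]]
                       for p in planted["scene"]])
    images = td.images("scene")
    fix = synth.make_fixations(truth, subjects, images,
                               seed=_seed(cfg, "fixations"), B_self=B_self)
    resp = synth.make_responses(truth, B_self, subjects, images,
                                seed=_seed(cfg, "responses"))
    fix.to_csv(data / "fixations.csv", index=False)
    resp.to_csv(data / "responses.csv", index=False)

    planted_out = {
        cond: [{"A": p.A.tolist(), "B": p.B.tolist(), "C": p.C.tolist(),
                "hemo": p.hemo.tolist()} for p in planted[cond]]
        for cond in CONDITIONS}
    (data / "planted_truth.json").write_text(json.dumps(planted_out))
    log.info("simulate: %d subjects, %.1fs", cfg.n_subjects, time.time() - t0)
    return {"data_dir": str(data), "n_subjects": cfg.n_subjects}


def stage_invert(cfg: RunConfig) -> dict:
    """Subject-level variational-Laplace inversions per condition."""
    t0 = time.time()
    data = cfg.out / "data"
    pdir = cfg.out / "posteriors"
    pdir.mkdir(parents=True, exist_ok=True)
    events = io.read_events(data / "events.tsv")
    td = synth.TaskDesign(events, cfg.TR, cfg.TR / 16.0)
    switch = SwitchSpec.full_design()
    n_done = 0
    for cond in CONDITIONS:
        design = td.condition_design(cond)
        if cfg.crop_scans:
            design = synth.crop_design(design, cfg.crop_scans, cfg.TR)
        for subj in cfg.subjects():
            bold = io.read_timeseries(data / f"{subj}_{cond}_bold.tsv")
            post = variational_laplace(bold, design, switch)
            io.write_posterior(pdir / f"{subj}_{cond}.json", post)
            n_done += 1
            log.info("invert %s/%s: F=%.1f (%d iter)", subj, cond,
                     post.F, post.n_iter)
    log.info("invert: %d inversions, %.1fs", n_done, time.time() - t0)
    return {"n_inversions": n_done}


def _load_posteriors(cfg: RunConfig, cond: str):
    pdir = cfg.out / "posteriors"
    return [io.read_posterior(pdir / f"{subj}_{cond}.json")
            for subj in cfg.subjects()]


def stage_peb(cfg: RunConfig) -> dict:
    """Group PEB, A/C automatic search, B family comparison + BMA, and
    empirical updates of subject-level modulatory parameters."""
    t0 = time.time()
    rdir = cfg.out / "results"
    rdir.mkdir(parents=True, exist_ok=True)
    peb.model_space_table().to_csv(rdir / "model_space.csv", index=False)
    out = {}
    for cond in CONDITIONS:
        posts = _load_posteriors(cfg, cond)

        peb_b = peb.fit_peb(posts, which_params=list(MODULATORY_ENTRIES))
        bma_b = peb.family_analysis(peb_b)
        fam = pd.DataFrame(sorted(bma_b.family_post.items()),
                           columns=["family", "Pp"])
        fam.to_csv(rdir / f"families_{cond}.csv", index=False)

        peb_ac = peb.fit_peb(posts, which_params="A+C")
        _, bma_ac = peb.automatic_prune(peb_ac)

        rows = []
        for names, bma in ((bma_b.param_names, bma_b),
                           (bma_ac.param_names, bma_ac)):
            for nm, ep, pp in zip(names, bma.Ep, bma.Pp):
                rows.append({"parameter": nm, "Ep": ep, "Pp": pp,
                             "condition": cond,
                             "strong_evidence": bool(pp >= cfg.pp_threshold)})
        pd.DataFrame(rows).to_csv(rdir / f"bma_{cond}.csv", index=False)

        updated = peb.empirical_update_subjects(peb_b, posts)
        pd.DataFrame(updated, index=cfg.subjects(),
                     columns=list(MODULATORY_ENTRIES)) \
            .rename_axis("subject") \
            .to_csv(rdir / f"subject_modulatory_{cond}.csv")
        out[cond] = {"winning_family": bma_b.winning_family,
                     "family_Pp": bma_b.family_post}
    log.info("peb: %.1fs", time.time() - t0)
    return out


def stage_behavior(cfg: RunConfig) -> dict:
    """Memory-strength and gaze-reinstatement differences per subject."""
    t0 = time.time()
    data = cfg.out / "data"
    rdir = cfg.out / "results"
    rdir.mkdir(parents=True, exist_ok=True)
    fix = io.read_fixations(data / "fixations.csv")
    resp = io.read_responses(data / "responses.csv")

    scale = cfg.grid_scale
    fx = fix.copy()
    fx["x"] = fx["x"] * scale
    fx["y"] = fx["y"] * scale
    w = h = max(int(round(synth.IMG_W * scale)), 8)
    reinst = gaze.reinstatement_table(
        fx, w, h, sigma=cfg.sigma_px * scale, k=cfg.control_k,
        seed=_seed(cfg, "behavior"))
    reinst.to_csv(rdir / "reinstatement.csv", index=False)

    old = resp[resp["truth"] == "old"].copy()
    old["score"] = [gaze.memory_strength_score(t, r, c) for t, r, c in
                    zip(old["truth"], old["response"], old["confidence"])]
    table = gaze.behavior_differences(old, reinst)
    table.to_csv(rdir / "behavior.csv")
    log.info("behavior: %d subjects, %.1fs", len(table), time.time() - t0)
    return {"n_subjects": len(table)}


def stage_cva(cfg: RunConfig) -> dict:
    """CVA of scene modulatory strength against behavior, plus the
    scene-vs-scrambled per-connection contrasts."""
    t0 = time.time()
    rdir = cfg.out / "results"
    bma = pd.read_csv(rdir / "bma_scene.csv")
    bma_b = bma[bma["parameter"].isin(MODULATORY_ENTRIES)]
    strong = [p for p in MODULATORY_ENTRIES
              if bool(bma_b.loc[bma_b["parameter"] == p,
                                "strong_evidence"].iloc[0])]
    if not strong:
        warnings.warn("no modulatory parameter reached the Pp threshold; "
                      "using all modulatory entries for CVA")
        strong = list(MODULATORY_ENTRIES)
    beh = pd.read_csv(rdir / "behavior.csv", index_col="subject")
    Xdf = pd.read_csv(rdir / "subject_modulatory_scene.csv",
                      index_col="subject")
    common = [s for s in Xdf.index if s in beh.index]
    q = beh.shape[1]
    max_p = len(common) - q - 1
    if len(strong) > max_p:
        warnings.warn(f"N={len(common)} supports at most {max_p} X columns; "
                      f"keeping the {max_p} highest-Pp parameters")
        order = bma_b.set_index("parameter").loc[strong, "Pp"] \
            .sort_values(ascending=False)
        strong = list(order.index[:max_p])
    X = Xdf.loc[common, strong].to_numpy()
    Y = beh.loc[common].to_numpy()
    cva = stats.canonical_variate_analysis(
        X, Y, tuple(strong), tuple(beh.columns),
        n_perm=cfg.n_perm, seed=_seed(cfg, "cva"))

    pd.DataFrame(cva.x_loadings, index=strong,
                 columns=[f"variate_{i + 1}" for i
                          in range(cva.x_loadings.shape[1])]) \
        .rename_axis("parameter").to_csv(rdir / "cva_x_loadings.csv")
    pd.DataFrame(cva.y_loadings, index=list(beh.columns),
                 columns=[f"variate_{i + 1}" for i
                          in range(cva.y_loadings.shape[1])]) \
        .rename_axis("measure").to_csv(rdir / "cva_y_loadings.csv")
    cva_json = {
        "canonical_correlations": cva.correlations.tolist(),
        "shared_variance_pct": cva.shared_variance_pct.tolist(),
        "chi2": cva.chi2.tolist(), "chi2_p": cva.chi2_p.tolist(),
        "perm_p": cva.perm_p.tolist(), "n_perm": cva.n_perm,
        "x_names": list(strong), "y_names": list(beh.columns),
    }
    (rdir / "cva.json").write_text(json.dumps(cva_json, indent=1))

    Xs = pd.read_csv(rdir / "subject_modulatory_scene.csv",
                     index_col="subject")
    Xr = pd.read_csv(rdir / "subject_modulatory_scrambled.csv",
                     index_col="subject")
    common2 = [s for s in Xs.index if s in Xr.index]
    table, omnibus = stats.connection_contrasts(
        Xs.loc[common2].to_numpy(), Xr.loc[common2].to_numpy(),
        tuple(Xs.columns))
    table.to_csv(rdir / "contrasts.csv", index=False)
    (rdir / "omnibus_anova.json").write_text(json.dumps(omnibus, indent=1))
    log.info("cva: r1=%.3f, %.1fs", cva.correlations[0], time.time() - t0)
    return {"r": cva.correlations.tolist(),
            "shared_variance_pct": cva.shared_variance_pct.tolist(),
            "perm_p": cva.perm_p.tolist()}


def validate_inputs(paths: dict) -> dict:
    """Schema and cross-reference checks on input files.

    ``paths`` may contain events, fixations, responses, and a list of
    timeseries files.  Returns {"errors": [...], "warnings": [...]};
    an empty ``errors`` list means the inputs are usable.
    """
    report = {"errors": [], "warnings": []}
    subjects_bold, subjects_beh = set(), set()
    if "events" in paths:
        try:
            ev = io.read_events(paths["events"])
            bad = ev[(ev["duration"] <= 0) | (ev["onset"] < 0)]
            if len(bad):
                report["errors"].append(
                    f"events: {len(bad)} rows with non-positive duration or "
                    f"negative onset (rows {bad.index.tolist()[:10]})")
        except Exception as e:
            report["errors"].append(f"events: {e}")
    for key, reader in (("fixations", io.read_fixations),
                        ("responses", io.read_responses)):
        if key in paths:
            try:
                df = reader(paths[key])
                subjects_beh |= set(df["subject"].unique())
            except Exception as e:
                report["errors"].append(f"{key}: {e}")
    trs = set()
    for ts in paths.get("timeseries", []):
        try:
            b = io.read_timeseries(ts)
            trs.add(b.TR)
            subjects_bold.add(Path(ts).name.split("_")[0])
        except Exception as e:
            report["errors"].append(f"timeseries {ts}: {e}")
    if len(trs) > 1:
        report["errors"].append(f"inconsistent TR across series: {sorted(trs)}")
    if subjects_bold and subjects_beh:
        only_bold = subjects_bold - subjects_beh
        if only_bold:
            report["warnings"].append(
                f"subjects with BOLD but no behavior: {sorted(only_bold)}")
    return report


def write_reports(cfg: RunConfig, results: dict) -> Path:
    """Manifest (input hashes, seeds, versions) and human-readable summary."""
    rdir = cfg.out / "results"
    rdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "versions": {"gazedcm": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "inputs": {p.name: _sha256(p)
                   for p in sorted((cfg.out / "data").glob("*"))
                   if p.is_file()},
        "stages": {k: v for k, v in results.items()},
    }
    (cfg.out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    lines = ["gazedcm pipeline summary", "=" * 24, ""]
    for cond in CONDITIONS:
        if cond in results.get("peb", {}):
            r = results["peb"][cond]
            lines.append(f"[{cond}] winning modulatory family: "
                         f"{r['winning_family']} "
                         f"(Pp={r['family_Pp'][r['winning_family']]:.3f})")
            bma = pd.read_csv(rdir / f"bma_{cond}.csv")
            for _, row in bma.iterrows():
                flag = " *" if row["strong_evidence"] else ""
                lines.append(f"    {row['parameter']:<16s} Ep={row['Ep']:+.3f}"
                             f" Pp={row['Pp']:.3f}{flag}")
            lines.append("")
    if "cva" in results:
        r = results["cva"]
        lines.append(f"CVA: r1={r['r'][0]:.3f}, shared variance "
                     f"{r['shared_variance_pct'][0]:.1f}%, "
                     f"permutation p={r['perm_p'][0]:.4f}")
    (cfg.out / "summary.txt").write_text("\n".join(lines) + "\n")
    return cfg.out / "summary.txt"


STAGES = {"simulate": stage_simulate, "invert": stage_invert,
          "peb": stage_peb, "behavior": stage_behavior, "cva": stage_cva}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; abort (keeping partial outputs) on the
    first failing stage, naming it."""
    results = {}
    for name in ("simulate", "invert", "peb", "behavior", "cva"):
        t0 = time.time()
        try:
            results[name] = STAGES[name](cfg)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        log.info("stage %s done in %.1fs", name, time.time() - t0)
    write_reports(cfg, results)
    return results
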