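"""Shared configuration for the numbered analysis drivers."""

from pathlib import Path

from gazedcm.pipeline import RunConfig

HERE = Path(__file__).resolve().parent


def load_config(seed: int | None = None) -> RunConfig:
    cfg = RunConfig.from_file(HERE / "config.yaml")
    cfg.outdir = str((HERE.parent / cfg.outdir).resolve())
    if seed is not None:
        cfg.seed = seed
    return cfg
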