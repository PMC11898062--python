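"""End-to-end toy-wire pipeline: generate -> sample -> WHAM -> classify.

The pipeline is a pure function of (config, seed): rerunning with the same
configuration reproduces every output byte-for-byte.  Outputs are written
to a run directory: per-window time series, the WHAM profile with bootstrap
bands, the quadrature reference (1-D wires), and a JSON report with the
profile features, the feasibility category and the thresholds used.

Sampling requires a potential surface, so the pipeline operates on the
synthetic wire systems; structure-based stages (wire enumeration, CEC
tables) are exposed as separate CLI commands.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .fes import UmbrellaWHAM
from .io import config_hash, write_profile, write_segment
from .profiles import ClassificationThresholds
from .toys import ToyWireSpec, build_toy_wire, sample_toy_profile, scenario_presets

__all__ = ["RunConfig", "ToyConfig", "WindowConfig", "WHAMConfig", "run_pipeline"]


class ToyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: str | None = None
    n_waters: int = 1
    affinities: tuple[float, ...] | None = None
    spacing: float = 2.7
    trap_site: int | None = None
    trap_extra: float = 0.0
    redox_shift: float = 0.0
    dimensionality: str = "1d"


class WindowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    spacing: float = 0.1
    k: float = 1000.0
    steps: int = 50000
    temperature: float = 310.0
    max_refine: int = 4
    overlap_threshold: float = 0.10


class WHAMConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bin_width: float = 0.01
    tol: float = 1e-8
    max_iter: int = 100000
    equilibration: float = 0.2
    bootstrap_cycles: int = 30


class ThresholdsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    uphill: float = 70.0
    unstable_reverse: float = 15.0
    trap_depth: float = 20.0
    trap_escape: float = 70.0
    downhill: float = -70.0
    plausible_barrier: float = 45.0
    plausible_dgr: float = 20.0


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    toy: ToyConfig = ToyConfig()
    windows: WindowConfig = WindowConfig()
    wham: WHAMConfig = WHAMConfig()
    thresholds: ThresholdsConfig = ThresholdsConfig()
    seed: int = 0


def _toy_spec(cfg: ToyConfig, seed: int) -> ToyWireSpec:
    if cfg.preset is not None:
        presets = scenario_presets()
        if cfg.preset not in presets:
            raise ValueError(
                f"unknown preset {cfg.preset!r}; choose from {sorted(presets)}"
            )
        base = presets[cfg.preset]
        return ToyWireSpec(**{**base.__dict__, "seed": seed})
    return ToyWireSpec(
        n_waters=cfg.n_waters,
        affinities=tuple(cfg.affinities) if cfg.affinities else (),
        spacing=cfg.spacing,
        trap_site=cfg.trap_site,
        trap_extra=cfg.trap_extra,
        redox_shift=cfg.redox_shift,
        dimensionality=cfg.dimensionality,
        seed=seed,
    )


def run_pipeline(config: RunConfig | dict, outdir: str | Path) -> dict:
    """Run generate -> windows -> sample -> discard -> WHAM -> bootstrap ->
    features -> classification; returns the report dict."""
    if isinstance(config, dict):
        config = RunConfig(**config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.model_dump())

    system = build_toy_wire(_toy_spec(config.toy, config.seed))
    segments = sample_toy_profile(
        system,
        steps_per_window=config.windows.steps,
        base_seed=config.seed,
        k=config.windows.k,
        spacing=config.windows.spacing,
        max_refine=config.windows.max_refine,
        overlap_threshold=config.windows.overlap_threshold,
        temperature=config.windows.temperature,
    )
    wdir = outdir / "windows"
    wdir.mkdir(exist_ok=True)
    for seg in segments:
        write_segment(seg, wdir / f"window_{seg.window_id:03d}.tsv")

    model = UmbrellaWHAM.from_segments(
        segments,
        temperature=config.windows.temperature,
        bin_width=config.wham.bin_width,
        equilibration=config.wham.equilibration,
    )
    result = model.fit(tol=config.wham.tol, max_iter=config.wham.max_iter)
    result.bootstrap(n_cycles=config.wham.bootstrap_cycles, seed=config.seed + 10000)
    write_profile(result.profile, outdir / "profile.tsv", {"config_hash": chash})

    if system.spec.dimensionality == "1d":
        ref = system.reference_profile(
            bin_width=config.wham.bin_width,
            temperature=config.windows.temperature,
        )
        write_profile(ref, outdir / "reference.tsv", {"config_hash": chash})

    thresholds = ClassificationThresholds(**config.thresholds.model_dump())
    feats = result.features()
    cls = result.classify(thresholds)

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_windows": len(segments),
        "category": cls.category,
        "reason": cls.reason,
        "features": {
            "forward_barrier_kJmol": feats.forward_barrier,
            "reverse_barrier_kJmol": feats.reverse_barrier,
            "delta_G_R_kJmol": feats.delta_G_R,
            "minima": feats.minima,
            "maxima": feats.maxima,
        },
        "thresholds": config.thresholds.model_dump(),
        "wham_iterations": result.n_iter,
        "wham_residual_kJmol": result.residual,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {"config": config.model_dump(), "config_hash": chash,
             "window_seeds": [s.spec.seed for s in segments]},
            fh, indent=2, sort_keys=True, default=str,
        )
    return report
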