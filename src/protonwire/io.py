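"""Tabular I/O: profile and window TSVs, trajectory tables, config hashing.

One tabular dialect throughout: tab-separated, dot-decimal floats, with
'#'-prefixed ``key=value`` metadata lines before the header row.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from .fes import FreeEnergyProfile
from .sampling import TrajectorySegment, UmbrellaWindowSpec

__all__ = [
    "write_profile",
    "read_profile",
    "write_segment",
    "read_segment",
    "write_cec_table",
    "config_hash",
]

_FMT = "%.10g"


def _parse_float(token: str, path, lineno: int) -> float:
    if "," in token:
        raise ValueError(
            f"{path}:{lineno}: comma decimal {token!r} rejected (dot-decimal TSV)"
        )
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed number {token!r}") from exc


def config_hash(config) -> str:
    """Stable sha256 of a JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# free-energy profiles
# ---------------------------------------------------------------------------

def write_profile(profile: FreeEnergyProfile, path: str | Path, metadata: dict | None = None):
    """Profile TSV: zeta, G_kJmol and (when present) the 95% CI columns."""
    path = Path(path)
    meta = dict(profile.metadata)
    if metadata:
        meta.update(metadata)
    has_ci = profile.ci_low is not None
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}={meta[key]}\n")
        cols = ["zeta", "G_kJmol"] + (["ci_low", "ci_high"] if has_ci else [])
        fh.write("\t".join(cols) + "\n")
        for i in range(len(profile.zeta)):
            row = [profile.zeta[i], profile.G[i]]
            if has_ci:
                row += [profile.ci_low[i], profile.ci_high[i]]
            fh.write("\t".join(_FMT % v for v in row) + "\n")


def read_profile(path: str | Path) -> FreeEnergyProfile:
    """Read a profile TSV back; lossless to ~1e-9 relative."""
    path = Path(path)
    meta: dict = {}
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            toks = line.split("\t")
            if header is None:
                header = toks
                if header[:2] != ["zeta", "G_kJmol"]:
                    raise ValueError(f"{path}:{lineno}: unexpected header {header}")
                continue
            if len(toks) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(toks)}"
                )
            rows.append([_parse_float(t, path, lineno) for t in toks])
    if header is None or not rows:
        raise ValueError(f"{path}: no profile data found")
    arr = np.array(rows)
    has_ci = "ci_low" in header
    if not has_ci:
        warnings.warn(f"{path}: no confidence-interval columns; bands absent")
    return FreeEnergyProfile(
        zeta=arr[:, 0],
        G=arr[:, 1],
        ci_low=arr[:, 2] if has_ci else None,
        ci_high=arr[:, 3] if has_ci else None,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# umbrella-window time series
# ---------------------------------------------------------------------------

def write_segment(segment: TrajectorySegment, path: str | Path):
    """One window's time series: step, time_ps, zeta, T_kin."""
    spec = segment.spec
    with open(path, "w") as fh:
        for key, val in (
            ("window_id", segment.window_id),
            ("zeta0", spec.zeta0),
            ("k", spec.k),
            ("steps", spec.steps),
            ("dt_ps", spec.dt),
            ("temperature_K", spec.temperature),
            ("friction_ps", spec.friction),
            ("seed", spec.seed),
            ("save_stride", spec.save_stride),
        ):
            fh.write(f"# {key}={val}\n")
        fh.write("step\ttime_ps\tzeta\tT_kin\n")
        for i in range(len(segment.times)):
            step = (i + 1) * spec.save_stride
            z = segment.zeta[i] if segment.zeta is not None else float("nan")
            fh.write(
                "\t".join(
                    [str(step), _FMT % segment.times[i], _FMT % z, _FMT % segment.t_kin[i]]
                )
                + "\n"
            )


def read_segment(path: str | Path) -> TrajectorySegment:
    path = Path(path)
    meta: dict = {}
    rows = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
                continue
            toks = line.split("\t")
            if header is None:
                header = toks
                continue
            rows.append([_parse_float(t, path, lineno) for t in toks])
    if not rows:
        raise ValueError(f"{path}: empty window table")
    arr = np.array(rows)
    spec = UmbrellaWindowSpec(
        zeta0=float(meta["zeta0"]),
        k=float(meta["k"]),
        steps=int(meta["steps"]),
        dt=float(meta["dt_ps"]),
        temperature=float(meta["temperature_K"]),
        friction=float(meta["friction_ps"]),
        seed=int(meta["seed"]),
        save_stride=int(meta["save_stride"]),
        window_id=int(meta["window_id"]),
    )
    return TrajectorySegment(
        window_id=spec.window_id,
        spec=spec,
        times=arr[:, 1],
        zeta=arr[:, 2],
        t_kin=arr[:, 3],
    )


def write_cec_table(path: str | Path, frames: list):
    """Batch CEC evaluation table: frame, zeta, d_eD, d_eA, epsilon_x/y/z."""
    with open(path, "w") as fh:
        fh.write("frame\tzeta\td_eD\td_eA\tepsilon_x\tepsilon_y\tepsilon_z\n")
        for i, val in enumerate(frames):
            fh.write(
                "\t".join(
                    [str(i)]
                    + [_FMT % v for v in (val.zeta, val.d_eD, val.d_eA)]
                    + [_FMT % v for v in val.epsilon]
                )
                + "\n"
            )
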