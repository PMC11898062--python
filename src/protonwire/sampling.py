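"""Langevin dynamics with umbrella biasing on the zeta coordinate.

The propagator is the BAOAB splitting of Langevin dynamics, which remains
accurate at a 1 fs time step with the strong collision frequency (25 ps^-1)
used for proton-transfer sampling at 310 K.  The engine is
potential-agnostic: any object satisfying the :class:`PotentialSurface`
contract (energy in kJ/mol, forces in kJ/mol/A, optional frozen-DOF mask)
can be sampled.  Umbrella windows apply a harmonic bias

    U_bias = 1/2 k (zeta - zeta0)^2,    k in kJ/mol per unit zeta^2,

with forces obtained from the analytic zeta gradient.  Flat-bottom
positional restraints (zero inside a tolerance region, half-harmonic
outside) confine mobile waters exactly as in QC/MM practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Protocol, Sequence

import numpy as np

from .units import KB, KJ_PER_MOL

__all__ = [
    "PotentialSurface",
    "UmbrellaWindowSpec",
    "TrajectorySegment",
    "validate_surface",
    "langevin_propagate",
    "harmonic_bias_on_zeta",
    "flat_bottom_restraint",
    "place_windows",
    "refine_windows",
    "histogram_overlap",
    "run_umbrella_sweep",
    "kinetic_temperature",
]


class PotentialSurface(Protocol):
    """Energy/force contract every sampled surface must satisfy."""

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy (kJ/mol) and per-atom forces (kJ/mol/A) at *positions*."""
        ...

    #: boolean (n_atoms, 3) mask of frozen degrees of freedom, or None
    frozen_mask: np.ndarray | None


def validate_surface(
    surface: PotentialSurface,
    positions: np.ndarray,
    h: float = 1e-5,
    tol: float = 1e-3,
    max_dof: int = 60,
) -> float:
    """Check forces = -dE/dr by central finite differences; returns max error.

    Raises ``ValueError`` if any sampled component deviates by more than
    *tol* kJ/mol/A.  Frozen DOFs are skipped.
    """
    positions = np.array(positions, dtype=float)
    _, forces = surface.energy_forces(positions)
    mask = getattr(surface, "frozen_mask", None)
    free = np.argwhere(np.ones_like(positions, dtype=bool) if mask is None else ~mask)
    if len(free) > max_dof:
        sel = np.linspace(0, len(free) - 1, max_dof).astype(int)
        free = free[sel]
    worst = 0.0
    for i, k in free:
        p = positions.copy()
        p[i, k] += h
        ep, _ = surface.energy_forces(p)
        p[i, k] -= 2 * h
        em, _ = surface.energy_forces(p)
        err = abs(-(ep - em) / (2 * h) - forces[i, k])
        worst = max(worst, err)
    if worst > tol:
        raise ValueError(
            f"surface failed force check: max |F + dE/dr| = {worst:.3e} kJ/mol/A"
        )
    return worst


@dataclass(frozen=True)
class UmbrellaWindowSpec:
    """One umbrella window: bias center/strength plus integrator settings."""

    zeta0: float
    k: float = 1000.0        # kJ/mol per unit zeta^2
    steps: int = 50000
    dt: float = 0.001        # ps (1 fs)
    temperature: float = 310.0  # K
    friction: float = 25.0   # ps^-1
    seed: int = 0
    save_stride: int = 10
    window_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.zeta0 <= 1.0):
            raise ValueError("zeta0 must lie in [0, 1]")
        if self.k <= 0 or self.dt <= 0:
            raise ValueError("k and dt must be positive")


@dataclass
class TrajectorySegment:
    """Saved time series from one umbrella window."""

    window_id: int
    spec: UmbrellaWindowSpec
    times: np.ndarray                 # ps
    zeta: np.ndarray | None
    t_kin: np.ndarray                 # K
    energies: np.ndarray | None = None  # total (potential + kinetic), kJ/mol
    positions: np.ndarray | None = None
    final_positions: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray, ndof: int) -> float:
    """Instantaneous kinetic temperature in K (velocities in A/ps)."""
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2)) / KJ_PER_MOL
    return 2.0 * ke / (ndof * KB)


def harmonic_bias_on_zeta(cec_value, zeta0: float, k: float):
    """Umbrella bias energy and per-atom forces from an evaluated CEC value.

    The CEC value must carry a zeta and its analytic gradient.  Refinement
    windows simply pass k' = 3k.
    """
    dz = cec_value.zeta - zeta0
    energy = 0.5 * k * dz * dz
    forces = -k * dz * cec_value.gradient
    return energy, forces


def flat_bottom_restraint(
    position: np.ndarray,
    center: np.ndarray,
    width: float = 2.0,
    k: float = 150.0,
):
    """Flat-bottom positional restraint on one atom.

    Zero within ``width/2`` of *center* (the restraint is *width* wide in
    diameter), half-harmonic with force constant *k* (kJ/mol/A^2) in the
    excess distance outside.  Returns (energy, force-on-atom).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    dv = np.asarray(position, float) - np.asarray(center, float)
    r = float(np.linalg.norm(dv))
    half = width / 2.0
    if r <= half:
        return 0.0, np.zeros(3)
    excess = r - half
    energy = 0.5 * k * excess * excess
    force = -k * excess * dv / r
    return energy, force


def langevin_propagate(
    masses: np.ndarray,
    positions: np.ndarray,
    surface: PotentialSurface,
    spec: UmbrellaWindowSpec,
    cv: Callable[[np.ndarray], object] | None = None,
    bias: bool = True,
    record_energy: bool = False,
    record_positions: bool = False,
) -> TrajectorySegment:
    """BAOAB Langevin trajectory of *spec.steps* steps.

    If *cv* is given it is evaluated every step (with gradient) and, when
    *bias* is true, the harmonic umbrella bias of the spec is applied.
    Frozen DOFs never move.  A fixed seed makes runs bit-reproducible.
    """
    masses = np.asarray(masses, dtype=float)
    x = np.array(positions, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(spec.seed)

    mask = getattr(surface, "frozen_mask", None)
    free = np.ones((n, 3), dtype=bool) if mask is None else ~np.asarray(mask, bool)
    ndof = int(free.sum())
    if ndof == 0:
        raise ValueError("all degrees of freedom are frozen")

    inv_m = KJ_PER_MOL / masses[:, None]          # a = F * inv_m, A/ps^2
    gamma, dt = spec.friction, spec.dt
    c1 = float(np.exp(-gamma * dt)) if gamma > 0 else 1.0
    c2 = float(np.sqrt(1.0 - c1 * c1))
    sigma_v = np.sqrt(KJ_PER_MOL * KB * spec.temperature / masses)[:, None]  # A/ps

    def total_force(xx):
        e, f = surface.energy_forces(xx)
        if not np.isfinite(e):
            raise FloatingPointError(
                f"non-finite energy ({e}) encountered; frame: {np.array2string(xx)}"
            )
        z = None
        if cv is not None:
            val = cv(xx)
            z = val
            if bias:
                be, bf = harmonic_bias_on_zeta(val, spec.zeta0, spec.k)
                e = e + be
                f = f + bf
        return e, f, z

    # thermalized start on free DOFs
    v = rng.standard_normal((n, 3)) * sigma_v
    v[~free] = 0.0
    e, f, zval = total_force(x)

    n_save = spec.steps // spec.save_stride
    times = np.empty(n_save)
    zeta = np.empty(n_save) if cv is not None else None
    t_kin = np.empty(n_save)
    energies = np.empty(n_save) if record_energy else None
    snaps = [] if record_positions else None

    half_dt = 0.5 * dt
    isave = 0
    for step in range(1, spec.steps + 1):
        a = f * inv_m
        a[~free] = 0.0
        v += half_dt * a                      # B
        x[free] += half_dt * v[free]          # A
        if gamma > 0:                         # O
            noise = rng.standard_normal((n, 3)) * sigma_v
            v[free] = c1 * v[free] + c2 * noise[free]
        x[free] += half_dt * v[free]          # A
        e, f, zval = total_force(x)
        a = f * inv_m
        a[~free] = 0.0
        v += half_dt * a                      # B
        if step % spec.save_stride == 0:
            times[isave] = step * dt
            if zeta is not None:
                zeta[isave] = zval.zeta
            t_kin[isave] = kinetic_temperature(v, masses, ndof)
            if record_energy:
                ke_kj = 0.5 * float(np.sum(masses[:, None] * v * v)) / KJ_PER_MOL
                energies[isave] = e + ke_kj
            if record_positions:
                snaps.append(x.copy())
            isave += 1

    return TrajectorySegment(
        window_id=spec.window_id,
        spec=spec,
        times=times,
        zeta=zeta,
        t_kin=t_kin,
        energies=energies,
        positions=np.array(snaps) if record_positions else None,
        final_positions=x.copy(),
    )


# ---------------------------------------------------------------------------
# window placement and refinement
# ---------------------------------------------------------------------------

def place_windows(
    zeta_range: tuple[float, float] = (0.0, 1.0),
    spacing: float = 0.1,
    k: float = 1000.0,
    steps: int = 50000,
    base_seed: int = 0,
    **kwargs,
) -> list[UmbrellaWindowSpec]:
    """Equally spaced umbrella windows over the zeta interval.

    The defaults divide [0, 1] into windows 0.1 apart (11 centers) with
    k = 1000 kJ/mol per unit zeta^2.  Per-window seeds are base_seed + index.
    """
    lo, hi = zeta_range
    n = round((hi - lo) / spacing)
    if abs(lo + n * spacing - hi) > 1e-9:
        raise ValueError("spacing must divide the zeta range")
    centers = [lo + i * spacing for i in range(n + 1)]
    return [
        UmbrellaWindowSpec(
            zeta0=c, k=k, steps=steps, seed=base_seed + i, window_id=i, **kwargs
        )
        for i, c in enumerate(centers)
    ]


def histogram_overlap(counts_a, counts_b) -> float:
    """Shared normalized area of two histograms on a common grid."""
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.sum() == 0 or b.sum() == 0:
        return 0.0
    return float(np.minimum(a / a.sum(), b / b.sum()).sum())


def refine_windows(
    specs: Sequence[UmbrellaWindowSpec],
    zeta_series: Sequence[np.ndarray],
    threshold: float = 0.10,
    bins: int = 100,
    base_seed: int | None = None,
    k_max: float | None = None,
) -> list[UmbrellaWindowSpec]:
    """Midpoint refinement windows (k' = 3k) where adjacent overlap is poor.

    Adjacent window pairs (ordered by center) whose zeta histograms share
    less than *threshold* normalized area get one inserted window at the
    midpoint with triple the force constant (capped at *k_max* when given;
    once the cap is reached the spacing keeps halving at constant k).
    Pairs closer than 0.005 in zeta are left alone - at that separation the
    coordinate itself, not window spacing, limits overlap.
    """
    order = np.argsort([s.zeta0 for s in specs])
    edges = np.linspace(0.0, 1.0, bins + 1)
    hists = [np.histogram(zeta_series[i], bins=edges)[0] for i in order]
    ordered = [specs[i] for i in order]
    added: list[UmbrellaWindowSpec] = []
    next_id = max(s.window_id for s in specs) + 1
    seed = base_seed if base_seed is not None else max(s.seed for s in specs) + 1
    for a, b, ha, hb in zip(ordered[:-1], ordered[1:], hists[:-1], hists[1:]):
        if b.zeta0 - a.zeta0 < 0.005:
            continue
        if histogram_overlap(ha, hb) < threshold:
            k_new = 3.0 * max(a.k, b.k)
            if k_max is not None:
                k_new = min(k_new, k_max)
            added.append(
                replace(
                    a,
                    zeta0=0.5 * (a.zeta0 + b.zeta0),
                    k=k_new,
                    seed=seed,
                    window_id=next_id,
                )
            )
            next_id += 1
            seed += 1
    return added


def fill_gap_windows(
    specs: Sequence[UmbrellaWindowSpec],
    zeta_series: Sequence[np.ndarray],
    k_fill: float,
    bins: int = 100,
    min_gap_bins: int = 1,
    spacing: float = 0.03,
    min_counts: float = 1.0,
) -> list[UmbrellaWindowSpec]:
    """Stiff windows centered on interior zeta stretches no window sampled.

    Windows whose centers bracket a region can both equilibrate into the
    same basin and leave the stretch between basins unvisited; pairwise
    overlap refinement never sees such a hole.  This scans the pooled
    histogram for interior runs of bins holding fewer than *min_counts*
    samples (transient crossing trails do not count as coverage) and
    plants windows (force constant *k_fill*, one per ~*spacing* of zeta)
    across each run.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    total = np.zeros(bins)
    for z in zeta_series:
        total += np.histogram(z, bins=edges)[0]
    nz = np.nonzero(total >= min_counts)[0]
    if nz.size == 0:
        return []
    lo, hi = nz[0], nz[-1]
    added: list[UmbrellaWindowSpec] = []
    next_id = max(s.window_id for s in specs) + 1
    seed = max(s.seed for s in specs) + 1
    i = lo
    while i <= hi:
        if total[i] < min_counts:
            j = i
            while j <= hi and total[j] < min_counts:
                j += 1
            if j - i >= min_gap_bins:
                za, zb = edges[i], edges[j]
                n_ins = max(1, int(round((zb - za) / spacing)))
                for c in np.linspace(za, zb, n_ins + 2)[1:-1]:
                    added.append(
                        replace(
                            specs[0], zeta0=float(np.clip(c, 0.0, 1.0)), k=k_fill,
                            seed=seed, window_id=next_id,
                        )
                    )
                    next_id += 1
                    seed += 1
            i = j
        else:
            i += 1
    return added


def run_umbrella_sweep(
    masses: np.ndarray,
    positions: np.ndarray,
    surface: PotentialSurface,
    specs: Sequence[UmbrellaWindowSpec],
    cv: Callable[[np.ndarray], object],
    sequential_start: bool = True,
    window_init: Callable[[UmbrellaWindowSpec], np.ndarray] | None = None,
) -> list[TrajectorySegment]:
    """Sample every umbrella window; returns one segment per spec.

    Windows are run in order of their centers; by default each window starts
    from the final frame of the previous one so the system is dragged along
    the wire.  When *window_init* is given it supplies the starting frame of
    each window instead (e.g. placing the excess proton at the window's own
    target zeta), which avoids hysteresis across sticky stretches of the
    coordinate.  A propagation failure stops the sweep but the segments
    sampled so far are returned with a ``failed`` marker on the list.
    """
    if len(specs) == 0:
        raise ValueError("no umbrella windows specified")
    segments: list[TrajectorySegment] = []
    order = np.argsort([s.zeta0 for s in specs])
    x = np.array(positions, dtype=float)
    failed = False
    import warnings as _warnings

    for i in order:
        spec = specs[i]
        if spec.steps == 0:
            _warnings.warn(f"window {spec.window_id}: zero-step spec skipped")
            continue
        start = window_init(spec) if window_init is not None else x
        try:
            seg = langevin_propagate(masses, start, surface, spec, cv=cv, bias=True)
        except FloatingPointError:
            failed = True
            break
        segments.append(seg)
        if sequential_start and window_init is None:
            x = seg.final_positions
    segments.sort(key=lambda s: s.spec.zeta0)
    if failed:
        for s in segments:
            s.failed_sweep = True  # type: ignore[attr-defined]
    return segments
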