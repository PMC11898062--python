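"""Synthetic proton-wire systems with exact reference free-energy profiles.

A toy wire is a linear chain of protonable heavy sites (a donor, 0-5
water-like carriers, an acceptor) at hydrogen-bonding separations, holding
one excess proton.  The proton binds each site through a soft-core radial
attraction well whose depth is the site's proton affinity: a logistic well
that is flat across the site center (the plateau represents the
hydronium-like protonated state) and decays over a narrow wall aligned
with the mCEC switching region, so the binding energy is expressed exactly
while the transfer coordinate responds (bond breaking).  The soft core is
essential in one dimension - a hard-core bond well would make the carrier
nucleus impassable.  Tuning the per-site
affinities produces the four canonical profile shapes (near-thermoneutral
"plausible", trapped intermediate, steeply uphill, steeply downhill), and a
redox-switch parameter shifts the product well to mimic electron-transfer
activation of the acceptor side.

In the default 1-D mode the excess proton is the single mobile degree of
freedom, moving on the wire axis between carrier sites of zero CEC weight
(bare acceptors, like quinone or carboxylate oxygens).  The configurational
partition function is then a one-dimensional integral and the exact profile
G(zeta) is available by dense trapezoid quadrature - the independent truth
that umbrella sampling + WHAM must reproduce.  The 3-D mode adds explicit
reference protons (waters carry two, weight 2.0; the donor hydroxyl one,
weight 1.0) and proton-proton repulsion, exercising the full vector
mCEC/gradient path without an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import KB
from .cec import CECEvaluator, MCECParams
from .fes import FreeEnergyProfile
from .topology import AtomRecord, ProtonableSite, SystemTopology
from .sampling import validate_surface

__all__ = [
    "ToyWireSpec",
    "ToyWireSystem",
    "HarmonicTestSystem",
    "build_toy_wire",
    "reference_profile_quadrature",
    "propagate_windows_1d",
    "sample_toy_profile",
    "scenario_presets",
]

#: Soft-core attraction-well geometry: well radius (A) and wall width (A).
#: Fixed so that site affinity alone tunes the thermodynamics.
WELL_RADIUS = 1.25
WELL_WIDTH = 0.08


def _well(d: np.ndarray, depth) -> np.ndarray:
    """Logistic site well: -depth inside ~WELL_RADIUS, 0 far away."""
    x = np.clip((d - WELL_RADIUS) / WELL_WIDTH, -500.0, 500.0)
    return -depth / (1.0 + np.exp(x))


def _well_ddist(d: np.ndarray, depth) -> np.ndarray:
    """dV/dd of the logistic well (nonnegative: energy rises outward)."""
    x = np.clip((d - WELL_RADIUS) / WELL_WIDTH, -500.0, 500.0)
    f = 1.0 / (1.0 + np.exp(x))
    return depth * f * (1.0 - f) / WELL_WIDTH

#: screened proton-proton repulsion strength (kJ A / mol) and softening (A)
REPULSION_K = 350.0
REPULSION_SOFT = 1.0

TETHER_K = 1000.0  # heavy-atom positional tether, kJ/mol/A^2 (3-D mode)


@dataclass(frozen=True)
class ToyWireSpec:
    """Recipe for a synthetic wire.

    ``affinities`` lists the proton-binding well depth (kJ/mol, positive)
    for donor, each water carrier, and acceptor, in wire order
    (n_waters + 2 entries).  ``redox_shift`` is an energy added to the
    acceptor-side well bottom: a negative shift deepens the product well,
    emulating electron transfer that activates the acceptor.
    """

    n_waters: int = 1
    affinities: tuple = ()
    spacing: float = 2.7  # O-O hydrogen-bond distance, A
    trap_site: int | None = None
    trap_extra: float = 0.0
    redox_shift: float = 0.0
    dimensionality: str = "1d"
    seed: int = 0
    expected_class: str | None = None

    def __post_init__(self):
        if not (0 <= self.n_waters <= 5):
            raise ValueError("n_waters must be in 0..5")
        if self.dimensionality not in ("1d", "3d"):
            raise ValueError("dimensionality must be '1d' or '3d'")
        affs = self.affinities or (100.0,) * (self.n_waters + 2)
        if len(affs) != self.n_waters + 2:
            raise ValueError("need n_waters + 2 affinities (donor, waters..., acceptor)")
        if not np.all(np.isfinite(affs)):
            raise ValueError("affinities must be finite")
        object.__setattr__(self, "affinities", tuple(float(a) for a in affs))

    @property
    def n_sites(self) -> int:
        return self.n_waters + 2

    def site_depths(self) -> np.ndarray:
        """Effective well depths including trap and redox adjustments."""
        depths = np.array(self.affinities, dtype=float)
        if self.trap_site is not None:
            depths[self.trap_site] += self.trap_extra
        depths[-1] -= self.redox_shift  # negative shift deepens the product well
        return depths


class ToyWireSurface:
    """Potential surface of a toy wire (kJ/mol, kJ/mol/A)."""

    def __init__(
        self,
        proton_idx: np.ndarray,
        heavy_idx: np.ndarray,
        depths: np.ndarray,
        tether_ref: np.ndarray | None,
        confine_center: np.ndarray,
        confine_half: float,
        frozen_mask: np.ndarray | None,
        repulsion: bool,
    ):
        self.proton_idx = proton_idx
        self.heavy_idx = heavy_idx
        self.depths = depths
        self.tether_ref = tether_ref
        self.confine_center = confine_center
        self.confine_half = confine_half
        self.confine_k = 150.0
        self.frozen_mask = frozen_mask
        self.repulsion = repulsion

    def energy_forces(self, positions: np.ndarray):
        pos = np.asarray(positions, dtype=float)
        F = np.zeros_like(pos)
        rp = pos[self.proton_idx]  # (nP, 3)
        rh = pos[self.heavy_idx]   # (nS, 3)

        diff = rp[:, None, :] - rh[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        d = np.maximum(d, 1e-9)
        # logistic well and its radial derivative share one tanh evaluation
        f = 0.5 * (1.0 - np.tanh((0.5 / WELL_WIDTH) * (d - WELL_RADIUS)))
        E = -float(np.sum(self.depths[None, :] * f))
        dVdd = self.depths[None, :] * f * (1.0 - f) / WELL_WIDTH
        fp = (-dVdd / d)[:, :, None] * diff     # force on protons
        F[self.proton_idx] += fp.sum(axis=1)
        F[self.heavy_idx] -= fp.sum(axis=0)

        if self.tether_ref is not None:
            dv = rh - self.tether_ref
            E += 0.5 * TETHER_K * float(np.sum(dv * dv))
            F[self.heavy_idx] += -TETHER_K * dv

        if self.repulsion and len(self.proton_idx) > 1:
            n = len(self.proton_idx)
            for i in range(n):
                for j in range(i + 1, n):
                    dv = rp[i] - rp[j]
                    r2 = float(np.dot(dv, dv)) + REPULSION_SOFT**2
                    r = np.sqrt(r2)
                    E += REPULSION_K / r
                    f = REPULSION_K / (r2 * r) * dv
                    F[self.proton_idx[i]] += f
                    F[self.proton_idx[j]] -= f

        # flat-bottom confinement keeps protons in the wire region
        dv = rp - self.confine_center
        r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
        outside = r > self.confine_half
        if np.any(outside):
            excess = r[outside] - self.confine_half
            E += 0.5 * self.confine_k * float(np.sum(excess * excess))
            fdir = dv[outside] / r[outside, None]
            F[self.proton_idx[outside]] += -self.confine_k * excess[:, None] * fdir
        return E, F


@dataclass
class ToyWireSystem:
    """A built toy wire: topology + potential surface (+ exact 1-D oracle)."""

    spec: ToyWireSpec
    topology: SystemTopology
    surface: ToyWireSurface
    heavy_x: np.ndarray  # wire-axis coordinates of the heavy sites

    def initial_positions(self) -> np.ndarray:
        return self.topology.positions()

    def masses(self) -> np.ndarray:
        return self.topology.masses()

    def cec_evaluator(self, params: MCECParams = MCECParams()) -> CECEvaluator:
        return CECEvaluator(self.topology, params)

    def zeta_of_x(self, x: np.ndarray) -> np.ndarray:
        """zeta for the excess proton at on-axis positions x (1-D mode)."""
        if self.spec.dimensionality != "1d":
            raise ValueError("zeta_of_x is defined for the 1-D mode only")
        x = np.atleast_1d(np.asarray(x, float))
        params = MCECParams()
        hx = self.heavy_x
        dd = np.abs(x[:, None] - hx[None, :])
        xc = np.clip((dd - params.r_sw) / params.d_sw, -500, 500)
        f = 1.0 / (1.0 + np.exp(xc))
        eps_x = x + np.sum(f * (hx[None, :] - x[:, None]), axis=1)
        dD = np.abs(eps_x - hx[0])
        dA = np.abs(eps_x - hx[-1])
        return dD / (dD + dA)

    def energy_of_x(self, x: np.ndarray) -> np.ndarray:
        """Potential energy with the excess proton on-axis at x (1-D mode)."""
        if self.spec.dimensionality != "1d":
            raise ValueError("energy_of_x is defined for the 1-D mode only")
        x = np.atleast_1d(np.asarray(x, float))
        depths = self.spec.site_depths()
        d = np.maximum(np.abs(x[:, None] - self.heavy_x[None, :]), 1e-9)
        E = np.sum(_well(d, depths[None, :]), axis=1)
        # same flat-bottom confinement as the dynamical surface
        r = np.abs(x - self.surface.confine_center[0])
        excess = np.maximum(r - self.surface.confine_half, 0.0)
        return E + 0.5 * self.surface.confine_k * excess * excess

    def position_at_zeta(self, zeta0: float, dx: float = 1e-3) -> np.ndarray:
        """Frame with the excess proton placed where zeta is closest to zeta0.

        Scans the donor->acceptor branch of the wire axis; used to seed each
        umbrella window at its own target so no window has to diffuse across
        the sticky plateaus of the coordinate (1-D mode only).
        """
        if self.spec.dimensionality != "1d":
            raise ValueError("position_at_zeta is defined for the 1-D mode only")
        xs = np.arange(self.heavy_x[0], self.heavy_x[-1] + dx, dx)
        z = self.zeta_of_x(xs)
        xbest = xs[int(np.argmin(np.abs(z - zeta0)))]
        pos = self.topology.positions()
        pos[-1] = [xbest, 0.0, 0.0]
        return pos

    def window_init(self, spec) -> np.ndarray:
        return self.position_at_zeta(spec.zeta0)

    def reference_profile(self, **kwargs) -> FreeEnergyProfile:
        return reference_profile_quadrature(self, **kwargs)


def build_toy_wire(spec: ToyWireSpec) -> ToyWireSystem:
    """Construct the toy wire system described by *spec*.

    Heavy sites are placed on the x axis at the hydrogen-bonding spacing;
    the excess proton starts in the donor well.  The assembled surface is
    verified against finite differences before being returned.
    """
    ns = spec.n_sites
    hx = spec.spacing * np.arange(ns)
    if spec.spacing < 1.0:
        raise ValueError("sites overlap: spacing must exceed 1 A")

    one_d = spec.dimensionality == "1d"
    atoms: list[AtomRecord] = []
    sites: list[ProtonableSite] = []
    roles = ["donor"] + ["water"] * spec.n_waters + ["acceptor"]
    names = ["DON"] + [f"W{i+1}" for i in range(spec.n_waters)] + ["ACC"]

    for s in range(ns):
        atoms.append(AtomRecord(s, "O", np.array([hx[s], 0.0, 0.0]), name=names[s]))
    next_id = ns
    proton_ids: list[int] = []

    if one_d:
        # single explicit excess proton; carriers are bare (w = 0) sites
        weights = [0.0] * ns
        refcounts = [0] * ns
        atoms.append(
            AtomRecord(next_id, "H", np.array([WELL_RADIUS, 0.0, 0.0]),
                       name="HX", is_mobile_proton=True)
        )
        proton_ids.append(next_id)
        next_id += 1
    else:
        # explicit reference protons: donor hydroxyl-like (1 H, w = 1),
        # waters (2 H, w = 2), acceptor bare (w = 0); plus the excess proton
        weights = [1.0] + [2.0] * spec.n_waters + [0.0]
        refcounts = [1] + [2] * spec.n_waters + [0]
        rng = np.random.default_rng(spec.seed)

        def add_h(base, direction):
            nonlocal next_id
            p = base + WELL_RADIUS * direction + 0.02 * rng.standard_normal(3)
            atoms.append(AtomRecord(next_id, "H", p, name=f"H{next_id}",
                                    is_mobile_proton=True))
            proton_ids.append(next_id)
            next_id += 1

        add_h(atoms[0].position, np.array([-1.0, 0.0, 0.0]))  # donor reference H
        for wsite in range(1, 1 + spec.n_waters):
            for ang in (2.0 * np.pi / 3.0, -2.0 * np.pi / 3.0):
                add_h(atoms[wsite].position,
                      np.array([np.cos(ang), np.sin(ang), 0.0]))
        add_h(atoms[0].position, np.array([1.0, 0.0, 0.0]))  # excess proton

    for s in range(ns):
        sites.append(ProtonableSite(s, names[s], [s], weights[s], refcounts[s], roles[s]))
        atoms[s].site_id = s

    topo = SystemTopology(atoms, sites, donor_atom_id=0, acceptor_atom_id=ns - 1)

    n_atoms = len(atoms)
    frozen = np.zeros((n_atoms, 3), dtype=bool)
    if one_d:
        frozen[:ns, :] = True            # heavy lattice fixed
        frozen[ns:, 1:] = True           # proton moves on the axis only
        tether_ref = None
    else:
        tether_ref = np.array([a.position for a in atoms[:ns]])
        frozen = None

    surface = ToyWireSurface(
        proton_idx=np.array(proton_ids, dtype=int),
        heavy_idx=np.arange(ns, dtype=int),
        depths=spec.site_depths(),
        tether_ref=tether_ref,
        confine_center=np.array([0.5 * (hx[0] + hx[-1]), 0.0, 0.0]),
        confine_half=0.5 * (hx[-1] - hx[0]) + 1.8,
        frozen_mask=frozen,
        repulsion=not one_d,
    )
    system = ToyWireSystem(spec, topo, surface, hx)
    validate_surface(surface, topo.positions(), tol=5e-3)
    return system


def reference_profile_quadrature(
    system: ToyWireSystem,
    bin_width: float = 0.01,
    temperature: float = 310.0,
    dx: float = 2e-5,
    pad: float = 2.5,
) -> FreeEnergyProfile:
    """Exact G(zeta) of a 1-D toy wire by dense trapezoid quadrature.

    The Boltzmann weight of the on-axis proton coordinate is accumulated
    into zeta bins:  G(bin) = -kT ln sum_{x in bin} exp(-U(x)/kT) dx,
    anchored at the sampled minimum.  Only defined in 1-D mode.
    """
    if system.spec.dimensionality != "1d":
        raise ValueError("quadrature oracle is unsupported in 3-D mode")
    hx = system.heavy_x
    x = np.arange(hx[0] - pad, hx[-1] + pad + dx, dx)
    U = system.energy_of_x(x)
    z = system.zeta_of_x(x)
    beta = 1.0 / (KB * temperature)
    w = np.exp(-beta * (U - U.min()))

    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    mass = np.bincount(idx, weights=w, minlength=n_bins) * dx
    with np.errstate(divide="ignore"):
        G = np.where(mass > 0, -np.log(np.where(mass > 0, mass, 1.0)) / beta, np.nan)
    G = G - np.nanmin(G)
    return FreeEnergyProfile(
        zeta=0.5 * (edges[:-1] + edges[1:]),
        G=G,
        metadata={"method": "quadrature", "temperature_K": temperature, "dx": dx},
    )


class HarmonicTestSystem:
    """Independent 3-D harmonic oscillators: the thermostat test bench.

    Each particle is tethered to its own center with force constant *k*
    (kJ/mol/A^2).  Soft springs (default 100) keep the oscillation period
    two orders above the 1 fs step, so kinetic-temperature checks probe the
    thermostat, not integrator artifacts.
    """

    def __init__(self, n_particles: int = 10, k: float = 100.0, mass: float = 12.011,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.centers = 5.0 * rng.standard_normal((n_particles, 3))
        self.k = float(k)
        self.mass = float(mass)
        self.frozen_mask = None

    def energy_forces(self, positions: np.ndarray):
        dv = np.asarray(positions, float) - self.centers
        return 0.5 * self.k * float(np.sum(dv * dv)), -self.k * dv

    def initial_positions(self) -> np.ndarray:
        return self.centers.copy()

    def masses(self) -> np.ndarray:
        return np.full(len(self.centers), self.mass)


def _zeta_grad_of_x(system: ToyWireSystem, x: np.ndarray, params: MCECParams):
    """Vectorized (zeta, dzeta/dx) for the on-axis excess proton (1-D mode).

    Closed-form reduction of the mCEC chain rule to the single proton
    coordinate; agrees with the generic per-atom evaluator to rounding.
    """
    hx = system.heavy_x
    dd = x[:, None] - hx[None, :]
    sgn = np.sign(dd)
    ad = np.abs(dd)
    f = 0.5 * (1.0 - np.tanh((0.5 / params.d_sw) * (ad - params.r_sw)))
    eps = x + np.sum(f * (-dd), axis=1)
    fp = -f * (1.0 - f) / params.d_sw
    deps = 1.0 + np.sum(fp * sgn * (-dd) - f, axis=1)
    vD = eps - hx[0]
    vA = eps - hx[-1]
    dD = np.abs(vD)
    dA = np.abs(vA)
    S = dD + dA
    zeta = dD / S
    dzeta_deps = (np.sign(vD) * dA - np.sign(vA) * dD) / (S * S)
    return zeta, dzeta_deps * deps


def _du_dx(system: ToyWireSystem, x: np.ndarray) -> np.ndarray:
    """dU/dx of the 1-D toy surface (wells + flat-bottom confinement)."""
    hx = system.heavy_x
    depths = system.spec.site_depths()
    dd = x[:, None] - hx[None, :]
    ad = np.maximum(np.abs(dd), 1e-9)
    f = 0.5 * (1.0 - np.tanh((0.5 / WELL_WIDTH) * (ad - WELL_RADIUS)))
    dVdd = depths[None, :] * f * (1.0 - f) / WELL_WIDTH
    du = np.sum(dVdd * np.sign(dd), axis=1)
    r = x - system.surface.confine_center[0]
    excess = np.sign(r) * np.maximum(np.abs(r) - system.surface.confine_half, 0.0)
    return du + system.surface.confine_k * excess


def propagate_windows_1d(
    system: ToyWireSystem,
    specs,
    params: MCECParams = MCECParams(),
):
    """All umbrella windows of a 1-D toy wire propagated as one batch.

    The only mobile degree of freedom per window is the on-axis proton
    coordinate, so the whole window ladder advances in lockstep with
    vectorized energy, zeta and bias evaluations.  Each window consumes an
    independent noise stream from its own seed, so its trajectory is
    bit-reproducible regardless of which other windows share the batch.
    Returns segments identical in layout to :func:`langevin_propagate`.
    """
    from .sampling import TrajectorySegment
    from .units import KB, KJ_PER_MOL

    if system.spec.dimensionality != "1d":
        raise ValueError("batched propagation requires a 1-D toy wire")
    specs = list(specs)
    if not specs:
        return []
    steps = {s.steps for s in specs}
    dt = {s.dt for s in specs}
    temp = {s.temperature for s in specs}
    gam = {s.friction for s in specs}
    stride = {s.save_stride for s in specs}
    if len(steps) > 1 or len(dt) > 1 or len(temp) > 1 or len(gam) > 1 or len(stride) > 1:
        raise ValueError("batched windows must share steps/dt/temperature/friction/stride")
    steps, dt, temp, gamma, stride = (
        steps.pop(), dt.pop(), temp.pop(), gam.pop(), stride.pop()
    )

    nw = len(specs)
    m = 1.008  # the mobile proton
    z0 = np.array([s.zeta0 for s in specs])
    kk = np.array([s.k for s in specs])
    x = np.array([system.position_at_zeta(s.zeta0)[-1, 0] for s in specs])

    c1 = float(np.exp(-gamma * dt)) if gamma > 0 else 1.0
    c2 = float(np.sqrt(1.0 - c1 * c1))
    sigma_v = float(np.sqrt(KJ_PER_MOL * KB * temp / m))
    inv_m = KJ_PER_MOL / m

    # independent, per-window noise streams (1 initial + steps O-draws each)
    noise = np.empty((nw, steps + 1))
    for i, s in enumerate(specs):
        noise[i] = np.random.default_rng(s.seed).standard_normal(steps + 1)
    v = sigma_v * noise[:, 0]

    def force(xx):
        zeta, dzdx = _zeta_grad_of_x(system, xx, params)
        f = -_du_dx(system, xx) - kk * (zeta - z0) * dzdx
        return f, zeta

    f, zeta = force(x)
    n_save = steps // stride
    half_dt = 0.5 * dt
    zrec = np.empty((nw, n_save))
    trec = np.empty((nw, n_save))
    times = dt * stride * np.arange(1, n_save + 1)
    isave = 0
    for step in range(1, steps + 1):
        v += half_dt * inv_m * f
        x += half_dt * v
        if gamma > 0:
            v = c1 * v + (c2 * sigma_v) * noise[:, step]
        x += half_dt * v
        f, zeta = force(x)
        v += half_dt * inv_m * f
        if step % stride == 0:
            zrec[:, isave] = zeta
            trec[:, isave] = m * v * v / (KJ_PER_MOL * KB)
            isave += 1

    segments = []
    for i, s in enumerate(specs):
        final = system.topology.positions()
        final[-1] = [x[i], 0.0, 0.0]
        segments.append(
            TrajectorySegment(
                window_id=s.window_id, spec=s, times=times.copy(),
                zeta=zrec[i].copy(), t_kin=trec[i].copy(), final_positions=final,
            )
        )
    return segments


def sample_toy_profile(
    system: ToyWireSystem,
    steps_per_window: int = 50000,
    base_seed: int = 0,
    k: float = 1000.0,
    spacing: float = 0.1,
    max_refine: int = 4,
    overlap_threshold: float = 0.10,
    temperature: float = 310.0,
    equilibration: float = 0.2,
):
    """Umbrella-sample a toy wire with the standard window protocol.

    Places equally spaced windows (0.1 apart, k = 1000 kJ/mol per unit
    zeta^2), seeds each window at its own target zeta, then runs up to
    *max_refine* rounds of refinement: midpoint windows with k' = 3k
    (escalating, capped at 9k) wherever adjacent windows share less than
    *overlap_threshold* normalized histogram area, plus stiff gap-filling
    windows across any interior zeta stretch left unsampled.  Refinement
    decisions are taken on the post-equilibration part of each window -
    the same samples WHAM will see.  Returns the trajectory segments.
    """
    from .sampling import (
        fill_gap_windows, place_windows, refine_windows, run_umbrella_sweep,
    )

    def stabilize(spec):
        """Shrink dt for stiff windows so the biased oscillation stays
        resolved (period >= ~8 steps); total window time is preserved."""
        if spec.k <= 3000.0:
            return spec
        fac = max(np.sqrt(3000.0 / spec.k), 0.2)
        dt = 0.001 * fac
        return replace(spec, dt=dt, steps=int(round(spec.steps * spec.dt / dt)))

    if system.spec.dimensionality == "1d":

        def runner(sp):
            groups: dict = {}
            for s in sp:
                groups.setdefault((s.steps, s.dt), []).append(s)
            out = []
            for grp in groups.values():
                out.extend(propagate_windows_1d(system, grp))
            return out

    else:
        masses = system.masses()
        ev = system.cec_evaluator()
        cv = lambda x: ev.evaluate(x, gradient=True)  # noqa: E731

        def runner(sp):
            return run_umbrella_sweep(
                masses, system.initial_positions(), system.surface, sp, cv
            )

    specs = place_windows(
        spacing=spacing, k=k, steps=steps_per_window,
        base_seed=base_seed, temperature=temperature,
    )
    segments = runner(specs)
    for rnd in range(max_refine):
        all_specs = [s.spec for s in segments]
        kept = [s.zeta[int(len(s.zeta) * equilibration):] for s in segments]
        added = refine_windows(
            all_specs, kept, threshold=overlap_threshold, k_max=9.0 * k,
        )
        # escalate gap-filling stiffness: free-energy walls steeper than
        # k * sigma_zeta shed soft windows, so each round triples k again
        k_fill = min(9.0 * k * 3.0**rnd, 27.0 * k)
        have = {(round(s.zeta0, 4), s.k) for s in all_specs} | {
            (round(s.zeta0, 4), s.k) for s in added
        }
        for g in fill_gap_windows(all_specs, kept, k_fill=k_fill, min_counts=5.0):
            if (round(g.zeta0, 4), g.k) not in have:
                added.append(g)
                have.add((round(g.zeta0, 4), g.k))
        if not added:
            break
        # renumber to keep ids/seeds unique across both refinement sources
        base_id = max(s.window_id for s in all_specs) + 1
        base_seed_next = max(s.spec.seed for s in segments) + 1
        added = [
            stabilize(replace(a, window_id=base_id + i, seed=base_seed_next + i))
            for i, a in enumerate(added)
        ]
        segments = sorted(segments + runner(added), key=lambda s: s.spec.zeta0)
    return segments


def scenario_presets() -> dict[str, ToyWireSpec]:
    """Named toy-wire scenarios emulating the four canonical profile shapes.

    Affinities are scenario templates tuned to the magnitudes typical of
    quinol-oxidation proton transfers (barriers of a few tens of kJ/mol,
    traps ~50 kJ/mol deep, uphill walls above 100 kJ/mol); each preset
    stores its expected feasibility class.
    """
    return {
        # forward ~36, reverse ~30, dG_R ~ +6 kJ/mol: near-thermoneutral
        "plausible": ToyWireSpec(
            n_waters=1,
            affinities=(38.0, 22.0, 32.0),
            expected_class="plausible",
        ),
        # mid-wire hydronium-like minimum ~55 kJ/mol below both flanking maxima
        "trapped": ToyWireSpec(
            n_waters=1,
            affinities=(70.0, 45.0, 62.0),
            trap_site=1,
            trap_extra=50.0,
            expected_class="trapped_intermediate",
        ),
        # steep ascent with dG_R > +100 kJ/mol
        "uphill": ToyWireSpec(
            n_waters=1,
            affinities=(170.0, 65.0, 45.0),
            expected_class="infeasible_uphill",
        ),
        # redox switch deepens the product well: dG_R < -70 kJ/mol
        "downhill": ToyWireSpec(
            n_waters=1,
            affinities=(45.0, 30.0, 38.0),
            redox_shift=-90.0,
            expected_class="dissipative_downhill",
        ),
    }
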