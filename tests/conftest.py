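import numpy as np
import pytest

from protonwire import (
    AtomRecord,
    ProtonableSite,
    SystemTopology,
    build_toy_wire,
    scenario_presets,
)


def make_topology(atoms_spec, sites_spec, donor, acceptor):
    """Compact topology builder: atoms as (element, xyz, charge, name), sites
    as (name, heavy_ids, weight, nref, role)."""
    atoms = []
    for i, (el, xyz, q, name) in enumerate(atoms_spec):
        atoms.append(AtomRecord(i, el, np.array(xyz, float), q, name))
    sites = []
    for j, (name, ids, w, nref, role) in enumerate(sites_spec):
        sites.append(ProtonableSite(j, name, list(ids), w, nref, role))
        for aid in ids:
            atoms[aid].site_id = j
    topo = SystemTopology(atoms, sites, donor, acceptor)
    return topo


@pytest.fixture
def hydronium():
    """H3O+ with idealized geometry; single water-like site (w = 2)."""
    d = 0.98
    hs = [
        d * np.array([np.cos(a), np.sin(a), 0.1]) / np.linalg.norm([np.cos(a), np.sin(a), 0.1])
        for a in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
    ]
    atoms = [("O", [0, 0, 0], -0.834, "O")] + [
        ("H", h, 0.611, f"H{i+1}") for i, h in enumerate(hs)
    ]
    topo = make_topology(
        atoms,
        [("water", [0], 2.0, 2, "water")],
        donor=0,
        acceptor=0,
    )
    for a in topo.atoms[1:]:
        a.is_mobile_proton = True
    return topo


@pytest.fixture
def water_pair():
    """Two waters, O-O 2.8 A, one H-bond donated left-to-right."""
    atoms = [
        ("O", [0.0, 0.0, 0.0], 0.0, "O1"),
        ("H", [0.97, 0.0, 0.0], 0.0, "H11"),
        ("H", [-0.3, 0.92, 0.0], 0.0, "H12"),
        ("O", [2.8, 0.0, 0.0], 0.0, "O2"),
        ("H", [3.4, 0.8, 0.0], 0.0, "H21"),
        ("H", [3.4, -0.8, 0.0], 0.0, "H22"),
    ]
    topo = make_topology(
        atoms,
        [("w1", [0], 2.0, 2, "water"), ("w2", [3], 2.0, 2, "water")],
        donor=0,
        acceptor=3,
    )
    for a in topo.atoms:
        if a.element == "H":
            a.is_mobile_proton = True
    return topo


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def plausible_system(presets):
    return build_toy_wire(presets["plausible"])


@pytest.fixture(scope="session")
def trapped_system(presets):
    return build_toy_wire(presets["trapped"])


def random_wire_topology(rng, n_sites=None, n_protons=None):
    """Random 'wire' for gradient testing: arbitrary weights, several mobile
    protons, sites scattered around a line with jitter."""
    n_sites = n_sites or rng.integers(3, 8)
    n_protons = n_protons or rng.integers(1, 5)
    atoms = []
    sites = []
    for s in range(n_sites):
        pos = np.array([2.5 * s, 0.0, 0.0]) + 0.4 * rng.standard_normal(3)
        atoms.append((("O" if s % 2 == 0 else "N"), pos, 0.0, f"X{s}"))
    for p in range(n_protons):
        base = rng.integers(0, n_sites)
        pos = np.array([2.5 * base, 0.0, 0.0]) + np.array([1.0, 0, 0]) + 0.5 * rng.standard_normal(3)
        atoms.append(("H", pos, 0.0, f"H{p}"))
    weights = rng.uniform(0.0, 2.0, n_sites)
    sites = [(f"X{s}", [s], float(weights[s]), int(round(weights[s])), "relay") for s in range(n_sites)]
    topo = make_topology(atoms, sites, donor=0, acceptor=n_sites - 1)
    for a in topo.atoms[n_sites:]:
        a.is_mobile_proton = True
    return topo
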