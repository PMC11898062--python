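"""System topology: atoms, protonable sites, CEC weights and redox states.

A :class:`SystemTopology` is the static description of a proton-wire system:
atom records (element, position, partial charge), the protonable sites that
participate in the center-of-excess-charge coordinate, the designated donor
and acceptor atoms, and the redox state of the surrounding cofactors.

Weights follow the convention that each protonable heavy atom carries a
weight equal to the number of protons bound to it in its reference
(unprotonated-excess) state: a water oxygen holds two protons (w = 2.0), a
tyrosine hydroxyl one (w = 1.0), a histidine ring nitrogen on average half a
proton (w = 0.5), while carboxylate, heme-propionate and quinone oxygens are
bare acceptors (w = 0.0).  With a single excess proton this makes the sum of
weights equal the mobile-proton count minus one, which is what renders the
CEC point translationally equivariant.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .units import mass_of

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ProtonableSite",
    "RedoxState",
    "SystemTopology",
    "Q_RED",
    "Q_SEMI",
    "Q_OXI",
    "load_structure",
    "write_structure",
    "apply_redox_shift",
    "total_charge",
]

#: Default CEC weight per (residue class, element) pair.
DEFAULT_WEIGHTS = {
    ("TYR", "O"): 1.0,
    ("HIS", "N"): 0.5,
    ("HSD", "N"): 0.5,
    ("HSE", "N"): 0.5,
    ("ASP", "O"): 0.0,
    ("GLU", "O"): 0.0,
    ("HEM", "O"): 0.0,  # heme propionate oxygens
    ("HOH", "O"): 2.0,
    ("WAT", "O"): 2.0,
    ("TIP3", "O"): 2.0,
    ("SOL", "O"): 2.0,
    ("UQ", "O"): 0.0,  # (ubi)quinone oxygens
    ("Q", "O"): 0.0,
    ("QUI", "O"): 0.0,
}

#: Default reference proton count per residue class (protons bound to the
#: site in the state with no excess charge).
DEFAULT_REFERENCE_PROTONS = {
    "TYR": 1,
    "HIS": 1,
    "HSD": 1,
    "HSE": 1,
    "ASP": 0,
    "GLU": 0,
    "HEM": 0,
    "HOH": 2,
    "WAT": 2,
    "TIP3": 2,
    "SOL": 2,
    "UQ": 0,
    "Q": 0,
    "QUI": 0,
}

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "W"}

#: Covalent O/N-H bond cutoff used to pick up mobile protons at load time, A.
BOND_CUTOFF = 1.25


@dataclass
class AtomRecord:
    """One atom: identity, position (A) and MM-like partial charge (|e|)."""

    atom_id: int
    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    name: str = ""
    resname: str = ""
    resid: int = 0
    site_id: int | None = None
    is_mobile_proton: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.atom_id}: element symbol is empty")

    @property
    def mass(self) -> float:
        return mass_of(self.element)


@dataclass
class ProtonableSite:
    """A protonable group contributing weighted heavy atoms to the CEC."""

    site_id: int
    name: str
    heavy_atom_ids: list[int]
    weight_w: float
    reference_proton_count: int
    role: str = "relay"  # donor | acceptor | relay | water

    def __post_init__(self):
        if self.weight_w < 0:
            raise ValueError(f"site {self.name}: weight must be nonnegative")
        if self.role not in ("donor", "acceptor", "relay", "water"):
            raise ValueError(f"site {self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class RedoxState:
    """Cofactor redox state encoded as named-atom partial-charge shifts."""

    label: str
    charge_shifts: dict = field(default_factory=dict)

    def total_shift(self) -> float:
        return float(sum(self.charge_shifts.values()))


#: Fully reduced quinol: no electron has left the substrate, no shifts.
Q_RED = RedoxState("Q_red", {})

#: Semiquinol: one electron transferred to the FeS center (Cys-bound FE2
#: reduced by -0.50 |e|, each inorganic sulfide by -0.25 |e|).
Q_SEMI = RedoxState("Q_semi", {"FE2": -0.50, "S1": -0.25, "S2": -0.25})

#: Fully oxidized quinone: both the FeS center and heme b_L reduced (heme FE
#: by -0.60 |e| and each porphyrin nitrogen by -0.10 |e| on top of Q_semi).
Q_OXI = RedoxState(
    "Q_oxi",
    {
        "FE2": -0.50,
        "S1": -0.25,
        "S2": -0.25,
        "FE": -0.60,
        "NA": -0.10,
        "NB": -0.10,
        "NC": -0.10,
        "ND": -0.10,
    },
)

REDOX_STATES = {s.label: s for s in (Q_RED, Q_SEMI, Q_OXI)}


@dataclass
class SystemTopology:
    atoms: list[AtomRecord]
    sites: list[ProtonableSite]
    donor_atom_id: int
    acceptor_atom_id: int
    redox_state: RedoxState = Q_RED

    def __post_init__(self):
        ids = {a.atom_id for a in self.atoms}
        for aid, what in ((self.donor_atom_id, "donor"), (self.acceptor_atom_id, "acceptor")):
            if aid not in ids:
                raise ValueError(f"{what} atom id {aid} not present in topology")
        site_atoms = [aid for s in self.sites for aid in s.heavy_atom_ids]
        if len(site_atoms) != len(set(site_atoms)):
            raise ValueError("an atom is assigned to more than one protonable site")
        self._index = {a.atom_id: i for i, a in enumerate(self.atoms)}

    # -- array views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def index_of(self, atom_id: int) -> int:
        return self._index[atom_id]

    def atom(self, atom_id: int) -> AtomRecord:
        return self.atoms[self._index[atom_id]]

    def site(self, site_id: int) -> ProtonableSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site with id {site_id}")

    def site_by_name(self, name: str) -> ProtonableSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(f"no site named {name!r}")

    def mobile_proton_ids(self) -> list[int]:
        return [a.atom_id for a in self.atoms if a.is_mobile_proton]

    def heavy_atom_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(atom indices, weights) of all protonable-site heavy atoms."""
        idx, w = [], []
        for s in self.sites:
            for aid in s.heavy_atom_ids:
                idx.append(self.index_of(aid))
                w.append(s.weight_w)
        return np.array(idx, dtype=int), np.array(w, dtype=float)

    def copy(self) -> "SystemTopology":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# structure I/O (MDAnalysis handles the actual PDB/XYZ formats)
# ---------------------------------------------------------------------------

def _read_coordinates(path: str | Path):
    """Read a PDB or XYZ file into (names, elements, resnames, resids, xyz)."""
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        ag = u.atoms
        names = [str(n) for n in ag.names]
        try:
            elements = [str(e) for e in ag.elements]
        except Exception:
            from MDAnalysis.topology.guessers import guess_types

            elements = [str(e) for e in guess_types(ag.names)]
        try:
            resnames = [str(a.resname) for a in ag]
        except Exception:
            resnames = [""] * len(ag)
        try:
            resids = [int(a.resid) for a in ag]
        except Exception:
            resids = [0] * len(ag)
        xyz = np.array(ag.positions, dtype=float)
    return names, elements, resnames, resids, xyz


def write_structure(topology: SystemTopology, path: str | Path) -> None:
    """Write topology coordinates to PDB or XYZ (by file extension)."""
    import MDAnalysis as mda

    path = Path(path)
    n = topology.n_atoms
    keys = []
    resindex = []
    for a in topology.atoms:
        key = (a.resname or "UNK", a.resid)
        if key not in keys:
            keys.append(key)
        resindex.append(keys.index(key))
    u = mda.Universe.empty(
        n, n_residues=len(keys), atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", [a.name or a.element for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resnames", [k[0] for k in keys])
    u.add_TopologyAttr("resids", [k[1] if k[1] else 1 for k in keys])
    u.atoms.positions = topology.positions()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _match(name, resname, resid, sel: dict) -> bool:
    if "name" in sel and name != sel["name"]:
        return False
    if "names" in sel and name not in sel["names"]:
        return False
    if "resname" in sel and resname != sel["resname"]:
        return False
    if "resid" in sel and resid != int(sel["resid"]):
        return False
    if "element" in sel and name.upper()[:1] != sel["element"].upper()[:1]:
        return False
    return bool(sel)  # empty selector matches nothing


def _resolve_selector(atoms: list[AtomRecord], sel) -> list[int]:
    """Resolve a site-spec atom selector to a list of atom ids."""
    if isinstance(sel, int):
        return [sel]
    if isinstance(sel, list):
        out = []
        for s in sel:
            out.extend(_resolve_selector(atoms, s))
        return out
    matched = [a.atom_id for a in atoms if _match(a.name, a.resname, a.resid, sel)]
    return matched


def default_weight(resname: str, element: str) -> float | None:
    return DEFAULT_WEIGHTS.get((resname.upper(), element.upper()))


def load_structure(path: str | Path, site_spec: dict | str | Path) -> SystemTopology:
    """Build a :class:`SystemTopology` from a PDB/XYZ file and a site spec.

    The site spec (dict, or path to a YAML file) names the donor and acceptor
    atoms, lists the protonable sites with their heavy-atom selections, and
    may override per-site weights, reference proton counts and per-atom
    partial charges::

        donor: {name: O1}
        acceptor: {name: NE2, resname: HIS, resid: 152}
        sites:
          - {name: Y147, role: relay, select: {resname: TYR, resid: 147, name: OH}}
          - {name: w3,   role: water, select: {resname: HOH, resid: 3, name: O}}
        charges: {O1: -0.5}
        redox_state: Q_red

    Default weights are applied by residue type; unknown residues get w = 0
    with a logged warning.  Hydrogens within 1.25 A of a site heavy atom are
    marked as mobile protons.
    """
    if isinstance(site_spec, (str, Path)):
        with open(site_spec) as fh:
            site_spec = yaml.safe_load(fh)
    site_spec = dict(site_spec or {})

    names, elements, resnames, resids, xyz = _read_coordinates(path)
    atoms = [
        AtomRecord(i, elements[i], xyz[i], 0.0, names[i], resnames[i], resids[i])
        for i in range(len(names))
    ]

    # per-atom charges, keyed by atom name or serial
    for key, q in (site_spec.get("charges") or {}).items():
        hit = [a for a in atoms if a.name == str(key) or a.atom_id == key]
        if not hit:
            raise ValueError(f"charge entry {key!r}: no matching atom")
        for a in hit:
            a.partial_charge = float(q)

    sites: list[ProtonableSite] = []
    unmatched: list[str] = []
    for i, entry in enumerate(site_spec.get("sites") or []):
        sel = entry.get("select", entry.get("atoms"))
        ids = _resolve_selector(atoms, sel)
        if not ids:
            unmatched.append(entry.get("name", f"site[{i}]"))
            continue
        first = atoms[ids[0]]
        w = entry.get("weight")
        if w is None:
            w = default_weight(first.resname, first.element)
            if w is None:
                logger.warning(
                    "site %s: no default weight for residue %r, using w=0",
                    entry.get("name"), first.resname,
                )
                w = 0.0
        nref = entry.get("reference_protons")
        if nref is None:
            nref = DEFAULT_REFERENCE_PROTONS.get(first.resname.upper(), int(round(w)))
        role = entry.get("role")
        if role is None:
            role = "water" if first.resname.upper() in WATER_RESNAMES else "relay"
        site = ProtonableSite(i, str(entry.get("name", f"site{i}")), ids, float(w), int(nref), role)
        for aid in ids:
            if atoms[aid].site_id is not None:
                raise ValueError(
                    f"atom {aid} ({atoms[aid].name}) assigned to two sites: "
                    f"{sites[atoms[aid].site_id].name} and {site.name}"
                )
            atoms[aid].site_id = site.site_id
        sites.append(site)
    if unmatched:
        raise ValueError(f"site spec entries matched no atoms: {', '.join(unmatched)}")

    def resolve_one(key: str) -> int:
        sel = site_spec.get(key)
        if sel is None:
            raise ValueError(f"site spec must name a {key} atom")
        ids = _resolve_selector(atoms, sel)
        if len(ids) != 1:
            raise ValueError(f"{key} selector matched {len(ids)} atoms (need exactly 1)")
        return ids[0]

    donor_id = resolve_one("donor")
    acceptor_id = resolve_one("acceptor")

    # mobile protons: H within covalent range of any site heavy atom
    heavy_pos = np.array([atoms[aid].position for s in sites for aid in s.heavy_atom_ids])
    if len(heavy_pos):
        for a in atoms:
            if a.element.upper() != "H":
                continue
            d = np.linalg.norm(heavy_pos - a.position, axis=1)
            if np.min(d) <= BOND_CUTOFF:
                a.is_mobile_proton = True

    state = site_spec.get("redox_state", "Q_red")
    redox = REDOX_STATES[state] if isinstance(state, str) else state

    topo = SystemTopology(atoms, sites, donor_id, acceptor_id, Q_RED)
    if redox.label != "Q_red":
        topo = apply_redox_shift(topo, redox)
    return topo


# ---------------------------------------------------------------------------
# redox bookkeeping
# ---------------------------------------------------------------------------

def apply_redox_shift(topology: SystemTopology, state: RedoxState) -> SystemTopology:
    """Return a copy of *topology* with the state's charge shifts applied.

    Shifts are keyed by atom name (e.g. FE2, S1, S2 for the FeS cluster; FE,
    NA..ND for the heme).  The input topology is left unchanged.  Shifts are
    only applied on top of the fully reduced (Q_red) reference; re-applying a
    shifted state is rejected so the bookkeeping stays single-entry.
    """
    if state.label != "Q_red" and topology.redox_state.label != "Q_red":
        raise ValueError(
            f"topology already in state {topology.redox_state.label}; "
            "redox shifts apply from the Q_red reference only"
        )
    new = topology.copy()
    for name, shift in state.charge_shifts.items():
        hit = [a for a in new.atoms if a.name == name]
        if not hit:
            raise ValueError(f"redox state {state.label}: cofactor atom {name!r} not found")
        for a in hit:
            a.partial_charge += float(shift)
    new.redox_state = state
    return new


def total_charge(topology: SystemTopology) -> float:
    """Sum of partial charges, |e|."""
    q = topology.charges()
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite partial charge in topology")
    return float(np.sum(q))
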