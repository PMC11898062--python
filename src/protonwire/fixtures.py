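"""Synthetic example wires of the quinol-oxidation (Q_o) site.

Programmatic stand-ins for the five donor->acceptor proton wires of the
Q_o site of the cytochrome bc1 complex: chains of quinol oxygens, tyrosine
/ glutamate / histidine side-chain atoms, heme propionate and crystal-water
positions.  The geometries are synthetic - idealized hydrogen-bonded chains
at 2.8 A heavy-atom separations - and are meant to be validated by wire
composition (site identities and water counts), not by coordinates.
"""

from __future__ import annotations

import numpy as np

from .topology import AtomRecord, ProtonableSite, SystemTopology

__all__ = ["WIRE_COMPOSITIONS", "build_wire_fixture"]

#: site chains (donor ... acceptor) per wire label; w* entries are waters
WIRE_COMPOSITIONS = {
    "A": ["Q_O4", "w3", "H152"],
    "B": ["Q_O1", "Y147", "E295", "w1", "PRA"],
    "C": ["Q_O1", "Y147", "w1", "Y297", "w5", "PRA"],
    "D": ["Q_O1", "Y147", "w1", "w4", "w5", "PRA"],
    "E": ["Q_O1", "Y147", "E295", "w5", "w6", "w7", "H276", "D278"],
}

#: (resname, heavy element, weight, reference protons, role) per site class
_SITE_TYPES = {
    "Q": ("UQ", "O", 0.0, 0, "donor"),
    "Y": ("TYR", "O", 1.0, 1, "relay"),
    "E": ("GLU", "O", 0.0, 0, "relay"),
    "H": ("HIS", "N", 0.5, 1, "relay"),
    "D": ("ASP", "O", 0.0, 0, "relay"),
    "PRA": ("HEM", "O", 0.0, 0, "acceptor"),
    "w": ("HOH", "O", 2.0, 2, "water"),
}

_OO = 2.8  # heavy-heavy hydrogen-bond distance, A
_OH = 1.0  # covalent bond length, A


def _site_type(name: str):
    if name.startswith("w"):
        return _SITE_TYPES["w"]
    if name.startswith("PRA"):
        return _SITE_TYPES["PRA"]
    return _SITE_TYPES[name[0]]


def build_wire_fixture(label: str) -> SystemTopology:
    """One of the five example wires (labels A-E) as a topology.

    Heavy sites form a gently zig-zagging hydrogen-bonded chain; every site
    except the terminal acceptor carries a hydrogen pointing at the next
    site (waters carry their second hydrogen pointing away), so hydrogen
    bond detection recovers exactly the chain.  The first site is the
    donor, the last the acceptor.
    """
    try:
        chain = WIRE_COMPOSITIONS[label.upper()]
    except KeyError:
        raise ValueError(f"unknown wire label {label!r} (use A-E)") from None

    # zig-zag heavy-atom positions in the xy plane
    pos = [np.zeros(3)]
    angle = 0.0
    for i in range(1, len(chain)):
        angle = 0.35 * (-1) ** i  # +-20 degrees
        step = _OO * np.array([np.cos(angle), np.sin(angle), 0.0])
        pos.append(pos[-1] + step)

    atoms: list[AtomRecord] = []
    sites: list[ProtonableSite] = []
    aid = 0
    resid = 0
    for i, name in enumerate(chain):
        resname, element, weight, nref, role = _site_type(name)
        if i == 0:
            role = "donor"
        elif i == len(chain) - 1:
            role = "acceptor"
        resid += 1
        heavy_id = aid
        atoms.append(
            AtomRecord(aid, element, pos[i], name=name, resname=resname, resid=resid,
                       site_id=i)
        )
        aid += 1
        if i < len(chain) - 1:
            # hydrogen pointing at the next heavy atom
            direction = pos[i + 1] - pos[i]
            direction = direction / np.linalg.norm(direction)
            atoms.append(
                AtomRecord(aid, "H", pos[i] + _OH * direction, name=f"H{aid}",
                           resname=resname, resid=resid, is_mobile_proton=True)
            )
            aid += 1
        if role == "water":
            # second water hydrogen pointing off-chain
            atoms.append(
                AtomRecord(aid, "H", pos[i] + _OH * np.array([0.0, 0.0, 1.0]),
                           name=f"H{aid}", resname=resname, resid=resid,
                           is_mobile_proton=True)
            )
            aid += 1
        sites.append(ProtonableSite(i, name, [heavy_id], weight, nref, role))

    return SystemTopology(
        atoms, sites, donor_atom_id=0, acceptor_atom_id=sites[-1].heavy_atom_ids[0]
    )
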