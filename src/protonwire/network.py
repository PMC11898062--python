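"""Hydrogen-bond detection and proton-wire enumeration.

A proton wire is a chain of protonable sites (waters and side chains)
connected by hydrogen bonds that can relay an excess proton from a donor
group to an acceptor by Grotthuss hopping.  Hydrogen bonds are detected with
geometric criteria (donor-acceptor distance and D-H...A angle); wires are
simple paths in the site graph whose nodes are protonable sites and whose
edges are inter-site hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .topology import SystemTopology

__all__ = [
    "HBondCriteria",
    "HBond",
    "ProtonWire",
    "detect_hbonds",
    "build_site_graph",
    "enumerate_wires",
    "wire_min_waters",
    "to_dot",
]

#: Covalent X-H bond cutoff for identifying the donor heavy atom of each H, A.
_COVALENT_CUTOFF = 1.25

#: Elements that can donate/accept hydrogen bonds.
_POLAR = {"N", "O", "S"}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (donor-acceptor distance, DHA angle)."""

    d_DA_max: float = 3.5  # A
    angle_min: float = 135.0  # degrees


@dataclass(frozen=True)
class HBond:
    donor_atom_id: int
    hydrogen_atom_id: int
    acceptor_atom_id: int
    d_DA: float
    angle_DHA: float


@dataclass
class ProtonWire:
    """Ordered donor -> acceptor site path with its water content."""

    site_names: list[str]
    site_ids: list[int]
    water_count: int
    water_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.site_ids)


def detect_hbonds(
    topology: SystemTopology,
    positions: np.ndarray | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """All D-H...A triples passing the distance and angle cutoffs.

    Every hydrogen is attached to its nearest polar heavy atom within
    covalent range (the donor); any other polar heavy atom within
    ``d_DA_max`` of the donor and with a D-H...A angle above ``angle_min``
    accepts.
    """
    pos = topology.positions() if positions is None else np.asarray(positions, float)
    elements = [e.upper() for e in topology.elements()]
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    if not h_idx:
        raise ValueError("no hydrogens in topology: provide a protonated structure")
    heavy_idx = np.array([i for i, e in enumerate(elements) if e in _POLAR], dtype=int)
    if heavy_idx.size == 0:
        return []
    heavy_pos = pos[heavy_idx]

    bonds: list[HBond] = []
    for hi in h_idx:
        dv = heavy_pos - pos[hi]
        dist = np.linalg.norm(dv, axis=1)
        j = int(np.argmin(dist))
        if dist[j] > _COVALENT_CUTOFF:
            continue  # free hydrogen, no donor
        donor = int(heavy_idx[j])
        dDA = np.linalg.norm(heavy_pos - pos[donor], axis=1)
        for k in range(heavy_idx.size):
            acc = int(heavy_idx[k])
            if acc == donor or dDA[k] > criteria.d_DA_max:
                continue
            v1 = pos[donor] - pos[hi]
            v2 = pos[acc] - pos[hi]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if angle >= criteria.angle_min:
                bonds.append(
                    HBond(donor, hi, acc, float(dDA[k]), angle)
                )
    return bonds


def build_site_graph(topology: SystemTopology, hbonds: list[HBond]) -> nx.Graph:
    """Graph over protonable sites; an edge joins two sites linked by any H-bond.

    Sites, not atoms, are the nodes: a residue with two protonable oxygens
    (e.g. a propionate) is a single node.
    """
    atom_site = {}
    g = nx.Graph()
    for s in topology.sites:
        g.add_node(s.site_id, name=s.name, role=s.role)
        for aid in s.heavy_atom_ids:
            atom_site[topology.index_of(aid)] = s.site_id
    for hb in hbonds:
        sd = atom_site.get(hb.donor_atom_id)
        sa = atom_site.get(hb.acceptor_atom_id)
        if sd is None or sa is None or sd == sa:
            continue
        g.add_edge(sd, sa)
    return g


def enumerate_wires(
    graph: nx.Graph,
    donor_site: int,
    acceptor_sites: list[int] | int,
    max_length: int = 8,
) -> list[ProtonWire]:
    """All simple donor->acceptor site paths of up to *max_length* sites.

    Results are sorted by water count, then lexicographically by site names,
    so enumeration is deterministic for a given frame and criteria.
    """
    if donor_site not in graph:
        raise ValueError(f"donor site {donor_site} is not a node of the H-bond graph")
    if isinstance(acceptor_sites, int):
        acceptor_sites = [acceptor_sites]
    wires: list[ProtonWire] = []
    for acc in acceptor_sites:
        if acc not in graph:
            continue
        for path in nx.all_simple_paths(graph, donor_site, acc, cutoff=max_length - 1):
            names = [graph.nodes[s]["name"] for s in path]
            waters = [
                graph.nodes[s]["name"] for s in path if graph.nodes[s]["role"] == "water"
            ]
            wires.append(ProtonWire(names, list(path), len(waters), waters))
    wires.sort(key=lambda w: (w.water_count, w.site_names))
    return wires


def wire_min_waters(wire: ProtonWire) -> int:
    """Number of water molecules the wire runs through."""
    return wire.water_count


def to_dot(graph: nx.Graph) -> str:
    """Render the site graph in DOT format (for graphviz)."""
    lines = ["graph wires {"]
    for n, data in sorted(graph.nodes(data=True)):
        shape = "ellipse" if data.get("role") == "water" else "box"
        lines.append(f'  n{n} [label="{data.get("name", n)}", shape={shape}];')
    for a, b in sorted(graph.edges()):
        lines.append(f"  n{a} -- n{b};")
    lines.append("}")
    return "\n".join(lines) + "\n"
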