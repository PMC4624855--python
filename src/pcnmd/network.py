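"""Residue contact networks and their global descriptors.

A protein contact network is the unweighted, undirected graph whose nodes
are residue α-carbons and whose edges join residues with Cα–Cα distance
inside a fixed band (default 4–8 Å).  The lower bound together with the
explicit exclusion of sequence-adjacent pairs restricts the graph to
non-covalent packing contacts; the upper bound keeps it to van-der-Waals
range.  Sequence adjacency is judged within a chain only: the last residue
of one chain and the first of the next are not covalently linked, so they
may form an edge.

Per-network descriptors:

``adeg``     average degree — mean number of contacts per residue.
``asp``      average shortest-path length in steps, over all reachable
             unordered pairs (averaged within components when the graph is
             disconnected, with a ``connected`` flag).
``E``        graph energy — the sum of absolute adjacency eigenvalues, a
             global connectivity measure.
``dG_solv``  Eisenberg–McLachlan solvation free energy, Σ Δσ(class)·ASA
             over heavy atoms, in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import (
    ClassificationError,
    EmptyGraphError,
    InsufficientFramesError,
    MissingAtomError,
    NoPathError,
    ParameterError,
)
from .structure import AtomRecord, Ensemble, Structure


@dataclass
class NetworkNode:
    index: int  # sequential 0-based node index
    chain: str
    res_seq: int
    i_code: str
    res_name: str


@dataclass
class ContactNetwork:
    """Unweighted symmetric residue graph with node metadata."""

    nodes: list[NetworkNode]
    adjacency: np.ndarray
    planted_labels: np.ndarray | None = None
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.nodes):
            raise ValueError("adjacency size must match node count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        if self._graph is None:
            g = nx.from_numpy_array(self.adjacency)
            for node in self.nodes:
                g.nodes[node.index].update(
                    chain=node.chain, res_seq=node.res_seq, res_name=node.res_name
                )
            self._graph = g
        return self._graph

    @property
    def component_labels(self) -> np.ndarray:
        labels = np.full(self.n_nodes, -1, dtype=int)
        for c, comp in enumerate(nx.connected_components(self.to_networkx())):
            for i in comp:
                labels[i] = c
        return labels

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))


def build_contact_network(
    structure: Structure, dmin: float = 4.0, dmax: float = 8.0
) -> ContactNetwork:
    """Build the Cα contact network of a structure.

    Edge rule: ``dmin <= |Cα_i − Cα_j| <= dmax`` (inclusive on both bounds)
    and the pair is not sequence-adjacent within a chain.  Every protein
    residue must carry exactly one α-carbon.
    """
    if not (0 < dmin < dmax):
        raise ParameterError(f"need 0 < dmin < dmax, got {dmin}, {dmax}")
    residues = structure.residues
    if not residues:
        raise EmptyGraphError("structure has no protein residues")
    ca_coords = np.empty((len(residues), 3))
    nodes: list[NetworkNode] = []
    for i, res in enumerate(residues):
        ca_idx = [
            j for j in res.atom_indices if structure.atoms[j].name == "CA"
        ]
        if len(ca_idx) != 1:
            raise MissingAtomError(
                f"residue {res.chain}{res.res_seq}{res.i_code} "
                f"({res.res_name}) has {len(ca_idx)} CA atoms, expected 1"
            )
        ca_coords[i] = structure.atoms[ca_idx[0]].coords
        nodes.append(NetworkNode(i, res.chain, res.res_seq, res.i_code, res.res_name))
    d = squareform(pdist(ca_coords))
    adjacency = ((d >= dmin) & (d <= dmax)).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    chains = np.array([n.chain for n in nodes])
    idx = np.arange(len(nodes))
    covalent = (np.abs(idx[:, None] - idx[None, :]) <= 1) & (
        chains[:, None] == chains[None, :]
    )
    adjacency[covalent] = 0
    return ContactNetwork(nodes=nodes, adjacency=adjacency)


def average_degree(net: ContactNetwork) -> float:
    """Mean number of contacts per residue (2·E/N)."""
    if net.n_nodes == 0:
        raise EmptyGraphError("network has no nodes")
    return float(net.degrees.mean())


def average_shortest_path(net: ContactNetwork) -> float:
    """Average shortest-path length over all reachable unordered pairs.

    On a disconnected graph the average pools path lengths within each
    component (singletons contribute nothing); use :func:`is_connected` or
    the descriptor bundle's ``connected`` flag to tell the cases apart.
    """
    if net.n_nodes < 2:
        raise EmptyGraphError("need at least 2 nodes")
    if net.n_edges == 0:
        raise NoPathError("edgeless graph has no paths")
    g = net.to_networkx()
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(comp) * (len(comp) - 1)
    # each unordered pair counted twice above
    return total / pairs


def is_connected(net: ContactNetwork) -> bool:
    return net.n_nodes > 0 and nx.is_connected(net.to_networkx())


def graph_energy(net: ContactNetwork) -> float:
    """Graph energy: Σ|λ_i| over adjacency eigenvalues."""
    if net.n_nodes == 0:
        raise EmptyGraphError("network has no nodes")
    if net.n_edges == 0:
        return 0.0
    eigenvalues = np.linalg.eigvalsh(net.adjacency.astype(float))
    return float(np.abs(eigenvalues).sum())


# ---------------------------------------------------------------------------
# Eisenberg–McLachlan solvation free energy
# ---------------------------------------------------------------------------

#: atomic solvation parameters Δσ in cal/(mol·Å²)
EISENBERG_MCLACHLAN_DSIGMA = {
    "C": 16.0,
    "N/O": -6.0,
    "O-": -24.0,
    "N+": -50.0,
    "S": 21.0,
}

_CHARGED_OXYGENS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_NITROGENS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}


@dataclass
class SolvationParams:
    """Knobs of the solvation descriptor (Δσ values, probe, sphere points)."""

    delta_sigma: dict[str, float] = field(
        default_factory=lambda: dict(EISENBERG_MCLACHLAN_DSIGMA)
    )
    probe_radius: float = 1.4
    radii_set: str = "bondi"
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ParameterError("probe_radius must be > 0")


def solvation_class(atom: AtomRecord) -> str | None:
    """Eisenberg–McLachlan atom class, or None for hydrogens (no term)."""
    el = atom.element.upper()
    if el == "H":
        return None
    if el == "C":
        return "C"
    if el == "S":
        return "S"
    if el == "O":
        if (atom.res_name, atom.name) in _CHARGED_OXYGENS or atom.name == "OXT":
            return "O-"
        return "N/O"
    if el == "N":
        if (atom.res_name, atom.name) in _CHARGED_NITROGENS:
            return "N+"
        return "N/O"
    raise ClassificationError(
        f"cannot classify atom {atom.name} ({atom.element}) in "
        f"{atom.res_name} {atom.chain}{atom.res_seq}"
    )


def solvation_free_energy(
    structure: Structure, params: SolvationParams | None = None
) -> float:
    """dG_solv = Σ Δσ(class)·ASA over heavy atoms, in kcal/mol."""
    from .energetics import sasa  # local import to avoid a cycle

    params = params or SolvationParams()
    heavy = [i for i, a in enumerate(structure.atoms) if a.element.upper() != "H"]
    heavy_structure = Structure([structure.atoms[i] for i in heavy])
    classes = [solvation_class(a) for a in heavy_structure.atoms]
    areas = sasa(
        heavy_structure,
        probe=params.probe_radius,
        n_points=params.n_sphere_points,
    )
    total_cal = sum(
        params.delta_sigma[c] * area for c, area in zip(classes, areas) if c
    )
    return float(total_cal) / 1000.0


@dataclass
class NetworkDescriptors:
    """The per-structure descriptor bundle."""

    adeg: float
    asp: float
    graph_energy: float
    dg_solv: float | None
    n_nodes: int
    n_edges: int
    connected: bool


def network_descriptors(
    net: ContactNetwork,
    structure: Structure | None = None,
    params: SolvationParams | None = None,
) -> NetworkDescriptors:
    """Compute the descriptor bundle for one network (and its structure)."""
    dg = solvation_free_energy(structure, params) if structure is not None else None
    asp = average_shortest_path(net) if net.n_edges > 0 else 0.0
    return NetworkDescriptors(
        adeg=average_degree(net),
        asp=asp,
        graph_energy=graph_energy(net),
        dg_solv=dg,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        connected=is_connected(net),
    )


def descriptor_series(
    ensemble: Ensemble,
    dmin: float = 4.0,
    dmax: float = 8.0,
    params: SolvationParams | None = None,
    include_dg_solv: bool = True,
) -> pd.DataFrame:
    """Per-frame contact-network descriptors, aligned to frame times.

    Returns a DataFrame with columns ``time_ps, adeg, asp, E, dG_solv,
    n_nodes, n_edges, connected`` — the table the equilibration analysis
    consumes.
    """
    if ensemble.n_frames < 2:
        raise InsufficientFramesError("descriptor series needs >= 2 frames")
    rows = []
    for f in range(ensemble.n_frames):
        frame = ensemble.frame_structure(f)
        try:
            net = build_contact_network(frame, dmin=dmin, dmax=dmax)
            d = network_descriptors(
                net, frame if include_dg_solv else None, params
            )
        except Exception as exc:  # annotate with the offending frame
            raise type(exc)(f"frame {f}: {exc}") from exc
        rows.append(
            {
                "time_ps": ensemble.times[f],
                "adeg": d.adeg,
                "asp": d.asp,
                "E": d.graph_energy,
                "dG_solv": d.dg_solv if d.dg_solv is not None else np.nan,
                "n_nodes": d.n_nodes,
                "n_edges": d.n_edges,
                "connected": d.connected,
            }
        )
    return pd.DataFrame(rows)


def network_tables(net: ContactNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(edge table, node table) DataFrames for TSV export."""
    edges = pd.DataFrame(net.edge_list(), columns=["node_i", "node_j"])
    nodes = pd.DataFrame(
        [
            {
                "index": n.index,
                "chain": n.chain,
                "res_seq": n.res_seq,
                "res_name": n.res_name,
            }
            for n in net.nodes
        ]
    )
    return edges, nodes
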