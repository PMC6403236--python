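"""Residue interaction network (RIN) and betweenness-centrality analysis.

Residues are nodes; an edge joins two residues whose closest non-hydrogen
atoms are within a contact cutoff (default 0.7 nm), optionally weighted by
the number of hydrogen bonds between the residues.  Betweenness centrality

    C_B(v) = 2/((N−2)(N−1)) · Σ_{s<t} σ_st(v)/σ_st

is computed with the Brandes accumulation scheme, where σ_st counts
shortest paths between s and t and σ_st(v) those passing through v.  High
C_B marks residues on many communication pathways, candidates for signal
propagation through the structure.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .hbond import HBond
from .structio import Structure, Trajectory, TrajnetError, write_pdb


class NetworkError(TrajnetError):
    pass


NodeKey = tuple[str, int]  # (chain, resid)


@dataclass
class ResidueGraph:
    """Residue contact graph; nodes are (chain, resid), edges carry the
    minimum heavy-atom distance and a hydrogen-bond count weight."""

    graph: nx.Graph
    contact_cutoff: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def nodes(self) -> list[NodeKey]:
        return list(self.graph.nodes)

    def resname(self, node: NodeKey) -> str:
        return self.graph.nodes[node].get("resname", "UNK")


@dataclass
class CentralityTable:
    """Per-residue betweenness centrality values in [0, 1]."""

    values: dict[NodeKey, float]
    resnames: dict[NodeKey, str] = field(default_factory=dict)
    mode: str = "unweighted"

    def __getitem__(self, node: NodeKey) -> float:
        return self.values[node]

    def nodes(self) -> list[NodeKey]:
        return list(self.values)


def build_rin(
    structure: Structure,
    hbonds: list[HBond] | None = None,
    contact_cutoff: float = 0.7,
) -> ResidueGraph:
    """Build the residue interaction network from one structure frame.

    An edge joins two distinct residues iff any cross pair of their
    non-hydrogen atoms lies within ``contact_cutoff``; sequence-adjacent
    residues are treated like any other pair.  ``hbonds`` (from
    :func:`trajnet.hbond.detect_hbonds` on the same frame) set the
    per-edge hydrogen-bond weight.
    """
    top = structure.topology
    if len(top) == 0:
        raise NetworkError("empty structure")
    heavy = np.nonzero(top.elements != "H")[0]
    if heavy.size == 0:
        raise NetworkError("structure has no heavy atoms")
    res_index = top.residue_index()
    res_keys = top.residue_keys()
    g = nx.Graph()
    for chain, resid, resname in res_keys:
        g.add_node((chain, resid), resname=resname)
    # Min heavy-atom distance per residue pair within cutoff.
    from scipy.spatial import cKDTree

    xyz = structure.coords[heavy]
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    best: dict[tuple[int, int], float] = {}
    for a, b in pairs:
        ra, rb = int(res_index[heavy[a]]), int(res_index[heavy[b]])
        if ra == rb:
            continue
        key = (min(ra, rb), max(ra, rb))
        d = float(np.linalg.norm(xyz[a] - xyz[b]))
        if d <= contact_cutoff and d < best.get(key, np.inf):
            best[key] = d
    for (ra, rb), d in best.items():
        ka = res_keys[ra][:2]
        kb = res_keys[rb][:2]
        g.add_edge(ka, kb, distance_nm=d, hbond_weight=0)
    if hbonds:
        for hb in hbonds:
            ra = int(res_index[hb.donor])
            rb = int(res_index[hb.acceptor])
            if ra == rb:
                continue
            ka, kb = res_keys[ra][:2], res_keys[rb][:2]
            if g.has_edge(ka, kb):
                g.edges[ka, kb]["hbond_weight"] += 1
            else:
                # H-bond criteria imply contact, but guard anyway.
                g.add_edge(
                    ka, kb, distance_nm=float(hb.da_distance), hbond_weight=1
                )
    return ResidueGraph(g, contact_cutoff)


# --------------------------------------------------------------------------- #
# Brandes betweenness
# --------------------------------------------------------------------------- #


def _brandes(
    adj: dict, nodes: list, lengths: dict | None
) -> dict:
    """Brandes single-source accumulation; returns raw Σ over ordered pairs."""
    cb = {v: 0.0 for v in nodes}
    for s in nodes:
        sigma = {v: 0.0 for v in nodes}
        dist = {v: np.inf for v in nodes}
        pred: dict = {v: [] for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0.0
        order = []
        if lengths is None:  # BFS hop counts
            queue = [s]
            head = 0
            while head < len(queue):
                v = queue[head]
                head += 1
                order.append(v)
                for w in adj[v]:
                    if dist[w] == np.inf:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        pred[w].append(v)
        else:  # Dijkstra
            seen = set()
            counter = 0
            heap = [(0.0, counter, s)]
            while heap:
                d, _, v = heapq.heappop(heap)
                if v in seen:
                    continue
                seen.add(v)
                order.append(v)
                for w in adj[v]:
                    nd = d + lengths[(v, w)]
                    if nd < dist[w] - 1e-12:
                        dist[w] = nd
                        sigma[w] = sigma[v]
                        pred[w] = [v]
                        counter += 1
                        heapq.heappush(heap, (nd, counter, w))
                    elif abs(nd - dist[w]) <= 1e-12 and v not in pred[w] and w not in seen:
                        sigma[w] += sigma[v]
                        pred[w].append(v)
        delta = {v: 0.0 for v in nodes}
        for w in reversed(order):
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    return cb


def betweenness(
    rgraph: ResidueGraph, mode: str = "unweighted"
) -> CentralityTable:
    """Betweenness centrality per residue, normalized by 2/((N−2)(N−1)).

    ``unweighted`` uses hop-count shortest paths; ``hbond_weighted`` runs
    Dijkstra with edge length 1/(1 + hbond_weight), so edges with more
    hydrogen bonds are effectively shorter.  Disconnected pairs simply
    contribute no paths; normalization always uses the global N.
    """
    g = rgraph.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 3:
        raise NetworkError("betweenness normalization requires at least 3 nodes")
    if mode not in ("unweighted", "hbond_weighted"):
        raise NetworkError(f"unknown mode {mode!r}")
    adj = {v: list(g.neighbors(v)) for v in nodes}
    lengths = None
    if mode == "hbond_weighted":
        lengths = {}
        for u, v, data in g.edges(data=True):
            w = data.get("hbond_weight", 0)
            if w < 0:
                raise NetworkError(f"negative hbond weight on edge ({u}, {v})")
            ell = 1.0 / (1.0 + w)
            lengths[(u, v)] = ell
            lengths[(v, u)] = ell
    raw = _brandes(adj, nodes, lengths)
    # Brandes raw counts ordered (s, t) pairs: divide by 2 for s<t, then
    # apply the 2/((N−2)(N−1)) normalization.
    norm = 1.0 / ((n - 1) * (n - 2))
    values = {v: raw[v] * norm for v in nodes}
    resnames = {v: rgraph.resname(v) for v in nodes}
    return CentralityTable(values, resnames, mode)


def select_central(
    table: CentralityTable, threshold: float = 0.1
) -> list[NodeKey]:
    """Residues with C_B ≥ threshold, sorted by C_B descending then
    (chain, resid)."""
    hits = [(v, c) for v, c in table.values.items() if c >= threshold]
    hits.sort(key=lambda x: (-x[1], x[0]))
    return [v for v, _ in hits]


def differential_centrality(
    table_ref: CentralityTable,
    table_alt: CentralityTable | list[CentralityTable],
    threshold: float = 0.05,
) -> tuple[list[NodeKey], dict[NodeKey, float], set[NodeKey]]:
    """Residues whose centrality shifts between a reference and alternates.

    For each alternate, |ΔC_B| = |C_B,ref − C_B,alt| is computed per shared
    node and residues with |ΔC_B| ≥ threshold are flagged.  Returns the
    flagged residues of the first alternate (union ordering by |Δ|
    descending), the per-node Δ values of the first alternate, and the
    intersection of the flagged sets across all alternates.
    """
    alts = table_alt if isinstance(table_alt, list) else [table_alt]
    if not alts:
        raise NetworkError("no alternate table given")
    ref_nodes = set(table_ref.values)
    flagged_sets: list[set[NodeKey]] = []
    first_delta: dict[NodeKey, float] = {}
    for i, alt in enumerate(alts):
        alt_nodes = set(alt.values)
        if alt_nodes != ref_nodes:
            missing = sorted(ref_nodes ^ alt_nodes)
            raise NetworkError(f"node sets differ; mismatched residues: {missing}")
        delta = {v: abs(table_ref[v] - alt[v]) for v in table_ref.values}
        if i == 0:
            first_delta = delta
        flagged_sets.append({v for v, d in delta.items() if d >= threshold})
    flagged = sorted(flagged_sets[0], key=lambda v: (-first_delta[v], v))
    common = set.intersection(*flagged_sets)
    return flagged, first_delta, common


def map_centrality_to_structure(
    structure: Structure,
    table: CentralityTable,
    path,
    flagged: list[NodeKey] | None = None,
) -> np.ndarray:
    """Write the structure with 100·C_B in the B-factor column.

    Flagged residues are listed in REMARK records.  Returns the per-atom
    B-factor array that was written.
    """
    top = structure.topology
    bf = np.zeros(len(top))
    for i, a in enumerate(top.atoms):
        key = (a.chain, a.resid)
        if key not in table.values:
            raise NetworkError(f"residue {key} not present in centrality table")
        bf[i] = 100.0 * table[key]
    remarks = ["betweenness centrality mapped as B-factor = 100*C_B"]
    if flagged:
        for chain, resid in flagged:
            remarks.append(f"flagged residue {chain}:{resid}")
    from .structio import Trajectory as _Traj

    traj = _Traj(top, structure.coords[None, :, :])
    write_pdb(traj, path, bfactors=bf, remarks=remarks)
    return bf
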