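"""Dynamic-network analysis of correlated motions.

Nodes coarse-grain the complex: Cα (and Cβ, except Gly/Ala/Pro) per protein
residue; two nodes per nucleotide, a backbone node anchored on C3' and a base
node anchored on N3 (purines) or C4 (pyrimidines).  Edges connect node pairs
whose represented atom sets keep at least one atom-atom contact (≤ 4.5 Å) in
more than 75% of the frames, excluding trivially connected neighbors; the
edge length is d_mn = −log|C_mn| with C_mn the positional cross-correlation
of the anchor atoms.  Short network distance therefore means strong
correlated motion, and shortest/suboptimal paths trace putative allosteric
communication routes.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory_core import DNA_BACKBONE_ATOMS, Ensemble

__all__ = [
    "Node",
    "NodeSet",
    "build_nodes",
    "cross_correlation",
    "build_network",
    "shortest_path",
    "suboptimal_paths",
    "communities",
]

NO_CB = {"GLY", "ALA", "PRO"}
PURINES = {"DA", "DG", "A", "G", "ADE", "GUA"}


@dataclass(frozen=True)
class Node:
    node_id: str
    kind: str                   # protein-Ca | protein-Cb | dna-backbone | dna-base
    anchor: int                 # anchor atom index
    atoms: tuple[int, ...]      # represented atom set
    chain: str
    resid: int


@dataclass
class NodeSet:
    nodes: list[Node]

    def __len__(self):
        return len(self.nodes)

    def ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def by_id(self, node_id: str) -> Node:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)


_PROTEIN_BACKBONE = {"N", "CA", "C", "O", "H", "HA"}


def build_nodes(ensemble: Ensemble) -> NodeSet:
    """Standard coarse-graining of a protein-DNA complex into network nodes.

    Protein residues: a Cα node representing the backbone atoms, plus a Cβ
    node representing the side chain unless the residue is Gly/Ala/Pro (one
    node on Cα then, representing the whole residue).  Nucleotides: a
    backbone node anchored on C3' representing the sugar-phosphate atoms and
    a base node anchored on N3 (purines) / C4 (pyrimidines) representing the
    base atoms.
    """
    top = ensemble.topology
    is_dna = ensemble.is_dna()
    nodes: list[Node] = []
    for (chain, resid), grp in top.groupby(["chain", "resid"], sort=False):
        resname = grp["resname"].iloc[0].upper()
        atom_idx = grp.index.to_numpy()
        names = grp["name"].tolist()
        heavy = grp["is_heavy"].to_numpy()
        atom_idx = atom_idx[heavy]
        names = [n for n, h in zip(names, heavy) if h]
        name_to_idx = dict(zip(names, atom_idx))
        if is_dna[grp.index[0]]:
            bb = tuple(i for n, i in zip(names, atom_idx)
                       if n in DNA_BACKBONE_ATOMS)
            base = tuple(i for n, i in zip(names, atom_idx)
                         if n not in DNA_BACKBONE_ATOMS)
            base_anchor_name = "N3" if resname in PURINES else "C4"
            if "C3'" in name_to_idx and bb:
                nodes.append(Node(f"{chain}{resid}:bb", "dna-backbone",
                                  int(name_to_idx["C3'"]), bb, chain, int(resid)))
            if base_anchor_name in name_to_idx and base:
                nodes.append(Node(f"{chain}{resid}:base", "dna-base",
                                  int(name_to_idx[base_anchor_name]), base,
                                  chain, int(resid)))
        else:
            if "CA" not in name_to_idx:
                continue
            if resname in NO_CB or "CB" not in name_to_idx:
                nodes.append(Node(f"{chain}{resid}:ca", "protein-Ca",
                                  int(name_to_idx["CA"]), tuple(atom_idx),
                                  chain, int(resid)))
            else:
                bb = tuple(i for n, i in zip(names, atom_idx)
                           if n in _PROTEIN_BACKBONE)
                sc = tuple(i for n, i in zip(names, atom_idx)
                           if n not in _PROTEIN_BACKBONE)
                nodes.append(Node(f"{chain}{resid}:ca", "protein-Ca",
                                  int(name_to_idx["CA"]), bb, chain, int(resid)))
                nodes.append(Node(f"{chain}{resid}:cb", "protein-Cb",
                                  int(name_to_idx["CB"]), sc, chain, int(resid)))
    return NodeSet(nodes)


def cross_correlation(ensemble: Ensemble, nodes: NodeSet) -> pd.DataFrame:
    """Positional cross-correlation matrix of the node anchor atoms.

    C_mn = ⟨Δr_m·Δr_n⟩ / sqrt(⟨Δr_m²⟩⟨Δr_n²⟩) with Δr the displacement of
    the anchor atom from its ensemble mean — the scalar (dot-product)
    normalized covariance of the 3D displacement vectors.  The ensemble must
    already be superposed on whatever selection the analysis calls for.
    """
    anchors = np.array([n.anchor for n in nodes.nodes])
    traj = ensemble.frames[:, anchors]          # (F, N, 3)
    disp = traj - traj.mean(axis=0)
    cov = np.einsum("fmi,fni->mn", disp, disp) / ensemble.n_frames
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var < 1e-14)
    if bad.size:
        raise ValueError(
            f"zero-variance node(s): {[nodes.nodes[b].node_id for b in bad]}"
        )
    c = cov / np.sqrt(np.outer(var, var))
    return pd.DataFrame(c, index=nodes.ids(), columns=nodes.ids())


def _contact_persistence(ensemble: Ensemble, nodes: NodeSet,
                         cutoff: float) -> np.ndarray:
    """Fraction of frames in which each node pair keeps ≥1 atom contact."""
    n = len(nodes)
    counts = np.zeros((n, n))
    atom_node = {}
    for ni, node in enumerate(nodes.nodes):
        for a in node.atoms:
            atom_node.setdefault(a, []).append(ni)
    atoms = np.array(sorted(atom_node))
    for f in range(ensemble.n_frames):
        xyz = ensemble.frames[f][atoms]
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(r=cutoff + 1e-12, output_type="ndarray")
        touched = np.zeros((n, n), dtype=bool)
        for a_loc, b_loc in pairs:
            d = np.linalg.norm(xyz[a_loc] - xyz[b_loc])
            if d > cutoff + 1e-9:
                continue
            for na in atom_node[atoms[a_loc]]:
                for nb in atom_node[atoms[b_loc]]:
                    if na != nb:
                        touched[na, nb] = touched[nb, na] = True
        counts += touched
    return counts / ensemble.n_frames


def _excluded(a: Node, b: Node) -> bool:
    """Trivially connected neighbors carry no information and get no edge:
    the two nodes of one protein residue, sequence-adjacent protein Cα
    nodes, and sequence-adjacent same-strand DNA backbone nodes."""
    protein = {"protein-Ca", "protein-Cb"}
    if a.kind in protein and b.kind in protein:
        if a.chain == b.chain and a.resid == b.resid:
            return True
        if (a.kind == b.kind == "protein-Ca" and a.chain == b.chain
                and abs(a.resid - b.resid) == 1):
            return True
    if (a.kind == b.kind == "dna-backbone" and a.chain == b.chain
            and abs(a.resid - b.resid) == 1):
        return True
    return False


def build_network(ensemble: Ensemble, nodes: NodeSet,
                  corr: pd.DataFrame,
                  persistence: float = 0.75,
                  cutoff: float = 4.5) -> nx.Graph:
    """Persistence-filtered contact network weighted by −log|C_mn|.

    An edge joins nodes m, n when at least one atom-atom contact between
    their represented sets is present in strictly more than ``persistence``
    of the frames, the pair is not an excluded trivial neighbor, and
    |C_mn| > 0.  Edges with |C| = 0 would have infinite length and are
    dropped with a warning.
    """
    if list(corr.index) != nodes.ids():
        raise ValueError("correlation matrix does not match the node set")
    pers = _contact_persistence(ensemble, nodes, cutoff)
    g = nx.Graph()
    for node in nodes.nodes:
        g.add_node(node.node_id, kind=node.kind, chain=node.chain,
                   resid=node.resid)
    cmat = corr.to_numpy()
    dropped = 0
    for mi in range(len(nodes)):
        for ni in range(mi + 1, len(nodes)):
            if pers[mi, ni] <= persistence:
                continue
            a, b = nodes.nodes[mi], nodes.nodes[ni]
            if _excluded(a, b):
                continue
            c = abs(cmat[mi, ni])
            if c <= 0:
                dropped += 1
                continue
            g.add_edge(a.node_id, b.node_id,
                       weight=float(-np.log(c)),
                       correlation=float(cmat[mi, ni]),
                       persistence=float(pers[mi, ni]))
    if dropped:
        warnings.warn(f"{dropped} edges dropped: zero correlation "
                      "(infinite distance)", stacklevel=2)
    return g


def shortest_path(net: nx.Graph, source: str, target: str
                  ) -> tuple[Optional[list[str]], float]:
    """Minimum-total-weight path with a deterministic lexicographic
    tie-break.  Returns ``(None, inf)`` when no path exists."""
    if source not in net or target not in net:
        raise KeyError("source/target not in network")
    # Dijkstra over (distance, path) with lexicographic path comparison
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    heap = [(0.0, (source,))]
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (best[node][0] < dist - 1e-15
                             or (abs(best[node][0] - dist) <= 1e-15
                                 and best[node][1] <= path)):
            continue
        best[node] = (dist, path)
        if node == target:
            continue
        for nbr in net[node]:
            if nbr in path:
                continue
            heapq.heappush(
                heap, (dist + net[node][nbr]["weight"], path + (nbr,))
            )
    if target not in best:
        return None, float("inf")
    dist, path = best[target]
    return list(path), float(dist)


def suboptimal_paths(net: nx.Graph, source: str, target: str,
                     offset: float = 5.0,
                     max_paths: int = 100_000
                     ) -> tuple[list[tuple[list[str], float]], pd.DataFrame]:
    """All simple paths within ``offset`` of the optimal length.

    Enumerated by depth-first search with admissible pruning (single-source
    shortest distances to the target as a lower bound on the remaining
    length).  Returns the path list (sorted by length) and a per-edge
    traversal count table — the quantity used to size edges when drawing
    communication pathways.
    """
    opt_path, opt_len = shortest_path(net, source, target)
    if opt_path is None:
        raise ValueError("no path between source and target")
    limit = opt_len + offset
    dist_to_target = nx.single_source_dijkstra_path_length(
        net, target, weight="weight"
    )
    paths: list[tuple[list[str], float]] = []

    def dfs(node, length, path, visited):
        if len(paths) > max_paths:
            raise RuntimeError(
                f"more than {max_paths} suboptimal paths; reduce the offset"
            )
        if node == target:
            paths.append((list(path), length))
            return
        for nbr in net[node]:
            if nbr in visited:
                continue
            new_len = length + net[node][nbr]["weight"]
            bound = dist_to_target.get(nbr, float("inf"))
            if new_len + bound > limit + 1e-12:
                continue
            visited.add(nbr)
            path.append(nbr)
            dfs(nbr, new_len, path, visited)
            path.pop()
            visited.remove(nbr)

    dfs(source, 0.0, [source], {source})
    paths.sort(key=lambda pl: (pl[1], pl[0]))
    counts: dict[tuple[str, str], int] = {}
    for path, _ in paths:
        for a, b in zip(path[:-1], path[1:]):
            key = tuple(sorted((a, b)))
            counts[key] = counts.get(key, 0) + 1
    edges = pd.DataFrame(
        [{"u": k[0], "v": k[1], "n_paths": v} for k, v in sorted(counts.items())]
    )
    return paths, edges


def communities(net: nx.Graph) -> tuple[list[set[str]], float]:
    """Girvan–Newman community hierarchy cut at maximum modularity.

    Edge betweenness is computed with the −log|C| lengths (strongly
    correlated pairs are close); modularity is evaluated on the unweighted
    topology.  Disconnected components are necessarily in different
    communities.  Returns (partition, modularity).
    """
    if net.number_of_edges() == 0:
        parts = [{n} for n in net.nodes]
        return parts, 0.0

    def most_central(g):
        bet = nx.edge_betweenness_centrality(g, weight="weight")
        return max(bet, key=bet.get)

    base = [set(c) for c in nx.connected_components(net)]
    best_part = base
    best_q = nx.community.modularity(net, base)
    for part in nx.community.girvan_newman(net, most_valuable_edge=most_central):
        part = [set(p) for p in part]
        q = nx.community.modularity(net, part)
        if q > best_q:
            best_q, best_part = q, part
        if len(part) >= net.number_of_nodes():
            break
    return best_part, float(best_q)


def export_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
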