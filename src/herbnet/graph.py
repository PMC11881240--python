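"""Heterogeneous herb-molecule-target graph assembly and bookkeeping.

Three node types (herb, molecule, target) and three undirected relations:
herb-herb (weighted by the compatibility score C_ij), herb-molecule
(annotation links) and molecule-target (interaction links). Herbs carry no
intrinsic features (they get learned embeddings in the model); molecules carry
MACCS-style fingerprint bit vectors; targets carry binary functional-term
vectors. All relations are symmetrized for neighborhood-based message passing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .corpus import Corpus, PairLabel
from .errors import DegenerateGraphError, ReferentialError

NODE_TYPES = ("herb", "molecule", "target")


@dataclass
class HeteroGraph:
    """Typed node index plus typed edge lists and per-type feature blocks.

    Edges are stored once per unordered pair; adjacency helpers symmetrize.
    ``hh_labels[k]`` is the compatibility score attached to ``hh_edges[k]``.
    """

    herb_ids: list[str]
    mol_ids: list[str]
    target_ids: list[str]
    hh_edges: np.ndarray          # (E_hh, 2) int herb-index pairs, i < j
    hh_labels: np.ndarray         # (E_hh,) float c_ij
    hm_edges: np.ndarray          # (E_hm, 2) [herb_idx, mol_idx]
    mt_edges: np.ndarray          # (E_mt, 2) [mol_idx, target_idx]
    fingerprints: np.ndarray      # (n_mol, fingerprint_bits) float
    term_matrix: np.ndarray       # (n_target, n_terms) float
    term_vocab: tuple[str, ...] = ()
    _herb_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._herb_index:
            self._herb_index = {h: i for i, h in enumerate(self.herb_ids)}
        self._check()

    def _check(self) -> None:
        nh, nm, nt = len(self.herb_ids), len(self.mol_ids), len(self.target_ids)
        if len(self.hh_edges) == 0:
            raise DegenerateGraphError("graph has no herb-herb edges")
        for name, edges, lo, hi in (
            ("herb-herb", self.hh_edges, nh, nh),
            ("herb-molecule", self.hm_edges, nh, nm),
            ("molecule-target", self.mt_edges, nm, nt),
        ):
            if len(edges) and (
                edges[:, 0].min() < 0 or edges[:, 0].max() >= lo
                or edges[:, 1].min() < 0 or edges[:, 1].max() >= hi
            ):
                raise ReferentialError(f"{name} edge index out of bounds")
        if self.fingerprints.shape[0] != nm:
            raise ReferentialError("fingerprint rows != molecule count")
        if self.term_matrix.shape[0] != nt:
            raise ReferentialError("term-matrix rows != target count")
        if len(self.hh_labels) != len(self.hh_edges):
            raise ReferentialError("herb-herb label count != edge count")

    # -- indexing ----------------------------------------------------------

    def herb_index(self, herb_id: str) -> int:
        try:
            return self._herb_index[herb_id]
        except KeyError:
            raise LookupError(f"herb {herb_id!r} not in graph") from None

    @property
    def n_nodes(self) -> dict[str, int]:
        return {
            "herb": len(self.herb_ids),
            "molecule": len(self.mol_ids),
            "target": len(self.target_ids),
        }

    # -- adjacency ---------------------------------------------------------

    def adjacency(self, relation: str) -> sp.csr_matrix:
        """Row-normalized (mean-aggregation) adjacency for one directed relation.

        Relations: 'hh' herb<-herb, 'mh' herb<-molecule, 'hm' molecule<-herb,
        'tm' molecule<-target, 'mt' target<-molecule. Row r of the result
        averages feature rows of r's neighbors; all-zero rows correspond to
        isolated nodes (their aggregated neighborhood is the zero vector).
        """
        nh, nm, nt = len(self.herb_ids), len(self.mol_ids), len(self.target_ids)
        if relation == "hh":
            e = np.vstack([self.hh_edges, self.hh_edges[:, ::-1]])
            shape = (nh, nh)
        elif relation == "mh":
            e = self.hm_edges
            shape = (nh, nm)
        elif relation == "hm":
            e = self.hm_edges[:, ::-1]
            shape = (nm, nh)
        elif relation == "tm":
            e = self.mt_edges
            shape = (nm, nt)
        elif relation == "mt":
            e = self.mt_edges[:, ::-1]
            shape = (nt, nm)
        else:
            raise ValueError(f"unknown relation {relation!r}")
        if len(e) == 0:
            return sp.csr_matrix(shape)
        a = sp.csr_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=shape
        )
        deg = np.asarray(a.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return sp.diags(inv) @ a

    def hh_label_map(self) -> dict[tuple[int, int], float]:
        return {
            (int(i), int(j)): float(c)
            for (i, j), c in zip(self.hh_edges, self.hh_labels)
        }

    def with_hh_edges(self, keep: np.ndarray) -> "HeteroGraph":
        """Copy of the graph restricted to a boolean/index subset of herb-herb
        edges (used to hold out edges during cross-validation)."""
        return HeteroGraph(
            herb_ids=self.herb_ids,
            mol_ids=self.mol_ids,
            target_ids=self.target_ids,
            hh_edges=self.hh_edges[keep],
            hh_labels=self.hh_labels[keep],
            hm_edges=self.hm_edges,
            mt_edges=self.mt_edges,
            fingerprints=self.fingerprints,
            term_matrix=self.term_matrix,
            term_vocab=self.term_vocab,
        )


@dataclass(frozen=True)
class GraphStats:
    n_nodes: dict[str, int]
    n_edges: dict[str, int]          # unordered counts per relation
    n_hh_directed: int               # herb-herb count with both directions
    total_edges: int                 # sum of unordered counts

    def as_dict(self) -> dict:
        return {
            "n_nodes": dict(self.n_nodes),
            "n_edges_unordered": dict(self.n_edges),
            "herb_herb_directed": self.n_hh_directed,
            "total_edges_unordered": self.total_edges,
        }


def build_graph(corpus: Corpus, pair_labels: list[PairLabel]) -> HeteroGraph:
    """Assemble the heterogeneous graph from a (filtered) corpus.

    Herb-herb edges exist exactly for pairs with n_ij > 0; the compatibility
    score is attached symmetrically. Herb-molecule and molecule-target edges
    come from the corpus link sets.
    """
    herb_ids = sorted(corpus.herbs)
    mol_ids = sorted(corpus.molecules)
    target_ids = sorted(corpus.targets)
    h_idx = {h: i for i, h in enumerate(herb_ids)}
    m_idx = {m: i for i, m in enumerate(mol_ids)}
    t_idx = {t: i for i, t in enumerate(target_ids)}

    pos = [l for l in pair_labels if l.n_ij > 0]
    if not pos:
        raise DegenerateGraphError("no co-occurring herb pairs; cannot build graph")
    hh = np.array(
        [sorted((h_idx[l.pair[0]], h_idx[l.pair[1]])) for l in pos], dtype=np.int64
    )
    labels = np.array([l.c_ij for l in pos], dtype=np.float64)
    order = np.lexsort((hh[:, 1], hh[:, 0]))
    hh, labels = hh[order], labels[order]

    hm = np.array(
        sorted((h_idx[h], m_idx[m]) for h, m in corpus.herb_mol_links),
        dtype=np.int64,
    ).reshape(-1, 2)
    mt = np.array(
        sorted((m_idx[m], t_idx[t]) for m, t in corpus.mol_target_links),
        dtype=np.int64,
    ).reshape(-1, 2)

    fp = np.zeros((len(mol_ids), corpus.fingerprint_bits))
    for m, i in m_idx.items():
        for b in corpus.molecules[m].fingerprint:
            fp[i, b] = 1.0

    vocab = corpus.term_vocab
    term_pos = {t: i for i, t in enumerate(vocab)}
    tm = np.zeros((len(target_ids), len(vocab)))
    for t, i in t_idx.items():
        for term in corpus.targets[t].terms:
            tm[i, term_pos[term]] = 1.0

    return HeteroGraph(
        herb_ids=herb_ids,
        mol_ids=mol_ids,
        target_ids=target_ids,
        hh_edges=hh,
        hh_labels=labels,
        hm_edges=hm,
        mt_edges=mt,
        fingerprints=fp,
        term_matrix=tm,
        term_vocab=tuple(vocab),
    )


def graph_stats(g: HeteroGraph) -> GraphStats:
    """Per-type node and edge counts.

    Herb-herb connectivity is reported in both conventions: unordered pairs
    and the directed count (each pair in both directions) used by message
    passing.
    """
    n_edges = {
        "herb-herb": len(g.hh_edges),
        "herb-molecule": len(g.hm_edges),
        "molecule-target": len(g.mt_edges),
    }
    return GraphStats(
        n_nodes=g.n_nodes,
        n_edges=n_edges,
        n_hh_directed=2 * len(g.hh_edges),
        total_edges=sum(n_edges.values()),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_graph(g: HeteroGraph, path: str | Path) -> None:
    """Serialize to a .npz container (arrays + JSON node-id header)."""
    meta = {
        "herb_ids": g.herb_ids,
        "mol_ids": g.mol_ids,
        "target_ids": g.target_ids,
        "term_vocab": list(g.term_vocab),
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        hh_edges=g.hh_edges,
        hh_labels=g.hh_labels,
        hm_edges=g.hm_edges,
        mt_edges=g.mt_edges,
        fingerprints=g.fingerprints,
        term_matrix=g.term_matrix,
    )


def load_graph(path: str | Path) -> HeteroGraph:
    with np.load(path) as z:
        meta = json.loads(z["meta"].tobytes().decode())
        return HeteroGraph(
            herb_ids=list(meta["herb_ids"]),
            mol_ids=list(meta["mol_ids"]),
            target_ids=list(meta["target_ids"]),
            hh_edges=z["hh_edges"],
            hh_labels=z["hh_labels"],
            hm_edges=z["hm_edges"],
            mt_edges=z["mt_edges"],
            fingerprints=z["fingerprints"],
            term_matrix=z["term_matrix"],
            term_vocab=tuple(meta["term_vocab"]),
        )


def export_graphml(g: HeteroGraph, path: str | Path) -> None:
    """Export to GraphML with node 'type' and herb-herb 'c_ij' attributes."""
    import networkx as nx

    gx = nx.Graph()
    for h in g.herb_ids:
        gx.add_node(h, type="herb")
    for m in g.mol_ids:
        gx.add_node(m, type="molecule")
    for t in g.target_ids:
        gx.add_node(t, type="target")
    for (i, j), c in zip(g.hh_edges, g.hh_labels):
        gx.add_edge(g.herb_ids[i], g.herb_ids[j], edge_type="herb-herb", c_ij=float(c))
    for h, m in g.hm_edges:
        gx.add_edge(g.herb_ids[h], g.mol_ids[m], edge_type="herb-molecule")
    for m, t in g.mt_edges:
        gx.add_edge(g.mol_ids[m], g.target_ids[t], edge_type="molecule-target")
    nx.write_graphml(gx, path)


def export_edge_list(g: HeteroGraph, path: str | Path) -> None:
    """Plain TSV edge list: source_id, target_id, edge_type, label."""
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\tedge_type\tlabel\n")
        for (i, j), c in zip(g.hh_edges, g.hh_labels):
            fh.write(f"{g.herb_ids[i]}\t{g.herb_ids[j]}\therb-herb\t{c!r}\n")
        for h, m in g.hm_edges:
            fh.write(f"{g.herb_ids[h]}\t{g.mol_ids[m]}\therb-molecule\t\n")
        for m, t in g.mt_edges:
            fh.write(f"{g.mol_ids[m]}\t{g.target_ids[t]}\tmolecule-target\t\n")
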