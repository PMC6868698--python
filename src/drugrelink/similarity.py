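"""Similarity construction and fusion for drugs and diseases.

Four similarity sources feed the pair descriptors:

* interaction-profile sigmoid kernels for drugs and diseases,
  ``tanh(scale * <u, v> + offset)`` on binary association profiles;
* Tanimoto similarity of molecular fingerprints (drug chemical structure);
* a precomputed disease semantic similarity matrix (MimMiner-style);
* both side similarities are logistic-rescaled (small values pushed towards
  zero, large ones amplified) and then boosted for pairs that fall into the
  same cohesive module of the co-association graph (ClusterONE), capped at
  0.99.

Fusion picks the kernel value for a pair when both entities have a non-empty
interaction profile and falls back to the enhanced structure/semantic value
otherwise (the standard "new entity" rule in kernel-fusion repositioning).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dataio import AssociationMatrix, DrugCatalog, IdentifierError, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KernelParams",
    "LogisticParams",
    "ClusterSet",
    "SIMILARITY_CAP",
    "sigmoid_kernel",
    "tanimoto_structure_similarity",
    "tanimoto",
    "logistic_adjust",
    "build_coassociation_graph",
    "cluster_one",
    "cohesiveness",
    "enhance_similarity",
    "fuse_similarity",
]

#: hard upper bound on any similarity that feeds the encoder
SIMILARITY_CAP = 0.99


def _profiles(A: AssociationMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    """Interaction profiles as rows of a matrix, plus the matching identifiers."""
    if axis == "drugs":
        return A.values.T.astype(float), list(A.drug_ids)
    if axis == "diseases":
        return A.values.astype(float), list(A.disease_ids)
    raise ValueError(f"axis must be 'drugs' or 'diseases', got {axis!r}")


@dataclass(frozen=True)
class KernelParams:
    """Sigmoid-kernel parameters; ``scale=None`` means 1 / profile dimension."""

    scale: float | None = None
    offset: float = 0.0


@dataclass(frozen=True)
class LogisticParams:
    """Logistic rescaling L(x) = 1 / (1 + exp(c*x + f)).

    With the defaults c = -15, f = ln(9999), L(0) = 1e-4 and L(1) ~ 0.997:
    weak similarities collapse towards zero while strong ones are amplified.
    """

    c: float = -15.0
    f: float = math.log(9999.0)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + np.exp(self.c * np.asarray(x, dtype=float) + self.f))


def sigmoid_kernel(
    A: AssociationMatrix, axis: str, params: KernelParams = KernelParams()
) -> SimilarityMatrix:
    """Pairwise sigmoid kernel of interaction profiles along one axis.

    Entry (i, j) is ``tanh(scale * <p_i, p_j> + offset)`` where the profiles
    are the columns (drugs) or rows (diseases) of the association matrix.
    The default scale is the reciprocal of the profile length, so entries
    stay within [0, tanh(1)] for binary profiles.
    """
    P, ids = _profiles(A, axis)
    if P.shape[1] == 0:
        raise ValueError(f"empty profile dimension for axis {axis!r}")
    scale = 1.0 / P.shape[1] if params.scale is None else params.scale
    G = P @ P.T
    K = np.tanh(scale * G + params.offset)
    K = (K + K.T) / 2.0  # exact symmetry despite float round-off
    return SimilarityMatrix(ids, K)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a & b| / |a | b| of two binary bit vectors (0 on empty union)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def _fingerprints(catalog: DrugCatalog, n_bits: int) -> tuple[np.ndarray, np.ndarray]:
    """Path-based fingerprints as a (n_drugs, n_bits) boolean matrix + validity mask."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    n = len(catalog.drug_ids)
    bits = np.zeros((n, n_bits), dtype=bool)
    valid = np.zeros(n, dtype=bool)
    for k, drug_id in enumerate(catalog.drug_ids):
        smi = catalog.smiles.get(drug_id)
        if not smi:
            logger.warning("drug %s has no SMILES; structure similarity row set to 0", drug_id)
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("unparseable SMILES for drug %s; similarity row set to 0", drug_id)
            continue
        fp = gen.GetFingerprint(mol)
        bits[k, list(fp.GetOnBits())] = True
        valid[k] = True
    return bits, valid


def tanimoto_structure_similarity(
    catalog: DrugCatalog, n_bits: int = 2048
) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity of path-based molecular fingerprints.

    Drugs with missing or unparseable SMILES get 0 against every other drug;
    the fusion step can still supply kernel similarity for them.  The
    diagonal is 1 throughout.
    """
    if not catalog.drug_ids:
        raise ValueError("empty drug catalog")
    bits, valid = _fingerprints(catalog, n_bits)
    B = bits.astype(np.int64)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    S[~valid, :] = 0.0
    S[:, ~valid] = 0.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(catalog.drug_ids), S)


def logistic_adjust(
    S: SimilarityMatrix, params: LogisticParams = LogisticParams()
) -> SimilarityMatrix:
    """Apply the logistic rescaling element-wise off the diagonal.

    The diagonal (self-similarity) is preserved at its input value; with a
    negative slope the map is monotone increasing, so the ordering of
    similarities is unchanged while the contrast is sharpened.
    """
    values = np.asarray(params(S.values), dtype=float)
    np.fill_diagonal(values, np.diag(S.values))
    return SimilarityMatrix(list(S.entity_ids), values)


def build_coassociation_graph(A: AssociationMatrix, axis: str) -> nx.Graph:
    """Weighted co-association graph over drugs or diseases.

    Vertices are the entities of the chosen axis; an edge joins two entities
    that share at least one association partner, weighted by the number of
    shared partners (the off-diagonal of P P^T for binary profiles P).
    """
    P, ids = _profiles(A, axis)
    W = (P @ P.T).astype(int)
    G = nx.Graph()
    G.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(ids[i], ids[j], weight=int(W[i, j]))
    return G


def cohesiveness(G: nx.Graph, C, penalty_per_vertex: float = 2.0) -> float:
    """Cohesiveness f(C) = W_in / (W_in + W_bound + penalty_per_vertex * |C|).

    W_in is the total weight of edges internal to the vertex set C and
    W_bound the total weight of edges crossing its boundary; the per-vertex
    penalty models unobserved incident edges and keeps tiny sets from
    scoring 1.
    """
    C = set(C)
    w_in = 0.0
    w_bound = 0.0
    for u in C:
        for v, data in G[u].items():
            w = data.get("weight", 1.0)
            if v in C:
                w_in += w / 2.0  # each internal edge visited from both ends
            else:
                w_bound += w
    denom = w_in + w_bound + penalty_per_vertex * len(C)
    return w_in / denom if denom > 0 else 0.0


@dataclass
class ClusterSet:
    """Overlapping vertex clusters with their cohesiveness scores."""

    clusters: list[frozenset] = field(default_factory=list)
    cohesiveness: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.clusters) != len(self.cohesiveness):
            raise ValueError("clusters and cohesiveness lists differ in length")
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("empty cluster")

    def membership(self) -> dict:
        """Vertex -> set of cluster indices (overlap allowed)."""
        m: dict = {}
        for k, c in enumerate(self.clusters):
            for v in c:
                m.setdefault(v, set()).add(k)
        return m

    def __len__(self) -> int:
        return len(self.clusters)


class _GrowState:
    """Incremental W_in / W_bound bookkeeping for greedy cluster growth."""

    def __init__(self, G: nx.Graph, seed, penalty: float):
        self.G = G
        self.penalty = penalty
        self.members: set = {seed}
        self.w_in = 0.0
        self.w_bound = 0.0
        # link[v] = total edge weight from outside vertex v into the cluster
        self.link: dict = {}
        for v, data in G[seed].items():
            w = data.get("weight", 1.0)
            self.link[v] = self.link.get(v, 0.0) + w
            self.w_bound += w

    def f(self) -> float:
        denom = self.w_in + self.w_bound + self.penalty * len(self.members)
        return self.w_in / denom if denom > 0 else 0.0

    def f_after_add(self, v) -> float:
        lv = self.link.get(v, 0.0)
        ext = sum(d.get("weight", 1.0) for u, d in self.G[v].items() if u not in self.members)
        w_in = self.w_in + lv
        w_bound = self.w_bound - lv + ext
        denom = w_in + w_bound + self.penalty * (len(self.members) + 1)
        return w_in / denom if denom > 0 else 0.0

    def f_after_remove(self, v) -> float:
        internal = sum(d.get("weight", 1.0) for u, d in self.G[v].items() if u in self.members)
        ext = sum(d.get("weight", 1.0) for u, d in self.G[v].items() if u not in self.members)
        w_in = self.w_in - internal
        w_bound = self.w_bound + internal - ext
        denom = w_in + w_bound + self.penalty * (len(self.members) - 1)
        return w_in / denom if denom > 0 else 0.0

    def add(self, v) -> None:
        for u, data in self.G[v].items():
            w = data.get("weight", 1.0)
            if u in self.members:
                self.w_in += w
                self.w_bound -= w
            else:
                self.w_bound += w
                self.link[u] = self.link.get(u, 0.0) + w
        self.members.add(v)
        self.link.pop(v, None)

    def remove(self, v) -> None:
        self.members.discard(v)
        lv = 0.0
        for u, data in self.G[v].items():
            w = data.get("weight", 1.0)
            if u in self.members:
                self.w_in -= w
                self.w_bound += w
                lv += w
            else:
                self.w_bound -= w
                self.link[u] = self.link.get(u, 0.0) - w
                if self.link[u] <= 0:
                    del self.link[u]
        if lv > 0:
            self.link[v] = lv


_EPS = 1e-12


def cluster_one(
    G: nx.Graph,
    penalty_per_vertex: float = 2.0,
    density_threshold: float = 0.0,
    overlap_threshold: float = 0.8,
) -> ClusterSet:
    """Greedy cohesive-module detection on a weighted graph.

    Seeds are taken in descending weighted-degree order (lexicographic
    tie-break).  Each unclaimed seed starts as a singleton which grows by
    the single add/remove move that most increases the cohesiveness f(C),
    until no move improves it.  Grown groups whose overlap score
    ``|C1 n C2|^2 / (|C1| |C2|)`` exceeds ``overlap_threshold`` are merged
    (transitively), groups whose internal edge density falls below
    ``density_threshold`` are discarded, and each surviving cluster is
    reported with its recomputed cohesiveness.  Fully deterministic.
    """
    if penalty_per_vertex <= 0:
        raise ValueError("penalty_per_vertex must be positive")
    if G.number_of_nodes() == 0:
        return ClusterSet([], [])

    wdeg = {v: sum(d.get("weight", 1.0) for _, d in G[v].items()) for v in G.nodes}
    order = sorted(G.nodes, key=lambda v: (-wdeg[v], str(v)))
    claimed: set = set()
    grown: list[frozenset] = []

    for seed in order:
        if seed in claimed:
            continue
        st = _GrowState(G, seed, penalty_per_vertex)
        while True:
            f0 = st.f()
            best_gain = _EPS
            best_move = None  # (0=add, 1=remove, vertex); adds win ties by loop order
            for v in sorted(st.link, key=str):
                gain = st.f_after_add(v) - f0
                if gain > best_gain + _EPS:
                    best_gain, best_move = gain, (0, v)
            if len(st.members) > 1:
                for v in sorted(st.members, key=str):
                    gain = st.f_after_remove(v) - f0
                    if gain > best_gain + _EPS:
                        best_gain, best_move = gain, (1, v)
            if best_move is None:
                break
            if best_move[0] == 0:
                st.add(best_move[1])
            else:
                st.remove(best_move[1])
        cluster = frozenset(st.members)
        grown.append(cluster)
        claimed |= cluster

    # transitive merge of heavily-overlapping clusters
    merged = _merge_overlapping(grown, overlap_threshold)

    clusters: list[frozenset] = []
    scores: list[float] = []
    for c in merged:
        if len(c) >= 2:
            w_in = sum(
                d.get("weight", 1.0)
                for u, v, d in G.subgraph(c).edges(data=True)
            )
            density = 2.0 * w_in / (len(c) * (len(c) - 1))
        else:
            density = 0.0
        if density < density_threshold:
            continue
        clusters.append(c)
        scores.append(cohesiveness(G, c, penalty_per_vertex))
    return ClusterSet(clusters, scores)


def _merge_overlapping(groups: list[frozenset], threshold: float) -> list[frozenset]:
    if not groups:
        return []
    n = len(groups)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            inter = len(groups[i] & groups[j])
            if inter == 0:
                continue
            score = inter * inter / (len(groups[i]) * len(groups[j]))
            if score > threshold:
                parent[find(j)] = find(i)
    out: dict[int, set] = {}
    for i in range(n):
        out.setdefault(find(i), set()).update(groups[i])
    # deterministic order: by first seed index
    merged = [frozenset(out[r]) for r in sorted(out)]
    # drop exact duplicates while keeping order
    seen: set = set()
    uniq = []
    for c in merged:
        if c not in seen:
            uniq.append(c)
            seen.add(c)
    return uniq


def enhance_similarity(S: SimilarityMatrix, clusters: ClusterSet) -> SimilarityMatrix:
    """Boost similarity of pairs sharing a cohesive module.

    A pair co-resident in at least one cluster C has its similarity
    multiplied by (1 + f(C)), taking the maximum f over shared clusters;
    other pairs are unchanged.  Any resulting value at or above the cap is
    emitted as exactly 0.99, which also makes the cap idempotent.
    """
    values = S.values.copy()
    idx = {e: i for i, e in enumerate(S.entity_ids)}
    n = values.shape[0]
    boost = np.zeros((n, n))
    for c, f in zip(clusters.clusters, clusters.cohesiveness):
        members = [idx[v] for v in c if v in idx]
        if len(members) < 2:
            continue
        sel = np.ix_(members, members)
        boost[sel] = np.maximum(boost[sel], f)
    np.fill_diagonal(boost, 0.0)
    values = values * (1.0 + boost)
    values = np.minimum(values, SIMILARITY_CAP)
    return SimilarityMatrix(list(S.entity_ids), values)


def fuse_similarity(
    kernel: SimilarityMatrix,
    side: SimilarityMatrix,
    A: AssociationMatrix,
    axis: str,
) -> SimilarityMatrix:
    """Per-pair choice between kernel and structure/semantic similarity.

    A pair takes the kernel value when both entities have a non-empty
    interaction profile in the (training-view) association matrix; an entity
    with no known associations has an uninformative all-zero profile, so the
    enhanced side similarity is used instead.  The diagonal follows the side
    matrix's convention; output is clipped to the 0.99 cap.
    """
    P, ids = _profiles(A, axis)
    if kernel.entity_ids != ids or side.entity_ids != ids:
        raise IdentifierError(f"kernel/side/association identifiers disagree on axis {axis!r}")
    has_profile = P.sum(axis=1) > 0
    mask = np.outer(has_profile, has_profile)
    values = np.where(mask, kernel.values, side.values)
    np.fill_diagonal(values, np.diag(side.values))
    values = np.clip(values, 0.0, SIMILARITY_CAP)
    return SimilarityMatrix(ids, values)
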