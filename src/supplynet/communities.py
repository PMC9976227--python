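"""Community structure: modularity, seeded Louvain, dependence pairs.

Directed networks are symmetrized (A' = A + A^T) before modularity is
evaluated, matching the undirected treatment of the usual Louvain toolchain.
The Louvain implementation is the classic two-phase greedy scheme: seeded
best-gain local moves, then community aggregation, repeated until the
modularity gain of a full pass drops below tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedModularityError
from .trade_data import TradeFlowTable, TradeNetwork

__all__ = ["CommunityPartition", "DependencePair", "modularity", "louvain",
           "dependence_pairs", "symmetrized_matrix"]

_TOL = 1e-12


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity score.

    ``passes`` records the modularity after each aggregation level, which is
    non-decreasing by construction.
    """

    assignment: dict[str, int]
    q: float
    passes: list[float] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return out

    def labels(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.assignment[v] for v in nodes])


@dataclass
class DependencePair:
    """An importer drawing at least ``share`` >= theta of its imports from one supplier."""

    dependent: str
    supplier: str
    share: float


def symmetrized_matrix(net: TradeNetwork, weighted: bool = True) -> np.ndarray:
    """A' = A + A^T with A the weight matrix (or thresholded 0/1 adjacency)."""
    if weighted:
        a = net.weights.astype(float)
    elif net.binary is not None:
        a = net.binary.astype(float)
    else:
        a = (net.weights > 0).astype(float)
    return a + a.T


def modularity_matrix(w: np.ndarray, labels: np.ndarray,
                      resolution: float = 1.0) -> float:
    """Q of a labeling on a symmetric weight matrix (diagonal = 2x self-loop)."""
    two_m = w.sum()
    if two_m <= 0:
        raise UndefinedModularityError("modularity undefined: total weight is zero")
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = w[np.ix_(mask, mask)].sum()
        d_c = k[mask].sum()
        q += e_c / two_m - resolution * (d_c / two_m) ** 2
    return float(q)


def modularity(net: TradeNetwork, partition: dict[str, int],
               weighted: bool = True, resolution: float = 1.0) -> float:
    """Modularity Q of a partition of the (symmetrized) trade network."""
    missing = [v for v in net.nodes if v not in partition]
    if missing:
        raise ParameterError(f"partition misses nodes: {missing[:5]}")
    w = symmetrized_matrix(net, weighted=weighted)
    labels = np.array([partition[v] for v in net.nodes])
    return modularity_matrix(w, labels, resolution)


def _local_moves(w: np.ndarray, rng: np.random.Generator,
                 resolution: float,
                 init_labels: np.ndarray | None = None) -> np.ndarray:
    """One sweep phase: greedy best-gain single-node moves until stable.

    Candidate targets are the neighboring communities plus a fresh singleton
    (detaching can be the best move); ties go to the lowest community id so
    the only randomness is the seeded visit order.  Starts from singletons
    unless ``init_labels`` provides a partition to refine.
    """
    n = w.shape[0]
    labels = np.arange(n) if init_labels is None else init_labels.copy()
    two_m = w.sum()
    k = w.sum(axis=1)
    d_tot: dict[int, float] = {}
    size: dict[int, int] = {}
    for i in range(n):
        lab = int(labels[i])
        d_tot[lab] = d_tot.get(lab, 0.0) + float(k[i])
        size[lab] = size.get(lab, 0) + 1
    fresh = itertools.count(int(labels.max()) + 1)
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            a = int(labels[i])
            # weight from i to each community, excluding the self entry
            row = w[i].copy()
            row[i] = 0.0
            s_to: dict[int, float] = {}
            for j in np.nonzero(row)[0]:
                lab = int(labels[j])
                s_to[lab] = s_to.get(lab, 0.0) + float(row[j])
            s_a = s_to.get(a, 0.0)
            candidates = sorted(c for c in s_to if c != a)
            if size[a] > 1:
                candidates.append(-1)  # detach into a fresh singleton
            best_gain, best_c = _TOL, None
            for b in candidates:
                s_b = s_to.get(b, 0.0)
                d_b = 0.0 if b == -1 else d_tot[b]
                gain = (2.0 * (s_b - s_a) / two_m
                        - resolution * 2.0 * k[i]
                        * (d_b - d_tot[a] + k[i]) / two_m ** 2)
                if gain > best_gain:
                    best_gain, best_c = gain, b
            if best_c is not None:
                if best_c == -1:
                    best_c = next(fresh)
                    d_tot[best_c] = 0.0
                    size[best_c] = 0
                d_tot[a] -= float(k[i])
                d_tot[best_c] += float(k[i])
                size[a] -= 1
                size[best_c] += 1
                labels[i] = best_c
                improved = True
    return labels


def _aggregate(w: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    comms, dense = np.unique(labels, return_inverse=True)
    nc = len(comms)
    ind = np.zeros((nc, w.shape[0]))
    ind[dense, np.arange(w.shape[0])] = 1.0
    return ind @ w @ ind.T, dense


def louvain(net: TradeNetwork, weighted: bool = True, seed: int = 0,
            resolution: float = 1.0, restarts: int = 8,
            perturb_rounds: int = 6) -> CommunityPartition:
    """Seeded Louvain community detection on the symmetrized network.

    The greedy two-phase core (best-gain local moves, then community
    aggregation, repeated while Q improves) is wrapped in two quality
    safeguards: ``restarts`` independent runs seeded from ``seed``, and per
    run ``perturb_rounds`` of iterated local search (randomly reassign a
    fraction of nodes, re-run local moves, keep the result only if Q
    improves).  Both escape the local optima a single greedy pass can land
    in; everything is deterministic for a fixed seed.  Isolated nodes stay in
    singleton communities.  The returned ``q`` equals :func:`modularity`
    recomputed on the output.
    """
    if restarts < 1:
        raise ParameterError(f"restarts must be >= 1, got {restarts}")
    best: CommunityPartition | None = None
    for sub_seed in np.random.SeedSequence(seed).generate_state(restarts):
        part = _louvain_once(net, weighted, int(sub_seed), resolution,
                             perturb_rounds)
        if best is None or part.q > best.q + _TOL:
            best = part
    return best


def _louvain_once(net: TradeNetwork, weighted: bool, seed: int,
                  resolution: float, perturb_rounds: int = 0,
                  perturb_frac: float = 0.35) -> CommunityPartition:
    w = symmetrized_matrix(net, weighted=weighted)
    if w.sum() <= 0:
        raise UndefinedModularityError("cannot run Louvain on a zero-weight graph")
    rng = np.random.default_rng(seed)
    n = w.shape[0]
    membership = np.arange(n)  # original node -> current community
    level_w = w.copy()
    passes: list[float] = []
    q_prev = modularity_matrix(w, membership, resolution)
    while True:
        labels = _local_moves(level_w, rng, resolution)
        level_w, dense = _aggregate(level_w, labels)
        membership = dense[membership]
        q_now = modularity_matrix(w, membership, resolution)
        passes.append(q_now)
        if q_now - q_prev <= _TOL:
            break
        q_prev = q_now
    # node-level refinement on the original graph: aggregation freezes nodes
    # inside super-nodes, so the coarse result need not be single-move optimal
    refined = _local_moves(w, rng, resolution, init_labels=membership)
    q_ref = modularity_matrix(w, refined, resolution)
    if q_ref > passes[-1] + _TOL:
        membership = refined
        passes.append(q_ref)
    q_best = modularity_matrix(w, membership, resolution)
    for _ in range(perturb_rounds):
        shaken = membership.copy()
        idx = rng.random(n) < perturb_frac
        shaken[idx] = rng.integers(0, shaken.max() + 2, size=int(idx.sum()))
        shaken = _local_moves(w, rng, resolution, init_labels=shaken)
        q_shaken = modularity_matrix(w, shaken, resolution)
        if q_shaken > q_best + _TOL:
            membership, q_best = shaken, q_shaken
            passes.append(q_best)
    # renumber communities densely in node order
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for v, c in zip(net.nodes, membership):
        assignment[v] = remap.setdefault(int(c), len(remap))
    return CommunityPartition(assignment=assignment, q=q_best, passes=passes)


def dependence_pairs(flows: TradeFlowTable, year: int,
                     theta: float = 0.5) -> list[DependencePair]:
    """Importer/supplier pairs where one supplier covers >= theta of imports.

    With theta > 0.5 each importer can appear at most once.
    """
    if not (0 < theta <= 1):
        raise ParameterError(f"theta must be in (0, 1], got {theta}")
    out: list[DependencePair] = []
    for importer in flows.importers(year):
        supplies = flows.imports_by_supplier(importer, year)
        total = supplies.sum()
        if total <= 0:
            continue
        shares = (supplies / total).sort_index()
        for supplier, share in shares.items():
            if share >= theta:
                out.append(DependencePair(importer, str(supplier), float(share)))
    return out
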