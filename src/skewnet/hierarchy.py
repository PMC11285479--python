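"""Directed agonistic networks and social-control statistics.

For each social group in each year we build a directed, weighted network
whose entry (i, j) counts the agonistic acts individual *i* initiated
toward *j*.  Two families of statistics quantify how concentrated social
control is in the group:

Global reaching centrality (GRC)
    The local reaching centrality C_R(i) of a node is the fraction of the
    other N-1 group members reachable from it along directed paths — both
    direct targets of aggression and those dominated only indirectly.  The
    GRC aggregates the spread of reach across the group,

        GRC = sum_i (C_R_max - C_R(i)) / (N - 1),

    which is 0 for egalitarian, cycle-like structures (everyone reaches
    everyone) and 1 for a despotic out-star (one individual reaches all,
    nobody else reaches anyone).  Reachability is evaluated on the
    binarised graph by default: any aggression i -> j contributes a
    directed edge regardless of its count.  A weighted variant
    (edge-weight-scaled reach) is available behind a flag.

Dominance-hierarchy linearity (Landau's h, de Vries's h')
    Each dyad is classified win/loss (strict majority of directed acts),
    tie (equal non-zero counts) or unknown (no acts).  For a complete
    tournament, Landau's index

        h = 12 / (N^3 - N) * sum_i (S_i - (N - 1) / 2)^2

    (S_i = dyads won by i) is 1 for a perfectly linear hierarchy and 0 for
    maximal intransitivity.  With ties or unknowns, h' is the mean of h
    over random completions of the dominance matrix: each unknown dyad is
    assigned a uniform random direction and each tied dyad a fair-coin
    direction, 10 000 times by default.

Metrics require N >= 3 (the GRC is not defined for dyads); smaller groups
are flagged ineligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import networkx as nx
import numpy as np
import pandas as pd

from .grouping import GroupAssignment

log = logging.getLogger("skewnet")

MIN_GROUP_SIZE = 3
DEFAULT_N_PERMUTATIONS = 10_000


class Relation(IntEnum):
    """Dyadic dominance state from the directed act counts."""

    UNKNOWN = 0
    WIN = 1
    LOSS = 2
    TIE = 3


@dataclass
class AgonisticNetwork:
    """Directed weighted aggression network for one group-year.

    ``weights[i, j]`` counts agonistic acts initiated by ``ids[i]`` toward
    ``ids[j]``; the diagonal is zero.  ``eligible`` is False for groups of
    fewer than three adult females, for which the metrics are undefined.
    """

    ids: list[str]
    weights: np.ndarray
    year: int
    colony: str
    group_id: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("weights must be square and match ids")
        if (w < 0).any():
            raise ValueError("weights must be non-negative counts")
        if np.diag(w).any():
            raise ValueError("self-aggression is not a valid record")
        self.weights = w.astype(int)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def eligible(self) -> bool:
        return self.n >= MIN_GROUP_SIZE

    def digraph(self) -> nx.DiGraph:
        """Binarised directed graph: edge i -> j iff any act i -> j."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        src, dst = np.nonzero(self.weights)
        g.add_edges_from(
            (self.ids[i], self.ids[j], {"weight": int(self.weights[i, j])})
            for i, j in zip(src, dst)
        )
        return g


@dataclass
class HierarchyMetrics:
    grc: float
    local_reach: dict[str, float]
    h: float | None  # defined only for complete tournaments
    h_prime: float
    n_permutations: int
    seed: int
    group_id: str = ""
    year: int = 0
    colony: str = ""
    n_females: int = 0


def build_agonistic_network(filtered_interactions: pd.DataFrame,
                            group: GroupAssignment) -> AgonisticNetwork:
    """Count directed acts within one group from the filtered interaction set.

    Interactions whose two parties are not both group members are discarded
    (logged): aggression across group boundaries carries no information
    about within-group control.
    """
    ids = sorted(group.members)
    idx = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    weights = np.zeros((n, n), dtype=int)
    dropped = 0
    for _, row in filtered_interactions.iterrows():
        a, b = row["initiator_id"], row["recipient_id"]
        if a in idx and b in idx:
            weights[idx[a], idx[b]] += 1
        elif a in idx or b in idx:
            dropped += 1
    if dropped:
        log.info("group %s year %d: %d cross-group interaction(s) discarded",
                 group.group_id, group.year, dropped)
    net = AgonisticNetwork(ids=ids, weights=weights, year=group.year,
                           colony=group.colony, group_id=group.group_id)
    if not net.eligible:
        log.info("group %s year %d: N=%d < %d, ineligible for metrics",
                 group.group_id, group.year, n, MIN_GROUP_SIZE)
    return net


def local_reaching_centrality(net: AgonisticNetwork, node: str,
                              weighted: bool = False) -> float:
    """Fraction of other group members reachable from ``node``.

    With ``weighted=True`` each reachable member contributes the bottleneck
    capacity of the widest directed path from ``node`` to it, on weights
    normalised by the network maximum, instead of 1.  This discounts
    dominance chains supported by single observations; it is an alternative
    reach notion and NOT the default.
    """
    if node not in net.ids:
        raise ValueError(f"{node!r} not in network")
    if net.n < 2:
        raise ValueError("reach undefined for singleton networks")
    g = net.digraph()
    reachable = nx.descendants(g, node)
    if not weighted:
        return len(reachable) / (net.n - 1)
    if not reachable:
        return 0.0
    wmax = float(net.weights.max())
    # widest-path (max-min) capacities via Dijkstra on negated capacities
    # is not exact; with small N just take max over simple paths.
    total = 0.0
    for target in reachable:
        cap = max(
            min(g[u][v]["weight"] for u, v in zip(p, p[1:]))
            for p in nx.all_simple_paths(g, node, target)
        )
        total += cap / wmax
    return total / (net.n - 1)


def all_local_reach(net: AgonisticNetwork) -> dict[str, float]:
    g = net.digraph()
    return {v: len(nx.descendants(g, v)) / (net.n - 1) for v in net.ids}


def grc(net: AgonisticNetwork) -> float:
    """Global reaching centrality of one agonistic network.

    GRC = sum_i (C_R_max - C_R(i)) / (N - 1).  Requires N >= 3.  An
    all-zero network (no observed aggression) has all reaches 0 and GRC 0:
    egalitarian by absence of evidence, logged as low-information.
    """
    if net.n < MIN_GROUP_SIZE:
        raise ValueError(f"GRC requires N >= {MIN_GROUP_SIZE}, got N={net.n}")
    reach = all_local_reach(net)
    values = np.array([reach[v] for v in net.ids])
    if values.max() == 0:
        log.info("group %s year %d: no aggression observed, GRC = 0 "
                 "(low-information)", net.group_id, net.year)
        return 0.0
    return float((values.max() - values).sum() / (net.n - 1))


def dominance_relations(net: AgonisticNetwork) -> np.ndarray:
    """Dyadic relation matrix from the directed act counts.

    Entry (i, j) is WIN if i directed strictly more acts at j than vice
    versa, LOSS for the converse, TIE for equal non-zero counts and UNKNOWN
    when the dyad was never observed interacting.  The diagonal is UNKNOWN.
    """
    w = net.weights
    rel = np.full(w.shape, Relation.UNKNOWN, dtype=int)
    more = w > w.T
    rel[more] = Relation.WIN
    rel[more.T] = Relation.LOSS
    tied = (w == w.T) & (w > 0)
    rel[tied] = Relation.TIE
    np.fill_diagonal(rel, Relation.UNKNOWN)
    return rel


class IncompleteTournamentError(ValueError):
    """Raised when Landau's h is requested on a matrix with ties/unknowns."""


def _h_from_scores(scores: np.ndarray, n: int) -> np.ndarray:
    return 12.0 / (n**3 - n) * ((scores - (n - 1) / 2.0) ** 2).sum(axis=-1)


def landau_h(relations: np.ndarray) -> float:
    """Landau's linearity index for a complete dominance tournament.

    Raises :class:`IncompleteTournamentError` when any dyad is tied or
    unknown; use :func:`landau_h_prime` for such matrices.
    """
    rel = np.asarray(relations)
    n = rel.shape[0]
    off = ~np.eye(n, dtype=bool)
    if ((rel[off] == Relation.TIE) | (rel[off] == Relation.UNKNOWN)).any():
        raise IncompleteTournamentError(
            "matrix contains tied or unknown dyads; use landau_h_prime")
    scores = (rel == Relation.WIN).sum(axis=1).astype(float)
    return float(_h_from_scores(scores, n))


def landau_h_prime(relations: np.ndarray, n_perm: int = DEFAULT_N_PERMUTATIONS,
                   seed: int = 0) -> float:
    """De Vries's corrected linearity index h'.

    Mean of Landau's h over ``n_perm`` random completions of the dominance
    matrix: every unknown dyad gets a uniform random direction and every
    tied dyad a fair-coin direction.  One seeded generator per call; free
    dyads are filled in fixed row-major order, so results are
    bit-reproducible for a given seed.  Collapses to h exactly when the
    tournament is already complete.
    """
    rel = np.asarray(relations)
    n = rel.shape[0]
    if n < MIN_GROUP_SIZE:
        raise ValueError(f"h' requires N >= {MIN_GROUP_SIZE}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base_scores = (rel == Relation.WIN).sum(axis=1).astype(float)
    free = [(i, j) for i in range(n) for j in range(i + 1, n)
            if rel[i, j] in (Relation.TIE, Relation.UNKNOWN)]
    if not free:
        return float(_h_from_scores(base_scores, n))
    rng = np.random.default_rng(seed)
    wins_i = rng.random((n_perm, len(free))) < 0.5  # True: lower index wins
    scores = np.tile(base_scores, (n_perm, 1))
    for k, (i, j) in enumerate(free):
        scores[:, i] += wins_i[:, k]
        scores[:, j] += ~wins_i[:, k]
    return float(_h_from_scores(scores, n).mean())


def compute_metrics(net: AgonisticNetwork, n_perm: int = DEFAULT_N_PERMUTATIONS,
                    seed: int = 0) -> HierarchyMetrics:
    """GRC, local reach and h' for one eligible network."""
    if not net.eligible:
        raise ValueError(f"group {net.group_id}: N={net.n} < {MIN_GROUP_SIZE}")
    rel = dominance_relations(net)
    try:
        h: float | None = landau_h(rel)
    except IncompleteTournamentError:
        h = None
    return HierarchyMetrics(
        grc=grc(net),
        local_reach=all_local_reach(net),
        h=h,
        h_prime=landau_h_prime(rel, n_perm=n_perm, seed=seed),
        n_permutations=n_perm,
        seed=seed,
        group_id=net.group_id,
        year=net.year,
        colony=net.colony,
        n_females=net.n,
    )


def metrics_to_frame(metrics: list[HierarchyMetrics]) -> pd.DataFrame:
    """Tidy table, one row per group-year."""
    return pd.DataFrame(
        [
            {"group_id": m.group_id, "colony": m.colony, "year": m.year,
             "n_females": m.n_females, "grc": m.grc, "h": m.h,
             "h_prime": m.h_prime, "n_permutations": m.n_permutations,
             "seed": m.seed}
            for m in metrics
        ],
        columns=["group_id", "colony", "year", "n_females", "grc", "h",
                 "h_prime", "n_permutations", "seed"],
    )


def network_to_edgelist(net: AgonisticNetwork) -> pd.DataFrame:
    """Edge-list form (year, colony, group_id, initiator, recipient, count)."""
    src, dst = np.nonzero(net.weights)
    return pd.DataFrame(
        [
            {"year": net.year, "colony": net.colony, "group_id": net.group_id,
             "initiator": net.ids[i], "recipient": net.ids[j],
             "count": int(net.weights[i, j])}
            for i, j in zip(src, dst)
        ],
        columns=["year", "colony", "group_id", "initiator", "recipient", "count"],
    )
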