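"""Association indices and map-equation social-group detection.

Social groups are inferred from space-use overlap: the simple-ratio index
(SRI) between two individuals is the fraction of sampling days on which they
were associated, given that at least one of them was observed,

    SRI = x / (x + y_A + y_B + y_AB),

where ``x`` counts days both were seen together (same location, same day),
``y_A``/``y_B`` days only one was seen, and ``y_AB`` days both were seen but
apart.  The annual SRI matrix is then partitioned by minimising the
two-level map equation — the expected per-step description length of a
random walk on the weighted association graph under a two-level (module +
within-module) code:

    L(M) = q * H(Q) + sum_m p_m * H(P_m)

with node visit rates proportional to node strength, ``q`` the total
module-exit rate, ``H(Q)`` the entropy of the exit-rate distribution and
``H(P_m)`` the entropy of module *m*'s within-module code (its nodes' visit
rates plus its exit rate).  Partitions that trap the walk inside densely
associated sets compress the walk best, and those sets are the social
groups.

The optimiser is a seeded greedy agglomeration: repeated node-move sweeps in
seeded random order, followed by module aggregation, until no move lowers
the codelength.  Determinism (same input + seed -> same partition) is part
of the contract; ties are broken toward the lowest module index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AssociationMatrix:
    """Symmetric SRI matrix for one year's individuals.

    ``values[i, j]`` is the simple-ratio index between ``ids[i]`` and
    ``ids[j]``; entries lie in [0, 1], the diagonal is ignored (held at 0)
    and dyads with no observation days are stored as 0.
    """

    ids: list[str]
    values: np.ndarray
    year: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("values must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValueError("association matrix must be symmetric")
        off = v[~np.eye(len(self.ids), dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("association indices must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, year: int) -> "AssociationMatrix":
        return cls(ids=list(df.index), values=df.to_numpy(dtype=float), year=year)


@dataclass
class GroupAssignment:
    """One detected social group: a set of individuals in a colony-year."""

    year: int
    colony: str
    group_id: str
    members: frozenset[str]


def _daily_presence(copresence: pd.DataFrame) -> pd.DataFrame:
    df = copresence.copy()
    df["day"] = pd.to_datetime(df["date"]).dt.normalize()
    return df[["individual_id", "day", "location"]].drop_duplicates()


def simple_ratio_index(copresence: pd.DataFrame, id_a: str, id_b: str) -> float:
    """Simple-ratio association index between two individuals.

    The sampling period is one calendar day; two individuals are "together"
    on a day if they share at least one recorded location that day.
    Returns ``nan`` (distinct from 0) if neither individual was ever
    observed.
    """
    daily = _daily_presence(copresence)
    a = daily[daily["individual_id"] == id_a]
    b = daily[daily["individual_id"] == id_b]
    days_a = set(a["day"])
    days_b = set(b["day"])
    if not days_a and not days_b:
        return float("nan")
    together = 0
    for day in days_a & days_b:
        if set(a.loc[a["day"] == day, "location"]) & set(b.loc[b["day"] == day, "location"]):
            together += 1
    either = len(days_a | days_b)
    return together / either


def association_matrix(copresence: pd.DataFrame, ids: list[str], year: int
                       ) -> AssociationMatrix:
    """Annual SRI matrix over ``ids`` from a co-presence log.

    Vectorised equivalent of calling :func:`simple_ratio_index` on every
    dyad; unobserved dyads get 0.
    """
    daily = _daily_presence(copresence)
    daily = daily[daily["individual_id"].isin(ids)]
    idx = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    # day-level presence and (day, location)-level presence indicators
    seen = {}       # id -> set of days
    seen_at = {}    # id -> set of (day, location)
    for ind, sub in daily.groupby("individual_id"):
        seen[ind] = set(sub["day"])
        seen_at[ind] = set(zip(sub["day"], sub["location"]))
    values = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            b = ids[j]
            da, db = seen.get(a, set()), seen.get(b, set())
            either = len(da | db)
            if either == 0:
                continue
            shared_days = {day for (day, loc) in seen_at.get(a, set())
                           if (day, loc) in seen_at.get(b, set())}
            values[i, j] = values[j, i] = len(shared_days) / either
    return AssociationMatrix(ids=list(ids), values=values, year=year)


def _plogp(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def map_equation_codelength(weights: np.ndarray, partition: np.ndarray) -> float:
    """Two-level map-equation codelength, in bits per walk step.

    ``weights`` is a symmetric non-negative matrix (diagonal ignored);
    ``partition`` assigns a module label to every node.  Visit rates are
    strength-proportional (the stationary distribution of the undirected
    walk); nodes of zero strength contribute nothing.

    Raises
    ------
    ValueError
        If the graph is empty, the partition does not cover all nodes, or
        the total weight is zero (codelength undefined for a walk with no
        moves).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty graph: codelength undefined")
    part = np.asarray(partition)
    if part.shape[0] != w.shape[0]:
        raise ValueError("partition must assign a module to every node")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    strength = w.sum(axis=1)
    total = strength.sum()
    if total == 0:
        raise ValueError("graph has no edges: codelength undefined")
    p = strength / total

    modules = np.unique(part)
    q_m = np.empty(len(modules))
    within_terms = 0.0
    for k, m in enumerate(modules):
        members = part == m
        exit_w = w[np.ix_(members, ~members)].sum()
        q_m[k] = exit_w / total
        p_in = p[members]
        p_tot = q_m[k] + p_in.sum()
        if p_tot > 0:
            h = -(_plogp(np.append(p_in, q_m[k]) / p_tot)).sum()
            within_terms += p_tot * h
    q = q_m.sum()
    between_term = 0.0
    if q > 0:
        between_term = q * -(_plogp(q_m / q)).sum()
    return float(between_term + within_terms)


def _node_sweeps(w: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                 start_l: float) -> float:
    """Node-move sweeps in seeded random order until no move lowers L.

    Mutates ``labels`` in place; ties break toward the lowest module index.
    Returns the final codelength.
    """
    n = w.shape[0]
    best = start_l
    improved = True
    while improved:
        improved = False
        for node in rng.permutation(n):
            current = labels[node]
            neighbour_mods = np.unique(labels[w[node] > 0])
            candidates = sorted(set(int(m) for m in neighbour_mods) - {int(current)})
            best_move, best_l = current, best
            for cand in candidates:
                labels[node] = cand
                l = map_equation_codelength(w, labels)
                if l < best_l - 1e-12:
                    best_move, best_l = cand, l
            labels[node] = best_move
            if best_move != current:
                best = best_l
                improved = True
    return best


def _merge_pass(w: np.ndarray, labels: np.ndarray, start_l: float) -> float:
    """Merge connected module pairs while any merge lowers L (in place)."""
    best = start_l
    improved = True
    while improved:
        improved = False
        mods = sorted(int(m) for m in np.unique(labels))
        best_pair, best_l = None, best
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                link = w[np.ix_(labels == a, labels == b)].sum()
                if link == 0:
                    continue
                trial = labels.copy()
                trial[trial == b] = a
                l = map_equation_codelength(w, trial)
                if l < best_l - 1e-12:
                    best_pair, best_l = (a, b), l
        if best_pair is not None:
            a, b = best_pair
            labels[labels == b] = a
            best = best_l
            improved = True
    return best


def detect_groups(assoc: AssociationMatrix, seed: int, colony: str = "C0"
                  ) -> list[GroupAssignment]:
    """Partition an association matrix into social groups.

    Greedy two-level map-equation minimisation: seeded node-move sweeps
    alternating with whole-module merge passes until the codelength stops
    improving, then a guard comparison against the single-module partition
    (whichever codes the walk shorter wins).  Deterministic for a fixed
    seed.  Nodes of zero strength (never associated) become singleton
    groups, as does everything when the matrix is all-zero.
    """
    w = assoc.values
    n = len(assoc.ids)
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    if w.sum() == 0:
        labels = np.arange(n)
    else:
        labels = np.arange(n)
        # isolate zero-strength nodes; run the optimiser on the rest
        strength = w.sum(axis=1)
        active = np.flatnonzero(strength > 0)
        sub = w[np.ix_(active, active)]
        sub_labels = np.arange(len(active))
        l = map_equation_codelength(sub, sub_labels)
        while True:
            l = _node_sweeps(sub, sub_labels, rng, l)
            l_after = _merge_pass(sub, sub_labels, l)
            if l_after >= l - 1e-12:
                break
            l = l_after
        # guard: never report a partition worse than the one-module code
        one = np.zeros(len(active), dtype=int)
        if map_equation_codelength(sub, one) < l - 1e-12:
            sub_labels = one
        offset = n  # keep singleton labels of inactive nodes distinct
        labels[active] = sub_labels + offset
    # canonical group ids ordered by first member position
    groups: dict[int, list[str]] = {}
    for pos, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(assoc.ids[pos])
    ordered = sorted(groups.values(), key=lambda mem: assoc.ids.index(mem[0]))
    return [
        GroupAssignment(year=assoc.year, colony=colony, group_id=f"{colony}-G{k + 1}",
                        members=frozenset(mem))
        for k, mem in enumerate(ordered)
    ]


def assignments_to_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    """Long-format table (year, colony, group_id, individual_id)."""
    rows = [
        {"year": g.year, "colony": g.colony, "group_id": g.group_id,
         "individual_id": member}
        for g in assignments for member in sorted(g.members)
    ]
    return pd.DataFrame(rows, columns=["year", "colony", "group_id", "individual_id"])
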