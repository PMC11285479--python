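"""The multinomial reproductive-skew index M.

The M index asks how unevenly reproduction is distributed over the adult
females of a breeding group, relative to their exposure (time at risk),
after discounting the skew that random (multinomial) reproduction would
produce by chance in a group of that size and productivity.

For a group of N females with offspring counts s_i (group total S) and
exposures e_i (total E), the raw deviation statistic is

    M_raw = N * sum_i (s_i / S - e_i / E)^2

and the index is the chance-corrected

    M = M_raw - E[M_raw | null],

where the null assigns each of the S offspring independently to mother i
with probability p_i = e_i / E.  Under that multinomial null,
Var(s_i / S) = p_i (1 - p_i) / S and E[(s_i/S - p_i)^2] is exactly that
variance, so the correction has the closed form

    E[M_raw | null] = N * (1 - sum_i p_i^2) / S.

M = 0 therefore means "no more skew than chance", positive values mean
reproduction is more concentrated than random, and mildly negative values
can arise when reproduction is *more even* than random allocation
(e.g. every female weans exactly her expected share).

Groups need at least three adult females (the eligibility rule shared with
the network metrics) and at least one weaned offspring; zero-offspring
females are included — non-breeders are exactly what skew is about.
:func:`null_m_distribution` provides the Monte-Carlo oracle used to
validate the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_BREEDING_GROUP = 3


@dataclass
class SkewResult:
    group_id: str
    year: int
    n_females: int
    total_offspring: int
    m_index: float
    m_raw: float
    null_expectation: float


def m_index(offspring, exposure=None, group_id: str = "", year: int = 0
            ) -> SkewResult:
    """Chance-corrected multinomial skew index for one breeding group.

    Parameters
    ----------
    offspring
        Per-female weaned-offspring counts (length >= 3, total >= 1).
    exposure
        Per-female time at risk; defaults to equal exposure (1.0 each).

    Raises
    ------
    ValueError
        For groups below the eligibility size, all-zero offspring, or
        non-positive exposures.
    """
    s = np.asarray(offspring, dtype=float)
    if s.ndim != 1 or len(s) < MIN_BREEDING_GROUP:
        raise ValueError(
            f"breeding groups need >= {MIN_BREEDING_GROUP} females, got {len(s)}")
    if (s < 0).any():
        raise ValueError("offspring counts must be non-negative")
    total = s.sum()
    if total < 1:
        raise ValueError("M undefined for a group with no offspring")
    if exposure is None:
        e = np.ones_like(s)
    else:
        e = np.asarray(exposure, dtype=float)
        if e.shape != s.shape:
            raise ValueError("exposure must match offspring in length")
        if (e <= 0).any():
            raise ValueError("exposures must be positive")
    n = len(s)
    p = e / e.sum()
    m_raw = n * float(((s / total - p) ** 2).sum())
    null = n * (1.0 - float((p**2).sum())) / total
    return SkewResult(
        group_id=group_id, year=year, n_females=n,
        total_offspring=int(round(total)),
        m_index=m_raw - null, m_raw=m_raw, null_expectation=null,
    )


def null_m_distribution(n_females: int, exposure, total_offspring: int,
                        n_sims: int, seed: int) -> np.ndarray:
    """Monte-Carlo draws of M_raw under exposure-proportional reproduction.

    Simulation oracle for the closed-form null expectation: draws
    ``n_sims`` offspring vectors from Multinomial(total_offspring,
    e / sum(e)) and returns the M_raw of each.  The empirical mean should
    match :func:`m_index`'s ``null_expectation`` within Monte-Carlo error.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    e = np.asarray(exposure, dtype=float)
    if len(e) != n_females:
        raise ValueError("exposure must have one entry per female")
    p = e / e.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total_offspring, p, size=n_sims)
    shares = draws / total_offspring
    return n_females * ((shares - p) ** 2).sum(axis=1)


def skew_table(reproduction: pd.DataFrame, assignments: pd.DataFrame
               ) -> pd.DataFrame:
    """SkewResult rows for every eligible breeding group-year.

    ``assignments`` is the long-format group table (year, colony, group_id,
    individual_id); mothers are matched on (individual_id, year).  Group
    members absent from the reproduction table count as zero-offspring
    females with the default exposure.  Groups of fewer than three females
    or with no offspring at all are skipped.
    """
    rep = reproduction.set_index(["mother_id", "year"])
    rows = []
    for (year, colony, group_id), sub in assignments.groupby(
            ["year", "colony", "group_id"]):
        members = sorted(sub["individual_id"])
        if len(members) < MIN_BREEDING_GROUP:
            continue
        offspring, exposure = [], []
        for m in members:
            if (m, year) in rep.index:
                offspring.append(int(rep.loc[(m, year), "offspring"]))
                exposure.append(float(rep.loc[(m, year), "exposure"]))
            else:
                offspring.append(0)
                exposure.append(1.0)
        if sum(offspring) < 1:
            continue
        res = m_index(offspring, exposure, group_id=group_id, year=year)
        rows.append({"group_id": group_id, "colony": colony, "year": year,
                     "n_females": res.n_females,
                     "total_offspring": res.total_offspring,
                     "m_index": res.m_index, "m_raw": res.m_raw,
                     "null_expectation": res.null_expectation})
    return pd.DataFrame(rows, columns=["group_id", "colony", "year", "n_females",
                                       "total_offspring", "m_index", "m_raw",
                                       "null_expectation"])
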