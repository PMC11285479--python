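"""Synthetic colony generator with tunable despotism-skew coupling.

Emits the exact four CSV schemas the pipeline consumes (registry,
co-presence, interactions, reproduction) for a configurable number of
colonies and years, plus a ground-truth sidecar that the pipeline never
reads.  The generative model, per social group:

* Group sizes are drawn from a negative binomial truncated to 3..11,
  parameterised to match field-like summaries (mean ~4.7, s.d. ~2.6).
* Females carry latent ranks 1..N (1 = most dominant).  A despotism
  parameter delta >= 0 shapes aggression two ways: initiation propensity
  decays down the hierarchy as exp(-delta * (rank - 1)), and the direction
  of each dyad's acts follows a logistic bias sigma(delta * (rank_j -
  rank_i)).  At delta = 0 acts flow symmetrically in both directions
  (cyclic, egalitarian structure; GRC near 0); at large delta only the top
  female initiates and all acts run down-hierarchy (out-star; GRC near 1).
  Dyad counts are Poisson with mean interaction_rate per dyad, so matrices
  naturally contain tied and unknown relationships.
* Co-presence places group members at a shared home location on most
  observation days (within-group SRI high) with occasional visits to a
  colony-wide location (between-group SRI low but non-zero).
* Reproduction: the group total is Poisson(N * mean_litter) and offspring
  are allocated Dirichlet-multinomially with concentration weights
  proportional to exp(-kappa * delta * (rank - 1)).  kappa couples skew to
  despotism (kappa = 0 is the null world).  Colony- and year-level
  intercepts act on the log total concentration — lower concentration
  means noisier, more skewed allocations — giving the mixed model real
  random-effect variance to recover.

A separate row-level simulator, :func:`simulate_group_year_rows`, generates
analysis-ready group-year tables with an explicit standardised-scale
coefficient structure; it is the tool for power and coverage studies of
the inference stage, where a target coefficient (not a latent coupling)
must be planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import records as rec


@dataclass
class SyntheticConfig:
    """Study-design knobs for the record-level generator."""

    n_colonies: int = 3
    n_years: int = 6
    groups_per_colony_year: int = 2
    #: negative binomial (n, p) before truncation to the observed 3..11 range;
    #: matches the field mean (~4.7); truncation caps the spread near 1.9
    group_size_nbinom: tuple[float, float] = (0.9, 0.33)
    group_size_range: tuple[int, int] = (3, 11)
    #: per-group despotism delta ~ Uniform(low, high)
    despotism_range: tuple[float, float] = (0.0, 2.0)
    #: coupling of skew to despotism; 0 = null world
    coupling: float = 1.0
    #: mean agonistic acts per ordered dyad (aggression is rare)
    interaction_rate: float = 1.5
    #: s.d. of colony and year intercepts on the log-concentration scale
    colony_sd: float = 0.3
    year_sd: float = 0.3
    #: baseline log total Dirichlet concentration (higher = less noise)
    log_concentration: float = 1.6
    #: mean weaned offspring per female
    mean_litter: float = 1.5
    #: per-female daily detection probability at the home location
    detection_prob: float = 0.7
    n_observation_days: int = 20
    first_year: int = 2003
    seed: int = 0


@dataclass
class SyntheticData:
    """Generated record set plus the ground truth behind it."""

    registry: pd.DataFrame
    copresence: pd.DataFrame
    interactions: pd.DataFrame
    reproduction: pd.DataFrame
    truth_groups: pd.DataFrame   # group_id, colony, year, delta, kappa, n_females
    truth_ranks: pd.DataFrame    # individual_id, year, group_id, rank

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rec.write_records(self.registry, outdir / "registry.csv", "registry")
        rec.write_records(self.copresence, outdir / "copresence.csv", "copresence")
        rec.write_records(self.interactions, outdir / "interactions.csv",
                          "interactions")
        rec.write_records(self.reproduction, outdir / "reproduction.csv",
                          "reproduction")
        self.truth_groups.to_csv(outdir / "truth_groups.csv", index=False)
        self.truth_ranks.to_csv(outdir / "truth_ranks.csv", index=False)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def draw_group_sizes(n: int, rng: np.random.Generator,
                     nbinom: tuple[float, float] = (0.9, 0.33),
                     bounds: tuple[int, int] = (3, 11)) -> np.ndarray:
    """Group sizes from a truncated negative binomial (rejection sampling)."""
    lo, hi = bounds
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.negative_binomial(nbinom[0], nbinom[1], size=4 * n) + lo
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate_colony_data(config: SyntheticConfig) -> SyntheticData:
    """Generate a full multi-colony, multi-year synthetic record set.

    Deterministic for a fixed ``config.seed`` (byte-identical CSVs via
    :meth:`SyntheticData.write`).
    """
    if config.interaction_rate == 0 and config.despotism_range[1] > 0:
        import warnings
        warnings.warn("interaction_rate = 0: networks will be empty and "
                      "despotism unobservable", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    colony_eff = {f"C{c + 1}": rng.normal(0.0, config.colony_sd)
                  for c in range(config.n_colonies)}
    years = [config.first_year + t for t in range(config.n_years)]
    year_eff = {y: rng.normal(0.0, config.year_sd) for y in years}

    registry_rows, copres_rows, inter_rows, repro_rows = [], [], [], []
    truth_g, truth_r = [], []

    n_groups_total = (config.n_colonies * config.n_years
                      * config.groups_per_colony_year)
    sizes = draw_group_sizes(n_groups_total, rng, config.group_size_nbinom,
                             config.group_size_range)
    size_iter = iter(sizes)

    for colony in colony_eff:
        for year in years:
            season_days = pd.date_range(f"{year}-05-01", periods=config.n_observation_days,
                                        freq="3D")
            for g in range(config.groups_per_colony_year):
                n = int(next(size_iter))
                group_id = f"{colony}-Y{year}-G{g + 1}"
                ids = [f"{group_id}-F{i + 1}" for i in range(n)]
                ranks = np.arange(1, n + 1)  # id order is rank order
                delta = rng.uniform(*config.despotism_range)
                home = f"{colony}-burrow-{g + 1}"
                shared = f"{colony}-meadow"

                for ind in ids:
                    registry_rows.append(
                        {"individual_id": ind, "year": year, "sex": "F",
                         "age_class": "adult", "colony": colony,
                         "n_traps": 6 + int(rng.poisson(5.0))})
                # one transient female per group exercises the trap filter
                transient = f"{group_id}-T"
                registry_rows.append(
                    {"individual_id": transient, "year": year, "sex": "F",
                     "age_class": "adult", "colony": colony,
                     "n_traps": int(rng.integers(0, 6))})

                for ind in ids:
                    for day in season_days:
                        if rng.random() < config.detection_prob:
                            copres_rows.append({"individual_id": ind,
                                                "day": day, "location": home})
                        elif rng.random() < 0.1:
                            copres_rows.append({"individual_id": ind,
                                                "day": day, "location": shared})

                # directed agonistic acts
                w = np.exp(-delta * (ranks - 1.0))
                for i in range(n):
                    for j in range(n):
                        if i == j:
                            continue
                        bias = _sigmoid(delta * (ranks[j] - ranks[i]))
                        lam = config.interaction_rate * w[i] * bias
                        count = rng.poisson(lam)
                        for _ in range(count):
                            day = season_days[rng.integers(len(season_days))]
                            inter_rows.append(
                                {"timestamp": day + pd.Timedelta(hours=8),
                                 "initiator_id": ids[i], "recipient_id": ids[j],
                                 "itype": "agonistic", "location": home})
                # sprinkle affiliative and unknown-party acts (filter fodder)
                for _ in range(rng.poisson(2.0)):
                    a, b = rng.choice(n, size=2, replace=False)
                    day = season_days[rng.integers(len(season_days))]
                    inter_rows.append(
                        {"timestamp": day + pd.Timedelta(hours=9),
                         "initiator_id": ids[a], "recipient_id": ids[b],
                         "itype": "affiliative", "location": home})
                if rng.random() < 0.5:
                    day = season_days[rng.integers(len(season_days))]
                    inter_rows.append(
                        {"timestamp": day + pd.Timedelta(hours=10),
                         "initiator_id": rec.UNKNOWN, "recipient_id": ids[0],
                         "itype": "agonistic", "location": home})

                # reproduction: Dirichlet-multinomial allocation
                total = int(rng.poisson(n * config.mean_litter))
                alpha_shape = np.exp(-config.coupling * delta * (ranks - 1.0))
                alpha_shape = alpha_shape / alpha_shape.sum()
                conc = n * np.exp(config.log_concentration
                                  + colony_eff[colony] + year_eff[year])
                if total > 0:
                    p = rng.dirichlet(alpha_shape * conc)
                    offspring = rng.multinomial(total, p)
                else:
                    offspring = np.zeros(n, dtype=int)
                for ind, off in zip(ids, offspring):
                    repro_rows.append({"mother_id": ind, "year": year,
                                       "offspring": int(off), "exposure": 1.0})

                truth_g.append({"group_id": group_id, "colony": colony,
                                "year": year, "delta": delta,
                                "kappa": config.coupling, "n_females": n,
                                "total_offspring": total})
                for ind, rk in zip(ids, ranks):
                    truth_r.append({"individual_id": ind, "year": year,
                                    "group_id": group_id, "rank": int(rk)})

    registry = pd.DataFrame(registry_rows)
    copresence = pd.DataFrame(
        [{"individual_id": r["individual_id"],
          "date": r["day"], "location": r["location"]} for r in copres_rows])
    interactions = pd.DataFrame(inter_rows).sort_values("timestamp",
                                                        kind="stable")
    interactions = interactions.reset_index(drop=True)
    reproduction = pd.DataFrame(repro_rows)
    return SyntheticData(
        registry=registry, copresence=copresence, interactions=interactions,
        reproduction=reproduction,
        truth_groups=pd.DataFrame(truth_g), truth_ranks=pd.DataFrame(truth_r),
    )


def simulate_group_year_rows(n: int = 100,
                             betas: dict[str, float] | None = None,
                             colony_sd: float = 0.4, year_sd: float = 0.4,
                             residual_sd: float = 0.6,
                             n_colonies: int = 3, n_years: int = 11,
                             seed: int = 0) -> pd.DataFrame:
    """Analysis-ready group-year rows with a planted coefficient structure.

    Predictors ``grc_ls, hprime_ls, gsize_ls`` are standardised normals with
    field-like correlations (GRC-size 0.625, h'-size 0.202); the response is

        m_std = sum_k beta_k * x_k + u_colony + u_year + eps,

    with crossed Gaussian intercepts and residual noise.  The response is
    left on its generated scale (not re-standardised) so fitted
    coefficients estimate the planted betas directly.
    """
    betas = dict(betas or {"grc_ls": 0.6, "hprime_ls": 0.0, "gsize_ls": 0.0})
    rng = np.random.default_rng(seed)
    corr = np.array([
        [1.0, 0.2, 0.625],
        [0.2, 1.0, 0.202],
        [0.625, 0.202, 1.0],
    ])
    chol = np.linalg.cholesky(corr)
    x = rng.standard_normal((n, 3)) @ chol.T
    rows = pd.DataFrame(x, columns=["grc_ls", "hprime_ls", "gsize_ls"])
    rows["colony"] = [f"C{k + 1}" for k in rng.integers(0, n_colonies, size=n)]
    rows["year"] = [2003 + int(t) for t in rng.integers(0, n_years, size=n)]
    u_c = {f"C{k + 1}": rng.normal(0.0, colony_sd) for k in range(n_colonies)}
    u_y = {2003 + t: rng.normal(0.0, year_sd) for t in range(n_years)}
    y = np.zeros(n)
    for name, b in betas.items():
        y += b * rows[name].to_numpy()
    y += rows["colony"].map(u_c).to_numpy()
    y += rows["year"].map(u_y).to_numpy()
    y += rng.normal(0.0, residual_sd, size=n)
    rows["m_std"] = y
    rows["group_id"] = [f"G{k + 1}" for k in range(n)]
    rows["n_females"] = 4
    return rows


FIXTURES = ("toy_colony", "planted_partition", "skew_demo")


def make_fixture(name: str):
    """Small deterministic datasets used in docs and tests.

    ``toy_colony``
        A miniature :class:`SyntheticData`: 2 colonies x 2 years, 5 groups
        total, human-readable ids.
    ``planted_partition``
        (matrix, labels): a 15-individual association matrix with three
        5-member blocks (within 0.8, between 0.05) and the planted labels.
    ``skew_demo``
        (offspring, exposure): one 4-female group whose M index is
        hand-checkable from the deviation formula.
    """
    if name == "toy_colony":
        cfg = SyntheticConfig(n_colonies=2, n_years=2, groups_per_colony_year=2,
                              n_observation_days=10, seed=42)
        data = generate_colony_data(cfg)
        keep = tuple(data.truth_groups["group_id"].iloc[:5])

        def member(ids: pd.Series) -> pd.Series:
            return ids.str.startswith(keep) | (ids == rec.UNKNOWN)

        data.registry = data.registry[member(data.registry["individual_id"])
                                      ].reset_index(drop=True)
        data.copresence = data.copresence[
            member(data.copresence["individual_id"])].reset_index(drop=True)
        data.interactions = data.interactions[
            member(data.interactions["initiator_id"])
            & member(data.interactions["recipient_id"])].reset_index(drop=True)
        data.reproduction = data.reproduction[
            member(data.reproduction["mother_id"])].reset_index(drop=True)
        data.truth_groups = data.truth_groups[
            data.truth_groups["group_id"].isin(keep)].reset_index(drop=True)
        data.truth_ranks = data.truth_ranks[
            data.truth_ranks["group_id"].isin(keep)].reset_index(drop=True)
        return data
    if name == "planted_partition":
        labels = np.repeat([0, 1, 2], 5)
        w = np.where(labels[:, None] == labels[None, :], 0.8, 0.05)
        np.fill_diagonal(w, 0.0)
        return w, labels
    if name == "skew_demo":
        # 4 females, equal exposure, offspring (6, 2, 1, 1):
        # shares (0.6, 0.2, 0.1, 0.1) vs 0.25 each
        # M_raw = 4 * (0.35^2 + 0.05^2 + 2 * 0.15^2) = 0.68
        # E[M_raw|null] = 4 * (1 - 4 * 0.25^2) / 10 = 0.3; M = 0.38
        return np.array([6, 2, 1, 1]), np.ones(4)
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
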