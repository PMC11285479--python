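"""Group-year table assembly and mixed-model variance decomposition.

The unit of analysis is the social group-year.  Each row carries the
standardised skew response ``m_std`` and three log-transformed,
standardised predictors: global reaching centrality (``grc_ls``),
dominance linearity h' (``hprime_ls``) and adult-female group size
(``gsize_ls``).  Group size is kept in every model because network
measures co-vary with it.

The model is a linear mixed model with crossed random intercepts for
colony and year,

    m_std ~ grc_ls + hprime_ls + gsize_ls + (1 | colony) + (1 | year),

fitted by REML for the reported coefficients (Wald z tests) and refitted
by ML for AICc comparisons across the model ladder (full, GRC + size,
h' + size, size only).  The readout follows the variance-partitioning
conventions for mixed models:

* marginal R2   = var(fixed predictions) / total variance,
* conditional R2 = (fixed + random variances) / total variance,
* semi-partial (part) R2 of a predictor = marginal R2 of the full model
  minus marginal R2 of the model with that predictor removed, with 95%
  confidence intervals from a parametric bootstrap (simulate the response
  from the fitted model, refit, recompute),
* AICc = AIC + 2k(k+1)/(n-k-1) with k counting fixed effects, variance
  components and the residual,
* VIF per fixed effect from the fixed-effects design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

PREDICTORS = ["grc_ls", "hprime_ls", "gsize_ls"]
RESPONSE = "m_std"

#: The model ladder: fixed-effect sets fitted and compared by AICc.
MODEL_LADDER: dict[str, list[str]] = {
    "full": ["grc_ls", "hprime_ls", "gsize_ls"],
    "grc_size": ["grc_ls", "gsize_ls"],
    "hprime_size": ["hprime_ls", "gsize_ls"],
    "size_only": ["gsize_ls"],
}

VIF_CAP = 1e6


class AssemblyError(ValueError):
    pass


def log_standardise(x: np.ndarray, offset: float | None = None
                    ) -> tuple[np.ndarray, float]:
    """log-transform then z-score (sample s.d.).

    ``offset`` is added inside the log when zeros are present; by default
    it is half the smallest positive value (0 when all values are
    positive).  Returns the transformed column and the offset used.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise AssemblyError("log transform requires non-negative values")
    if offset is None:
        if (x == 0).any():
            positive = x[x > 0]
            if positive.size == 0:
                raise AssemblyError("all-zero column cannot be log-transformed")
            offset = float(positive.min()) / 2.0
        else:
            offset = 0.0
    return standardise(np.log(x + offset)), offset


def standardise(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or np.ptp(x) == 0 or sd == 0:
        raise AssemblyError("cannot standardise a constant column")
    return (x - x.mean()) / sd


def assemble_table(metrics: pd.DataFrame, skew_results: pd.DataFrame,
                   min_rows: int = 3) -> pd.DataFrame:
    """Join hierarchy metrics to skew results and build the analysis table.

    Keeps only group-years for which GRC, h' and M are all defined, then
    log-transforms and standardises the predictors and standardises the
    response.  Refuses to proceed with fewer than ``min_rows`` rows.
    """
    merged = metrics.merge(skew_results[["group_id", "year", "m_index"]],
                           on=["group_id", "year"], how="inner")
    merged = merged.dropna(subset=["grc", "h_prime", "m_index"]).reset_index(drop=True)
    if len(merged) < min_rows:
        raise AssemblyError(
            f"only {len(merged)} complete group-years; need >= {min_rows} to fit")
    out = merged[["group_id", "colony", "year", "n_females"]].copy()
    out["m_std"] = standardise(merged["m_index"].to_numpy())
    out["grc_ls"], _ = log_standardise(merged["grc"].to_numpy())
    out["hprime_ls"], _ = log_standardise(merged["h_prime"].to_numpy())
    out["gsize_ls"], _ = log_standardise(merged["n_females"].to_numpy(dtype=float))
    return out


@dataclass
class ModelResult:
    """One fitted model with its full variance-decomposition readout."""

    fixed: list[str]
    coefficients: pd.DataFrame  # index: const + predictors; estimate, se, p
    random_variances: dict[str, float]  # colony, year (if used) + residual
    r2_marginal: float
    r2_conditional: float
    aicc: float
    vif: dict[str, float]
    n_rows: int
    semi_partial_r2: pd.DataFrame | None = None  # part_r2, ci_low, ci_high
    converged: bool = True


def _design(rows: pd.DataFrame, fixed: list[str]) -> np.ndarray:
    return sm.add_constant(rows[fixed].to_numpy(dtype=float), has_constant="add")


def _fit_mixed(y: np.ndarray, rows: pd.DataFrame, fixed: list[str],
               random: tuple[str, ...], reml: bool):
    if not random:
        return sm.OLS(y, _design(rows, fixed)).fit()
    # crossed random intercepts: one all-encompassing group, each crossed
    # factor entering as a variance component over its level indicators
    data = rows[list(dict.fromkeys(list(fixed) + list(random)))].copy()
    data["_y"] = np.asarray(y, dtype=float)
    data["_grp"] = 1
    for term in random:
        data[term] = data[term].astype(str)
    vc = {term: f"0 + C({term})" for term in random}
    rhs = " + ".join(fixed) if fixed else "1"
    model = sm.MixedLM.from_formula(
        f"_y ~ {rhs}", groups="_grp", vc_formula=vc,
        re_formula="0", data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method="lbfgs", maxiter=500)
    return fit


def _variance_readout(fit, rows, fixed, random) -> tuple[dict, float, float]:
    """(random variances incl. residual, marginal R2, conditional R2)."""
    exog = _design(rows, fixed)
    beta = np.asarray(getattr(fit, "fe_params", fit.params))[: exog.shape[1]]
    var_fixed = float(np.var(exog @ beta))
    if random:
        vc_names = list(fit.model.exog_vc.names)
        vcomp = {name: float(v) for name, v in zip(vc_names, fit.vcomp)}
        resid = float(fit.scale)
    else:
        vcomp = {}
        resid = float(fit.scale)
    var_random = sum(vcomp.values())
    total = var_fixed + var_random + resid
    r2m = var_fixed / total if total > 0 else 0.0
    r2c = (var_fixed + var_random) / total if total > 0 else 0.0
    variances = dict(vcomp)
    variances["residual"] = resid
    return variances, r2m, r2c


def nakagawa_r2(fit, rows: pd.DataFrame, fixed: list[str],
                random: tuple[str, ...] = ("colony", "year")
                ) -> tuple[float, float]:
    """Marginal and conditional R2 of a fitted (mixed) model."""
    _, r2m, r2c = _variance_readout(fit, rows, fixed, random)
    return r2m, r2c


def aicc_from_fit(fit_ml, n: int, k: int) -> float:
    """Small-sample corrected AIC.  Requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    aic = -2.0 * float(fit_ml.llf) + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def vif(rows: pd.DataFrame, predictors: list[str]) -> dict[str, float]:
    """Variance inflation factors from the fixed-effects design matrix.

    Perfectly collinear predictors are reported capped at ``VIF_CAP``.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    exog = _design(rows, predictors)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, name in enumerate(predictors, start=1):
            v = variance_inflation_factor(exog, k)
            if not np.isfinite(v) or v > VIF_CAP:
                v = VIF_CAP
            out[name] = float(v)
    return out


def fit_lmm(rows: pd.DataFrame, fixed: list[str],
            random: tuple[str, ...] = ("colony", "year"),
            response: str = RESPONSE) -> ModelResult:
    """Fit one model of the ladder with the full readout.

    REML estimates and Wald z tests for the coefficients; a parallel ML
    refit supplies the likelihood for AICc.  With ``random=()`` the model
    collapses to ordinary least squares (also the oracle for the
    zero-variance limit).  A singular fit (a variance component estimated
    at zero) is reported as such with a warning, not an error.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows to fit")
    if not fixed:
        raise ValueError("need at least one fixed effect")
    y = rows[response].to_numpy(dtype=float)
    fit = _fit_mixed(y, rows, fixed, random, reml=True)
    fit_ml = _fit_mixed(y, rows, fixed, random, reml=False) if random else fit

    p = len(fixed) + 1
    params = np.asarray(getattr(fit, "fe_params", fit.params))[:p]
    bse = np.asarray(fit.bse)[:p]
    pvals = np.asarray(fit.pvalues)[:p]
    coef = pd.DataFrame({"estimate": params, "se": bse, "p": pvals},
                        index=["const"] + list(fixed))

    variances, r2m, r2c = _variance_readout(fit, rows, fixed, random)
    for term in random:
        # lme4-style near-singularity heuristic: a component this far below
        # the residual variance is effectively zero
        if variances.get(term, np.inf) < max(1e-8, 0.01 * variances["residual"]):
            warnings.warn(f"random effect '{term}' estimated at (near-)zero "
                          "variance (singular fit)", stacklevel=2)
    k = p + len(random) + 1  # fixed effects + variance components + residual
    converged = bool(getattr(fit, "converged", True))
    return ModelResult(
        fixed=list(fixed),
        coefficients=coef,
        random_variances=variances,
        r2_marginal=r2m,
        r2_conditional=r2c,
        aicc=aicc_from_fit(fit_ml, n=len(rows), k=k),
        vif=vif(rows, list(fixed)),
        n_rows=len(rows),
        converged=converged,
    )


def _marginal_r2_of(y, rows, fixed, random) -> float:
    fit = _fit_mixed(np.asarray(y, dtype=float), rows, fixed, random, reml=True)
    _, r2m, _ = _variance_readout(fit, rows, fixed, random)
    return r2m


def semi_partial_r2(rows: pd.DataFrame, fixed: list[str],
                    random: tuple[str, ...] = ("colony", "year"),
                    response: str = RESPONSE, n_boot: int = 100,
                    seed: int = 0) -> pd.DataFrame:
    """Per-predictor part R2 with parametric-bootstrap 95% CIs.

    part R2(x) = marginal R2(full) - marginal R2(full minus x).  The CIs
    come from ``n_boot`` parametric bootstrap iterations: the response is
    simulated from the fitted full model (fixed predictions + random-effect
    draws + residual noise), all models are refitted and the parts
    recomputed; ``n_boot=0`` skips the bootstrap (NaN CIs).  Failed refits
    are skipped and counted, with a warning past 10%.
    """
    y = rows[response].to_numpy(dtype=float)
    fit_full = _fit_mixed(y, rows, fixed, random, reml=True)
    variances, r2m_full, _ = _variance_readout(fit_full, rows, fixed, random)

    def parts_for(yy) -> dict[str, float]:
        full = _marginal_r2_of(yy, rows, fixed, random)
        return {x: full - _marginal_r2_of(yy, rows, [f for f in fixed if f != x],
                                          random)
                for x in fixed}

    point = {x: r2m_full - _marginal_r2_of(y, rows,
                                           [f for f in fixed if f != x], random)
             for x in fixed}

    ci_low = {x: np.nan for x in fixed}
    ci_high = {x: np.nan for x in fixed}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        exog = _design(rows, fixed)
        beta = np.asarray(fit_full.params)[: exog.shape[1]]
        mu = exog @ beta
        resid_sd = np.sqrt(variances["residual"])
        boot: dict[str, list[float]] = {x: [] for x in fixed}
        skipped = 0
        for _ in range(n_boot):
            yy = mu.copy()
            for term in random:
                sd = np.sqrt(max(variances.get(term, 0.0), 0.0))
                levels = rows[term].astype(str)
                u = {lv: rng.normal(0.0, sd) for lv in levels.unique()}
                yy = yy + levels.map(u).to_numpy(dtype=float)
            yy = yy + rng.normal(0.0, resid_sd, size=len(rows))
            try:
                res = parts_for(yy)
            except Exception:
                skipped += 1
                continue
            for x in fixed:
                boot[x].append(res[x])
        if skipped > 0.1 * n_boot:
            warnings.warn(f"{skipped}/{n_boot} bootstrap refits failed",
                          stacklevel=2)
        for x in fixed:
            if boot[x]:
                ci_low[x] = float(np.percentile(boot[x], 2.5))
                ci_high[x] = float(np.percentile(boot[x], 97.5))

    return pd.DataFrame(
        {"part_r2": [point[x] for x in fixed],
         "ci_low": [ci_low[x] for x in fixed],
         "ci_high": [ci_high[x] for x in fixed]},
        index=list(fixed),
    )


def model_ladder(rows: pd.DataFrame, random: tuple[str, ...] = ("colony", "year"),
                 n_boot: int = 100, seed: int = 0) -> dict[str, ModelResult]:
    """Fit the four-model ladder; the full model also gets part R2 CIs."""
    results = {}
    for name, fixed in MODEL_LADDER.items():
        results[name] = fit_lmm(rows, fixed, random=random)
    results["full"].semi_partial_r2 = semi_partial_r2(
        rows, MODEL_LADDER["full"], random=random, n_boot=n_boot, seed=seed)
    return results


def ladder_summary(results: dict[str, ModelResult]) -> pd.DataFrame:
    """One row per model: AICc, R2s and the headline coefficients."""
    rows = []
    for name, res in results.items():
        row = {"model": name, "aicc": res.aicc, "r2_marginal": res.r2_marginal,
               "r2_conditional": res.r2_conditional, "n": res.n_rows}
        for pred in PREDICTORS:
            if pred in res.coefficients.index:
                row[f"b_{pred}"] = res.coefficients.loc[pred, "estimate"]
                row[f"p_{pred}"] = res.coefficients.loc[pred, "p"]
        rows.append(row)
    return pd.DataFrame(rows)


def effect_plot(rows: pd.DataFrame, result: ModelResult, path,
                predictor: str = "grc_ls") -> None:
    """Marginal-effect plot of one predictor with a 95% CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.linspace(rows[predictor].min(), rows[predictor].max(), 100)
    coef = result.coefficients
    b0 = coef.loc["const", "estimate"]
    b = coef.loc[predictor, "estimate"]
    se = coef.loc[predictor, "se"]
    pred = b0 + b * grid
    lo = b0 + (b - 1.96 * se) * grid
    hi = b0 + (b + 1.96 * se) * grid
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(rows[predictor], rows[RESPONSE], s=18, color="0.3", zorder=3)
    ax.plot(grid, pred, color="tab:blue")
    ax.fill_between(grid, np.minimum(lo, hi), np.maximum(lo, hi),
                    alpha=0.25, color="tab:blue")
    ax.set_xlabel(f"{predictor} (log, standardised)")
    ax.set_ylabel("M index (standardised)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
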