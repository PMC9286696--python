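"""Ensemble simulations and the standardized regression analyses.

These functions reproduce the study-level experiments: a large ensemble of
independently parameterized metacommunity simulations, a multiple regression
of richness synchrony on the underlying simulation parameters (the driver
analysis), a regression on the emergent community-structure metrics, and the
simple diversity-stability regressions comparing richness synchrony with
mean richness as predictors of ecosystem stability.

Predictors are z-scored before fitting so coefficients are effect sizes
comparable across predictors with different natural scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import community_metrics
from .params import sample_params
from .simulate import run_simulation
from .synchrony import richness_series, synchrony

__all__ = [
    "RegressionReport",
    "run_ensemble",
    "standardized_regression",
    "parameter_drivers_regression",
    "community_structure_regression",
    "stability_regressions",
    "stability_comparison",
    "PARAMETER_PREDICTORS",
    "STRUCTURE_PREDICTORS",
]

logger = logging.getLogger(__name__)

#: Simulation parameters entering the driver regression.
PARAMETER_PREDICTORS = ["env_sd", "a", "P", "h", "r_avg", "beta_max", "d"]
#: Emergent community metrics entering the structure regression.
STRUCTURE_PREDICTORS = ["mean_richness", "evenness", "beta_jaccard", "turnover_rate"]


@dataclass
class RegressionReport:
    """OLS fit on standardized predictors: effect sizes, SEs, and R^2."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    r_squared: float
    n: int
    n_dropped: int = 0
    intercept: float = 0.0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.coefficients, "std_error": self.std_errors}
        )


def run_ensemble(
    n: int = 2500,
    master_seed: int = 0,
    dispersal_mode: str = "global",
    T_total: int = 100,
    burn_in: int = 50,
    min_occupancy: float = 0.05,
    overrides=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate ``n`` independently parameterized metacommunities.

    Each run draws a fresh parameter set, simulates ``T_total`` steps, and
    computes richness synchrony, stability, and the emergent community
    metrics on the post-burn-in window.  Runs whose richness never varies
    (no patch pair with usable rank information) cannot yield a synchrony
    value; they are retained with ``degenerate=True`` and NaN synchrony
    rather than aborting the ensemble.

    Fully reproducible from ``master_seed``: per-run seeds are drawn from a
    generator seeded with it.

    Returns
    -------
    DataFrame with one row per simulation: the run seed, the scalar
    parameters (S, P, h, a, env_sd, r_avg, beta_max, d), mean richness
    synchrony, the number of patch pairs used, the community metrics, and
    stability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed_rng = np.random.default_rng(master_seed)
    run_seeds = seed_rng.integers(0, 2**31 - 1, size=n)
    records = []
    iterator = enumerate(run_seeds)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = enumerate(tqdm(run_seeds, desc="ensemble"))
        except ImportError:
            pass
    for i, run_seed in iterator:
        rec = {"run": i, "seed": int(run_seed), "degenerate": False}
        try:
            params = sample_params(
                int(run_seed), overrides=overrides, dispersal_mode=dispersal_mode
            )
            rec.update(params.scalars())
            cube = run_simulation(params, T_total=T_total, burn_in=burn_in)
            R = richness_series(cube)
            try:
                sync = synchrony(R)
                rec["synchrony"] = sync.mean_synchrony
                rec["n_pairs_used"] = sync.n_pairs_used
            except ValueError:
                rec["synchrony"] = np.nan
                rec["n_pairs_used"] = 0
                rec["degenerate"] = True
            m = community_metrics(cube, min_occupancy=min_occupancy)
            rec.update(
                mean_richness=m.mean_richness,
                evenness=m.evenness,
                beta_jaccard=m.beta_jaccard,
                beta_turnover_component=m.beta_turnover_component,
                beta_nestedness_component=m.beta_nestedness_component,
                turnover_rate=m.turnover_rate,
                stability=m.stability,
            )
        except Exception:
            logger.exception("ensemble run %d (seed %d) failed", i, run_seed)
            rec["degenerate"] = True
        records.append(rec)
    return pd.DataFrame.from_records(records)


def standardized_regression(
    table: pd.DataFrame, response: str, predictors: list[str]
) -> RegressionReport:
    """OLS of ``response`` on z-scored ``predictors``.

    Rows with missing values in the response or any predictor (e.g. flagged
    degenerate runs) are dropped listwise; the count is reported.  A
    rank-deficient design raises an error naming the collinear columns.
    """
    if not predictors:
        raise ValueError("at least one predictor is required")
    cols = [response] + list(predictors)
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    data = table[cols].dropna()
    n_dropped = len(table) - len(data)
    if len(data) < len(predictors) + 2:
        raise ValueError("not enough complete rows for the regression")

    X = data[list(predictors)].astype(float)
    sds = X.std(ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"rank-deficient design: constant predictor(s) {zero_var}")
    Z = (X - X.mean()) / sds
    design = sm.add_constant(Z.to_numpy())
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = Z.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design: collinear predictors {worst}")
    fit = sm.OLS(data[response].astype(float).to_numpy(), design).fit()
    names = list(predictors)
    return RegressionReport(
        response=response,
        predictors=names,
        coefficients=dict(zip(names, fit.params[1:])),
        std_errors=dict(zip(names, fit.bse[1:])),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        n_dropped=n_dropped,
        intercept=float(fit.params[0]),
    )


def parameter_drivers_regression(table: pd.DataFrame) -> RegressionReport:
    """Richness synchrony regressed on the seven standardized simulation
    parameters (env_sd, a, P, h, r_avg, beta_max, d): the driver analysis."""
    return standardized_regression(table, "synchrony", PARAMETER_PREDICTORS)


def community_structure_regression(table: pd.DataFrame) -> RegressionReport:
    """Richness synchrony regressed on the four emergent community metrics
    (mean richness, evenness, Jaccard beta diversity, turnover rate)."""
    return standardized_regression(table, "synchrony", STRUCTURE_PREDICTORS)


def stability_regressions(
    table: pd.DataFrame,
) -> tuple[RegressionReport, RegressionReport]:
    """Simple regressions of stability on richness synchrony and on mean
    richness — the diversity-stability comparison.

    Returns ``(stability~synchrony, stability~mean_richness)``.
    """
    return (
        standardized_regression(table, "stability", ["synchrony"]),
        standardized_regression(table, "stability", ["mean_richness"]),
    )


def stability_comparison(
    table: pd.DataFrame, predictors: list[str] | None = None
) -> pd.DataFrame:
    """R^2 of simple regressions of stability on each candidate predictor.

    Defaults to synchrony, mean richness, evenness, beta diversity, and
    turnover rate; one row per predictor with its effect size, SE, and R^2.
    """
    if predictors is None:
        predictors = ["synchrony", "mean_richness", "evenness",
                      "beta_jaccard", "turnover_rate"]
    rows = []
    for pred in predictors:
        rep = standardized_regression(table, "stability", [pred])
        rows.append(
            {
                "predictor": pred,
                "coefficient": rep.coefficients[pred],
                "std_error": rep.std_errors[pred],
                "r_squared": rep.r_squared,
                "n": rep.n,
            }
        )
    return pd.DataFrame(rows)
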