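"""Quasi-Bayesian (Monte Carlo) mediation analysis.

Two linear models are fitted by OLS —

    mediator model:  M ~ X (+ covariates)
    outcome model:   Y ~ X + M (+ covariates)

— and ``n_sims`` parameter vectors are drawn from the asymptotic
multivariate normal of each fit. Per draw, the average causal mediation
effect is ACME = a * b (X->M slope times M->Y slope), the average direct
effect is ADE = c' (the X slope of the outcome model), the total effect is
ACME + ADE, and the proportion mediated is ACME / total. Point estimates
are the medians of the draws, confidence intervals percentile intervals
and p-values two-sided simulation tail probabilities. With linear models
and no exposure-mediator interaction, total = ACME + ADE holds per draw by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MediationSpec:
    outcome: str
    treatment: str
    mediator: str
    covariates: tuple[str, ...] = ()
    n_sims: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    point_estimate: str = "median"  # or 'mean'

    def __post_init__(self) -> None:
        cols = {self.outcome, self.treatment, self.mediator}
        if len(cols) != 3:
            raise ValueError("outcome, treatment and mediator must be distinct columns")
        if self.n_sims < 100:
            raise ValueError("n_sims must be at least 100")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class Effect:
    estimate: float
    ci: tuple[float, float]
    p: float


@dataclass
class MediationResult:
    acme: Effect
    ade: Effect
    total: Effect
    proportion_mediated: Effect
    n_sims: int
    n_obs: int
    undefined_proportion_fraction: float = 0.0
    draws: dict = field(default_factory=dict, repr=False)


def _ols(y: np.ndarray, x: np.ndarray):
    """OLS point estimates and asymptotic parameter covariance."""
    n, p = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise ValueError("non-invertible design matrix in mediation model")
    resid = y - x @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return beta, cov


def fit_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Quasi-Bayesian mediation estimates for linear no-interaction models."""
    cols = [spec.outcome, spec.treatment, spec.mediator, *spec.covariates]
    df = data[cols].astype(float).dropna()
    if len(df) < 20:
        raise ValueError(f"only {len(df)} complete cases; need at least 20")
    n = len(df)
    y = df[spec.outcome].to_numpy()
    x = df[spec.treatment].to_numpy()
    m = df[spec.mediator].to_numpy()
    cov_mat = df[list(spec.covariates)].to_numpy() if spec.covariates else np.empty((n, 0))
    ones = np.ones(n)
    design_m = np.column_stack([ones, x, cov_mat])
    design_y = np.column_stack([ones, x, m, cov_mat])
    beta_m, cov_m = _ols(m, design_m)
    beta_y, cov_y = _ols(y, design_y)

    rng = np.random.default_rng(spec.seed)
    draws_m = rng.multivariate_normal(beta_m, cov_m, size=spec.n_sims)
    draws_y = rng.multivariate_normal(beta_y, cov_y, size=spec.n_sims)
    a = draws_m[:, 1]  # X -> M
    c_prime = draws_y[:, 1]  # direct effect
    b = draws_y[:, 2]  # M -> Y
    acme = a * b
    total = acme + c_prime
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(np.abs(total) > 1e-12, acme / total, np.nan)
    undefined = float(np.isnan(prop).mean())

    alpha = 1.0 - spec.ci_level
    point = np.median if spec.point_estimate == "median" else np.mean

    def effect(draws: np.ndarray) -> Effect:
        d = draws[np.isfinite(draws)]
        lo, hi = np.percentile(d, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        p = 2.0 * min((d <= 0).mean(), (d >= 0).mean())
        return Effect(float(point(d)), (float(lo), float(hi)), float(min(p, 1.0)))

    return MediationResult(
        acme=effect(acme),
        ade=effect(c_prime),
        total=effect(total),
        proportion_mediated=effect(prop),
        n_sims=spec.n_sims,
        n_obs=n,
        undefined_proportion_fraction=undefined,
        draws={"acme": acme, "ade": c_prime, "total": total, "proportion": prop},
    )


def summarize_mediation(result: MediationResult) -> pd.DataFrame:
    """Tabular report of the mediation effects (proportion as percentage)."""
    rows = []
    for name, eff, as_pct in (
        ("ACME (indirect)", result.acme, False),
        ("ADE (direct)", result.ade, False),
        ("Total effect", result.total, False),
        ("Proportion mediated", result.proportion_mediated, True),
    ):
        est, lo, hi = eff.estimate, eff.ci[0], eff.ci[1]
        rows.append(
            {
                "effect": name,
                "estimate": est,
                "ci_lower": lo,
                "ci_upper": hi,
                "p": eff.p,
                "display": f"{est * 100:.1f}%" if as_pct else f"{est:.3g}",
            }
        )
    return pd.DataFrame(rows)
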