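"""Descriptive and inferential statistics on biomarkers and Z-scores.

Covers the study's statistical layer: standardized simple regressions with
Benjamini-Hochberg FDR (Spearman for the skewed TMT-B), a multivariate OLS
model, one-way ANOVA with Tukey-Kramer post hoc tests, pairwise Cohen's D,
ROC/AUC with DeLong confidence intervals, centile-threshold patient counts
on the rounded centile ranks, and amyloid/tau PET positivity
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AMYLOID_POSITIVITY_SUVR = 1.42
TAU_POSITIVITY_SUVR = 1.23

#: Cohen's D magnitude conventions used in reporting
COHENS_D_THRESHOLDS = {"small": 0.3, "medium": 0.5, "large": 0.8}


# ---------------------------------------------------------------------------
# associations


@dataclass
class AssociationResult:
    predictor: str
    method: str  # 'pearson' or 'spearman'
    coefficient: float  # standardized beta or rho
    t: float
    p: float
    adjusted_r2: float
    ci: tuple[float, float]
    p_fdr: float = np.nan


def simple_associations(
    outcome: np.ndarray,
    covariates: pd.DataFrame,
    methods: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """One standardized simple regression per covariate, BH-corrected.

    ``methods`` maps covariate name -> 'pearson' (default) or 'spearman';
    Spearman is meant for heavily skewed scores such as the TMT-B. The
    standardized Pearson beta equals the correlation; its CI comes from the
    regression, the Spearman CI from the Fisher-z approximation.
    """
    methods = methods or {}
    outcome = np.asarray(outcome, dtype=float)
    results: list[AssociationResult] = []
    for name in covariates.columns:
        x = np.asarray(covariates[name], dtype=float)
        keep = np.isfinite(x) & np.isfinite(outcome)
        xs, ys = x[keep], outcome[keep]
        if keep.sum() < 10:
            raise ValueError(f"fewer than 10 complete cases for {name}")
        if np.var(xs) == 0:
            warnings.warn(f"zero-variance covariate {name}: skipped")
            continue
        n = xs.size
        method = methods.get(name, "pearson")
        if method == "pearson":
            xs = (xs - xs.mean()) / xs.std(ddof=1)
            ys_std = (ys - ys.mean()) / ys.std(ddof=1)
            res = stats.linregress(xs, ys_std)
            beta, p = res.slope, res.pvalue
            t = beta / res.stderr if res.stderr > 0 else np.inf * np.sign(beta)
            r2 = beta**2
            adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
            ci = (beta - 1.96 * res.stderr, beta + 1.96 * res.stderr)
            results.append(
                AssociationResult(name, "pearson", float(beta), float(t), float(p), float(adj_r2), ci)
            )
        elif method == "spearman":
            rho, p = stats.spearmanr(xs, ys)
            zr = np.arctanh(rho)
            se = 1.0 / np.sqrt(n - 3)
            ci = (float(np.tanh(zr - 1.96 * se)), float(np.tanh(zr + 1.96 * se)))
            results.append(
                AssociationResult(name, "spearman", float(rho), np.nan, float(p), np.nan, ci)
            )
        else:
            raise ValueError(f"unknown method {method!r} for {name}")
    if results:
        adj = multipletests([r.p for r in results], alpha=alpha, method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_fdr = float(q)
    return results


def multivariate_regression(outcome: np.ndarray, predictors: pd.DataFrame):
    """OLS of the outcome on all predictors jointly (statsmodels fit).

    Raises on rank deficiency, naming the aliased columns.
    """
    import statsmodels.api as sm

    x = predictors.astype(float)
    keep = np.isfinite(np.asarray(outcome)) & np.isfinite(x).all(axis=1)
    x, y = x[keep], np.asarray(outcome, dtype=float)[keep]
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("need n > p + 1 complete cases")
    mat = np.column_stack([np.ones(len(x)), x.to_numpy()])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
            mat, mode="economic", pivoting=True
        )
        aliased = sorted(piv[rank:])
        names = ["const"] + list(x.columns)
        raise ValueError(
            f"rank-deficient design: aliased column(s) {[names[i] for i in aliased]}"
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return model


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    groups: list[str]
    f: float
    df: tuple[int, int]
    p: float
    tukey: pd.DataFrame | None = None
    cohens_d: dict = field(default_factory=dict)


def anova_tukey(values: np.ndarray, groups: np.ndarray) -> GroupComparison:
    """One-way ANOVA plus Tukey-Kramer post hoc pairwise tests.

    Singleton groups are excluded from the Tukey step with a warning
    (Tukey-Kramer handles unequal but not single-observation groups).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with n >= 2 each for the ANOVA")
    f, p = stats.f_oneway(*samples)
    df = (len(labels) - 1, values.size - len(labels))
    tukey_labels = [g for g, s in zip(labels, samples) if len(s) >= 2]
    if len(tukey_labels) < len(labels):
        warnings.warn("singleton group(s) excluded from Tukey post hoc tests")
    mask = np.isin(groups, tukey_labels)
    if np.allclose(values, values.mean()):
        # identical data in every group: F = 0, all pairwise p = 1
        pairs = [
            (a, b) for i, a in enumerate(tukey_labels) for b in tukey_labels[i + 1 :]
        ]
        tukey_df = pd.DataFrame(
            {"group1": [a for a, _ in pairs], "group2": [b for _, b in pairs],
             "meandiff": 0.0, "p_adj": 1.0}
        )
        return GroupComparison(list(labels), 0.0, df, 1.0, tukey_df)
    tk = pairwise_tukeyhsd(values[mask], groups[mask])
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    ).rename(columns={"p-adj": "p_adj"})
    return GroupComparison(list(labels), float(f), df, float(p), tukey_df)


def pairwise_cohens_d(
    a: np.ndarray, b: np.ndarray, ci_method: str = "noncentral_t", n_boot: int = 2000, seed: int = 0
) -> dict:
    """Cohen's D (a minus b, pooled SD) with a 95% CI.

    CI via the noncentral-t pivot by default, or a percentile bootstrap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD: Cohen's D undefined")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    scale = np.sqrt(1.0 / na + 1.0 / nb)
    if ci_method == "noncentral_t":
        t_obs = d / scale
        dof = na + nb - 2
        lo = _nct_ncp(t_obs, dof, 0.975) * scale
        hi = _nct_ncp(t_obs, dof, 0.025) * scale
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            ra = rng.choice(a, na)
            rb = rng.choice(b, nb)
            s2 = ((na - 1) * ra.var(ddof=1) + (nb - 1) * rb.var(ddof=1)) / (na + nb - 2)
            if s2 > 0:
                draws.append((ra.mean() - rb.mean()) / np.sqrt(s2))
        lo, hi = np.percentile(draws, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    magnitude = "negligible"
    for name, cut in COHENS_D_THRESHOLDS.items():
        if abs(d) >= cut:
            magnitude = name
    return {"d": float(d), "ci": (float(lo), float(hi)), "magnitude": magnitude,
            "order": "a_minus_b"}


def _nct_ncp(t_obs: float, dof: int, prob: float) -> float:
    """Noncentrality parameter delta with P(T_{dof,delta} > t_obs) = 1 - prob."""
    from scipy.optimize import brentq

    def f(delta):
        v = stats.nct.cdf(t_obs, dof, delta)
        if np.isnan(v):  # far tails underflow; limit values are known
            v = 0.0 if delta > t_obs else 1.0
        return v - prob

    # expand the bracket until it straddles the root
    width = 4.0
    lo, hi = t_obs - width, t_obs + width
    for _ in range(30):
        if f(lo) * f(hi) < 0:
            break
        width *= 2.0
        lo, hi = t_obs - width, t_obs + width
    return brentq(f, lo, hi, xtol=1e-8)


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores: np.ndarray, labels: np.ndarray, ci_method: str = "delong",
            n_boot: int = 2000, seed: int = 0) -> dict:
    """AUC by the rank (Mann-Whitney) statistic with ties given half credit.

    labels: 1 = case, 0 = control. CI by DeLong (default) or a stratified
    bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    auc, v_cases, v_controls = _delong_components(cases, controls)
    if ci_method == "delong":
        var = v_cases.var(ddof=1) / cases.size + v_controls.var(ddof=1) / controls.size
        se = np.sqrt(var)
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            ca = rng.choice(cases, cases.size)
            co = rng.choice(controls, controls.size)
            draws.append(_delong_components(ca, co)[0])
        ci = tuple(np.percentile(draws, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {"auc": float(auc), "ci": (float(ci[0]), float(ci[1]))}


def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """AUC plus the DeLong structural components (placement values)."""
    m, n = cases.size, controls.size
    diff = cases[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = psi.mean()
    return auc, psi.mean(axis=1), psi.mean(axis=0)


# ---------------------------------------------------------------------------
# centile-threshold counts, A/T classification


@dataclass(frozen=True)
class ThresholdRule:
    """'above' counts rounded centile >= cutoff; 'at_or_below' counts <= cutoff."""

    biomarker: str
    direction: str  # 'above' or 'at_or_below'
    cutoff: float  # proportion, e.g. 0.90 for the 90th centile

    def applies(self, centiles: np.ndarray) -> np.ndarray:
        if self.direction == "above":
            return centiles >= self.cutoff
        if self.direction == "at_or_below":
            return centiles <= self.cutoff
        raise ValueError(f"unknown direction {self.direction!r}")


def centile_threshold_counts(
    ztable: pd.DataFrame, rules: list[ThresholdRule]
) -> pd.DataFrame:
    """Patient counts per group for each centile-threshold rule.

    Counts operate on the 2-decimal rounded centile ranks: a printed 0.90
    counts as "above the 90th centile", matching the published reporting
    convention.
    """
    rows = []
    for rule in rules:
        sub = ztable[ztable["biomarker"] == rule.biomarker]
        if sub.empty:
            raise KeyError(f"unknown biomarker {rule.biomarker!r} in Z-score table")
        for group, grp in sub.groupby("group", sort=True):
            hits = rule.applies(np.asarray(grp["centile"], dtype=float))
            rows.append(
                {
                    "biomarker": rule.biomarker,
                    "group": group,
                    "direction": rule.direction,
                    "cutoff": rule.cutoff,
                    "count": int(hits.sum()),
                    "n": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)


def at_classify(amyloid_suvr: float, tau_suvr: float) -> tuple[bool, bool]:
    """Amyloid/tau positivity: A+ iff SUVR > 1.42, T+ iff SUVR > 1.23 (strict)."""
    if not (np.isfinite(amyloid_suvr) and np.isfinite(tau_suvr)):
        raise ValueError("SUVRs must be finite")
    return amyloid_suvr > AMYLOID_POSITIVITY_SUVR, tau_suvr > TAU_POSITIVITY_SUVR


def chi2_sex(counts: np.ndarray, correction: bool = False) -> dict:
    """Chi-square test on a groups x sexes contingency table (utility)."""
    chi2, p, dof, _ = stats.chi2_contingency(np.asarray(counts), correction=correction)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
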