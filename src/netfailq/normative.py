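"""Age-normative location/scale quantile curves and patient scoring.

For each biomarker the normative cohort is modelled as

    value | age  ~  Normal(mu(age), sigma(age)),
    mu(age)      = B(age) c_mu,
    log sigma(age) = B(age) c_sigma,

with B a cubic B-spline basis and both coefficient vectors penalized by a
second-order difference penalty (penalized maximum likelihood, back-fitting
mu given sigma and sigma given mu to convergence). Smoothness is indexed by
the effective degrees of freedom (EDF) of each curve; a candidate grid of
EDF pairs is scanned and the winner selected by the Schwarz Bayesian
criterion (global deviance and AIC are reported alongside).

Scoring an external subject at age ``a`` with value ``y`` gives the
age-adjusted Z-score ``z = (y - mu(a)) / sigma(a)`` and the centile rank
``Phi(z)`` (reported both unrounded and rounded to 2 decimals — the
rounding convention is load-bearing for centile-threshold counts).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

DEFAULT_CENTILES = (0.004, 0.02, 0.10, 0.25, 0.50, 0.75, 0.90, 0.99, 0.996)
DEFAULT_EDF_GRID = tuple(range(2, 9))


# ---------------------------------------------------------------------------
# penalized B-spline machinery


def _make_knots(lo: float, hi: float, n_interior: int, degree: int) -> np.ndarray:
    # uniform knots extended past the support (P-spline convention): the
    # second-difference coefficient penalty then has exactly the linear
    # functions as its null space
    h = (hi - lo) / (n_interior + 1)
    return lo + h * np.arange(-degree, n_interior + 2 + degree)


def _design(ages: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[len(knots) - degree - 1]
    x = np.clip(ages, lo, hi)
    # design_matrix requires x strictly inside the base interval
    x = np.minimum(x, np.nextafter(hi, -np.inf))
    return BSpline.design_matrix(x, knots, degree).toarray()


def _difference_penalty(n_coef: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n_coef), n=order, axis=0)
    return d.T @ d


def _penalty_eigvals(btwb: np.ndarray, penalty: np.ndarray) -> np.ndarray:
    """Generalized eigenvalues gamma of (penalty, btwb); edf(lam) =
    sum_i 1 / (1 + lam * gamma_i), monotone decreasing in lam."""
    # small ridge keeps the Cholesky factor well defined on degenerate grids
    ridge = 1e-10 * np.trace(btwb) / btwb.shape[0]
    chol = np.linalg.cholesky(btwb + ridge * np.eye(btwb.shape[0]))
    inner = np.linalg.solve(chol, np.linalg.solve(chol, penalty).T)
    return np.clip(np.linalg.eigvalsh((inner + inner.T) / 2.0), 0.0, None)


def _edf(btwb: np.ndarray, lam: float, penalty: np.ndarray) -> float:
    gamma = _penalty_eigvals(btwb, penalty)
    return float((1.0 / (1.0 + lam * gamma)).sum())


def _lam_for_edf(btwb: np.ndarray, penalty: np.ndarray, target: float) -> float:
    """Bisection on log-lambda; EDF is monotone decreasing in lambda."""
    gamma = _penalty_eigvals(btwb, penalty)

    def edf(lam: float) -> float:
        return float((1.0 / (1.0 + lam * gamma)).sum())

    lo, hi = -8.0, 9.0
    scale = np.trace(btwb) / max(np.trace(penalty), 1e-12)
    if edf(scale * 10**lo) <= target:
        return scale * 10**lo
    if edf(scale * 10**hi) >= target:
        return scale * 10**hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if edf(scale * 10**mid) > target:
            lo = mid
        else:
            hi = mid
    return scale * 10 ** (0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# model container


@dataclass
class NormativeModel:
    """Fitted location/scale quantile-curve model for one biomarker."""

    biomarker: str
    knots: np.ndarray
    degree: int
    coef_mu: np.ndarray
    coef_logsigma: np.ndarray
    lam_mu: float
    lam_sigma: float
    edf_mu: float
    edf_sigma: float
    support: tuple[float, float]
    family: str = "normal"
    scores: dict = field(default_factory=dict)  # global_deviance, aic, sbc
    diagnostics: dict = field(default_factory=dict)
    n_subjects: int = 0

    def mu(self, ages) -> np.ndarray:
        return _design(np.atleast_1d(np.asarray(ages, float)), self.knots, self.degree) @ self.coef_mu

    def sigma(self, ages) -> np.ndarray:
        return np.exp(
            _design(np.atleast_1d(np.asarray(ages, float)), self.knots, self.degree)
            @ self.coef_logsigma
        )

    def in_support(self, ages) -> np.ndarray:
        a = np.atleast_1d(np.asarray(ages, float))
        return (a >= self.support[0]) & (a <= self.support[1])

    def to_json(self, path=None) -> str:
        payload = {
            "biomarker": self.biomarker,
            "family": self.family,
            "knots": self.knots.tolist(),
            "degree": self.degree,
            "coef_mu": self.coef_mu.tolist(),
            "coef_logsigma": self.coef_logsigma.tolist(),
            "lam_mu": self.lam_mu,
            "lam_sigma": self.lam_sigma,
            "edf_mu": self.edf_mu,
            "edf_sigma": self.edf_sigma,
            "support": list(self.support),
            "scores": self.scores,
            "diagnostics": self.diagnostics,
            "n_subjects": self.n_subjects,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "NormativeModel":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            biomarker=payload["biomarker"],
            knots=np.asarray(payload["knots"]),
            degree=payload["degree"],
            coef_mu=np.asarray(payload["coef_mu"]),
            coef_logsigma=np.asarray(payload["coef_logsigma"]),
            lam_mu=payload["lam_mu"],
            lam_sigma=payload["lam_sigma"],
            edf_mu=payload["edf_mu"],
            edf_sigma=payload["edf_sigma"],
            support=tuple(payload["support"]),
            family=payload.get("family", "normal"),
            scores=payload.get("scores", {}),
            diagnostics=payload.get("diagnostics", {}),
            n_subjects=payload.get("n_subjects", 0),
        )


# ---------------------------------------------------------------------------
# fitting


def _fit_location_scale(
    ages: np.ndarray,
    values: np.ndarray,
    edf_mu: float,
    edf_sigma: float,
    n_interior: int = 8,
    degree: int = 3,
    tol: float = 1e-6,
    max_iter: int = 200,
    lam_mu: float | None = None,
    lam_sigma: float | None = None,
) -> NormativeModel:
    lo, hi = float(ages.min()), float(ages.max())
    knots = _make_knots(lo, hi, n_interior, degree)
    b = _design(ages, knots, degree)
    n, p = b.shape
    if np.unique(ages).size < degree + 2:
        raise ValueError(
            f"only {np.unique(ages).size} distinct ages; too few for a spline fit"
        )
    penalty = _difference_penalty(p)
    # init: linear mu, constant sigma
    coef_mu = np.linalg.solve(b.T @ b + 1e6 * np.trace(b.T @ b) * penalty, b.T @ values)
    resid = values - b @ coef_mu
    sigma = np.full(n, max(resid.std(), 1e-8))
    logsigma = np.log(sigma)
    deviance = np.inf
    fixed_lam_mu, fixed_lam_sigma = lam_mu, lam_sigma
    for iteration in range(max_iter):
        # location step: penalized WLS with weights 1 / sigma^2
        w = 1.0 / sigma**2
        btwb = b.T @ (b * w[:, None])
        cur_lam_mu = fixed_lam_mu if fixed_lam_mu is not None else _lam_for_edf(btwb, penalty, edf_mu)
        coef_mu = np.linalg.solve(btwb + cur_lam_mu * penalty, b.T @ (w * values))
        mu = b @ coef_mu
        resid = values - mu
        # scale step: Fisher scoring on log sigma (score r^2/s^2 - 1, info 2)
        for _ in range(3):
            z = logsigma + 0.5 * ((resid / np.exp(logsigma)) ** 2 - 1.0)
            btwb_s = 2.0 * (b.T @ b)
            cur_lam_sigma = (
                fixed_lam_sigma
                if fixed_lam_sigma is not None
                else _lam_for_edf(btwb_s, penalty, edf_sigma)
            )
            coef_logsigma = np.linalg.solve(btwb_s + cur_lam_sigma * penalty, 2.0 * (b.T @ z))
            logsigma = np.clip(b @ coef_logsigma, -30.0, 30.0)
        sigma = np.exp(logsigma)
        new_dev = float(-2.0 * stats.norm.logpdf(values, loc=mu, scale=sigma).sum())
        if abs(deviance - new_dev) <= tol * (abs(new_dev) + 1.0):
            deviance = new_dev
            break
        deviance = new_dev
    else:
        raise RuntimeError(
            f"location/scale fit did not converge in {max_iter} iterations "
            f"(last deviance {deviance:.6g})"
        )
    w = 1.0 / sigma**2
    edf_mu_actual = _edf(b.T @ (b * w[:, None]), cur_lam_mu, penalty)
    edf_sigma_actual = _edf(2.0 * (b.T @ b), cur_lam_sigma, penalty)
    edf_total = edf_mu_actual + edf_sigma_actual
    scores = {
        "global_deviance": deviance,
        "aic": deviance + 2.0 * edf_total,
        "sbc": deviance + np.log(n) * edf_total,
    }
    return NormativeModel(
        biomarker="",
        knots=knots,
        degree=degree,
        coef_mu=coef_mu,
        coef_logsigma=coef_logsigma,
        lam_mu=float(cur_lam_mu),
        lam_sigma=float(cur_lam_sigma),
        edf_mu=edf_mu_actual,
        edf_sigma=edf_sigma_actual,
        support=(lo, hi),
        scores=scores,
        n_subjects=n,
    )


def fit_normative(
    values: np.ndarray,
    ages: np.ndarray,
    candidates: Sequence[tuple[float, float]] | None = None,
    criterion: str = "sbc",
    biomarker: str = "",
    **fit_kwargs,
) -> NormativeModel:
    """Fit the normative location/scale model, selecting smoothness by SBC.

    ``candidates`` is a sequence of (EDF_mu, EDF_sigma) pairs; by default
    the product of EDF grid {2..8} for the location curve with {2, 3, 4}
    for the scale curve. ``criterion`` may be 'sbc' (default), 'aic' or
    'global_deviance'. Diagnostics of the winner are attached.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = np.isfinite(values) & np.isfinite(ages)
    values, ages = values[keep], ages[keep]
    if values.size < 50:
        warnings.warn(f"normative fit on only {values.size} subjects")
    if candidates is None:
        candidates = [(em, es) for em in DEFAULT_EDF_GRID for es in (2, 3, 4)]
    if criterion not in ("sbc", "aic", "global_deviance"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    best = None
    for edf_mu, edf_sigma in candidates:
        model = _fit_location_scale(ages, values, edf_mu, edf_sigma, **fit_kwargs)
        if best is None or model.scores[criterion] < best.scores[criterion]:
            best = model
    best.biomarker = biomarker
    best.diagnostics = worm_diagnostics(best, values, ages, coords=False)
    return best


# ---------------------------------------------------------------------------
# curves, scoring, diagnostics


def centile_curves(
    model: NormativeModel,
    centiles: Sequence[float] = DEFAULT_CENTILES,
    age_grid: np.ndarray | None = None,
):
    """Centile curves curve_c(age) = mu(age) + Phi^-1(c) * sigma(age).

    Returns a pandas DataFrame with an ``age`` column, one column per
    centile, and an ``extrapolated`` flag for ages outside the fit support.
    """
    import pandas as pd

    if age_grid is None:
        age_grid = np.linspace(model.support[0], model.support[1], 101)
    age_grid = np.asarray(age_grid, dtype=float)
    for c in centiles:
        if not 0.0 < c < 1.0:
            raise ValueError(f"centile {c} outside (0, 1)")
    mu = model.mu(age_grid)
    sigma = model.sigma(age_grid)
    out = {"age": age_grid}
    for c in centiles:
        out[f"c{c:g}"] = mu + stats.norm.ppf(c) * sigma
    out["extrapolated"] = ~model.in_support(age_grid)
    return pd.DataFrame(out)


@dataclass
class Score:
    z: float
    centile: float  # rounded to 2 decimals (reporting convention)
    centile_unrounded: float
    extrapolated: bool


def score_subject(model: NormativeModel, value: float, age: float) -> Score:
    """Age-adjusted Z-score and centile rank for one subject."""
    if not np.isfinite(value):
        raise ValueError("biomarker value must be finite")
    mu = float(model.mu(age)[0])
    sigma = float(model.sigma(age)[0])
    z = (value - mu) / sigma
    centile = float(stats.norm.cdf(z))
    return Score(
        z=float(z),
        centile=round(centile, 2),
        centile_unrounded=centile,
        extrapolated=not bool(model.in_support(age)[0]),
    )


def score_table(models: dict[str, NormativeModel], subjects) -> "pandas.DataFrame":
    """Score a subject table against a dict of fitted models.

    ``subjects`` needs columns id, group, age plus one column per biomarker
    named in ``models``. Returns the long-format Z-score table (one row per
    subject per biomarker).
    """
    import pandas as pd

    rows = []
    for _, rec in subjects.iterrows():
        for biomarker, model in models.items():
            value = rec[biomarker]
            if not np.isfinite(value):
                continue
            s = score_subject(model, float(value), float(rec["age"]))
            rows.append(
                {
                    "subject": rec["id"],
                    "group": rec["group"],
                    "biomarker": biomarker,
                    "z": s.z,
                    "centile": s.centile,
                    "centile_unrounded": s.centile_unrounded,
                    "extrapolated": s.extrapolated,
                }
            )
    return pd.DataFrame(rows)


def quantile_residuals(model: NormativeModel, values, ages) -> np.ndarray:
    """Normalized quantile residuals; exactly the Z-scores under the
    normal family (probability integral transform then Phi^-1)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    return (values - model.mu(ages)) / model.sigma(ages)


def worm_diagnostics(model: NormativeModel, values, ages, coords: bool = True) -> dict:
    """Residual diagnostics: moments plus detrended Q-Q (worm) coordinates.

    The worm plot shows ordered residuals minus their theoretical normal
    quantiles; under a well-specified model the worm is flat around zero
    and ~95% of points fall inside the pointwise 95% band.
    """
    r = quantile_residuals(model, values, ages)
    n = r.size
    report = {
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=1)),
        "skewness": float(stats.skew(r)),
        "kurtosis": float(stats.kurtosis(r, fisher=False)),
        "n": int(n),
    }
    if coords:
        order = np.sort(r)
        p = (np.arange(1, n + 1) - 0.5) / n
        q = stats.norm.ppf(p)
        # pointwise 95% band for the detrended Q-Q plot
        band = 1.96 * np.sqrt(p * (1 - p) / n) / stats.norm.pdf(q)
        report["worm"] = {
            "theoretical": q,
            "deviation": order - q,
            "band": band,
        }
    return report
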