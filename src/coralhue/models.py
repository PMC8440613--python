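"""Regression suite linking fish richness to coral richness and hue diversity.

The suite mirrors a standard species-richness analysis design:

* a linear model of fish richness on coral richness;
* a quadratic (second-order polynomial) model of fish richness on hue
  diversity;
* a saturating logistic curve of hue diversity on coral richness
  (hue = A / (1 + exp(-k (coral - x0)))), capturing the plateau in unique
  colours as coral richness grows;
* a combined multiple regression of fish richness on hue diversity plus
  coral richness as a second-order polynomial;
* AIC model selection over the separate and combined predictors, per fish
  family and globally, and the combined model refit within each ocean region.

Polynomial terms are fitted on an orthogonalized basis (as R's ``poly()``)
for numerical conditioning at richness values of several hundred; the
coefficients are back-transformed to the raw ``1, x, x²`` basis as well.
AIC uses the least-squares convention ``n·log(RSS/n) + 2k`` with
``k`` = number of coefficients + 1 for the error variance, so deltas are
comparable across implementations regardless of likelihood constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "ModelFit",
    "ModelComparison",
    "SingularDesignError",
    "FitFailureError",
    "ortho_poly",
    "fit_linear",
    "fit_quadratic",
    "fit_poly2_plus_hue",
    "fit_saturating",
    "compare_aic",
    "fit_family_models",
    "family_ranking",
    "fit_regional_models",
    "fit_global_suite",
]


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient (constant or collinear predictors)."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


@dataclass(frozen=True)
class ModelFit:
    """Summary of one fitted model."""

    model_label: str
    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    adjusted_r2: float
    f_statistic: float
    df_model: int
    df_residual: int
    p_value: float
    aic: float
    n: int
    rss: float = float("nan")
    raw_coefficients: dict[str, float] = field(default_factory=dict)
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "model_label": self.model_label,
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "adjusted_r2": self.adjusted_r2,
            "f_statistic": self.f_statistic,
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "p_value": self.p_value,
            "aic": self.aic,
            "n": self.n,
        }
        if self.raw_coefficients:
            d["raw_coefficients"] = self.raw_coefficients
        if self.notes:
            d["notes"] = list(self.notes)
        return d


@dataclass(frozen=True)
class ModelComparison:
    """AIC ranking of a set of fits sharing response and data."""

    fits: tuple[ModelFit, ...]
    delta_aic: dict[str, float]
    best: str

    def fit(self, label: str) -> ModelFit:
        for f in self.fits:
            if f.model_label == label:
                return f
        raise KeyError(label)


def _aic_ls(n: int, rss: float, n_coef: int) -> float:
    # least-squares AIC; +1 parameter for the error variance
    rss_per_n = max(rss / n, 1e-300)
    return n * float(np.log(rss_per_n)) + 2 * (n_coef + 1)


def ortho_poly(x: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal polynomial basis of ``x`` (no constant column).

    Returns ``(Z, C)`` where ``Z`` has ``degree`` orthonormal columns spanning
    the same space as ``x, x², ..`` after the constant, and ``C`` is the
    (degree+1, degree) matrix with ``Z = V @ C`` for the raw Vandermonde
    ``V = [1, x, .., x^degree]`` — used to map fitted coefficients back onto
    the raw basis.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise SingularDesignError("constant predictor")
    V = np.vander(x, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # drop the constant direction; fix signs so leading raw weight is positive
    Z = Q[:, 1:]
    signs = np.sign(np.diag(R)[1:])
    signs[signs == 0] = 1.0
    Z = Z * signs
    C, *_ = np.linalg.lstsq(V, Z, rcond=None)
    return Z, C


def _ols(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    label: str,
    response: str,
    raw_map: tuple[np.ndarray, Sequence[str]] | None = None,
) -> ModelFit:
    """OLS with intercept; names label the non-constant columns."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(f"{label}: singular design matrix")
    res = sm.OLS(y, design).fit()
    coefs = {"intercept": float(res.params[0])}
    coefs.update({nm: float(b) for nm, b in zip(names, res.params[1:])})
    notes: tuple[str, ...] = ()
    if np.ptp(y) == 0:
        notes = ("degenerate response (constant)",)
    raw_coefs: dict[str, float] = {}
    if raw_map is not None:
        C, raw_names = raw_map
        # beta_raw for [1, x, x², ..] from intercept + orthogonal-term betas
        beta_poly = np.array([coefs[nm] for nm in names if nm.startswith("poly")])
        beta_raw = C @ beta_poly
        beta_raw[0] += coefs["intercept"]
        raw_coefs = {nm: float(b) for nm, b in zip(raw_names, beta_raw)}
        for nm, b in zip(names, res.params[1:]):
            if not nm.startswith("poly"):
                raw_coefs[nm] = float(b)
    return ModelFit(
        model_label=label,
        response=response,
        predictors=tuple(names),
        coefficients=coefs,
        adjusted_r2=float(res.rsquared_adj) if not notes else float("nan"),
        f_statistic=float(res.fvalue) if not notes else float("nan"),
        df_model=int(res.df_model),
        df_residual=int(res.df_resid),
        p_value=float(res.f_pvalue) if not notes else float("nan"),
        aic=_aic_ls(n, float(res.ssr), design.shape[1]),
        n=n,
        rss=float(res.ssr),
        raw_coefficients=raw_coefs,
        notes=notes,
    )


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y lengths differ")
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.shape[0]}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def fit_linear(x, y, label: str = "linear", response: str = "y") -> ModelFit:
    """OLS of ``y`` on ``x`` with intercept; reports F(1, n-2)."""
    x, y = _check_xy(x, y, 3)
    if np.ptp(x) == 0:
        raise SingularDesignError("constant predictor")
    return _ols(x[:, None], y, ["x"], label, response)


def fit_quadratic(x, y, label: str = "quadratic", response: str = "y") -> ModelFit:
    """OLS of ``y`` on an orthogonalized ``{x, x²}`` basis; reports F(2, n-3)."""
    x, y = _check_xy(x, y, 4)
    Z, C = ortho_poly(x, 2)
    return _ols(
        Z, y, ["poly1", "poly2"], label, response,
        raw_map=(C, ["raw_intercept", "x", "x2"]),
    )


def fit_poly2_plus_hue(
    coral, hue, fish, label: str = "combined", response: str = "fish_richness"
) -> ModelFit:
    """Multiple regression of fish on hue + second-order polynomial in coral.

    Reports F(3, n-4): three non-constant model terms.
    """
    coral, fish = _check_xy(coral, fish, 5)
    hue = np.asarray(hue, dtype=float)
    if hue.shape[0] != coral.shape[0]:
        raise ValueError("hue length differs")
    if not np.isfinite(hue).all():
        raise ValueError("non-finite values in hue")
    Z, C = ortho_poly(coral, 2)
    X = np.column_stack([hue, Z])
    return _ols(
        X, fish, ["hue", "poly1", "poly2"], label, response,
        raw_map=(C, ["raw_intercept", "coral", "coral2"]),
    )


def _logistic(x: np.ndarray, A: float, k: float, x0: float) -> np.ndarray:
    return A / (1.0 + np.exp(-np.clip(k * (x - x0), -500, 500)))


def fit_saturating(
    coral, hue, label: str = "saturating_logistic", response: str = "hue_diversity"
) -> ModelFit:
    """Saturating logistic fit of hue diversity on coral richness.

    Fits ``hue = A / (1 + exp(-k (coral - x0)))`` by nonlinear least squares
    with a grid of starting points; ``A`` is the hue plateau (asymptote).
    Adjusted R² is computed from the residuals with 3 parameters.
    """
    coral, hue = _check_xy(coral, hue, 4)
    if (hue < 0).any():
        raise ValueError("hue diversity must be non-negative")
    n = len(coral)
    span = np.ptp(coral) or 1.0
    best = None
    starts = [
        (max(hue.max(), 1.0), 4.0 / span, np.median(coral)),
        (max(hue.max() * 1.2, 1.0), 8.0 / span, np.quantile(coral, 0.25)),
        (max(hue.max() * 1.5, 1.0), 2.0 / span, np.quantile(coral, 0.75)),
        (max(2.0 * hue.mean(), 1.0), 1.0 / span, coral.mean()),
    ]
    errors = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _logistic, coral, hue, p0=p0, maxfev=20000,
                bounds=([0.0, 1e-9, coral.min() - 2 * span],
                        [np.inf, np.inf, coral.max() + 2 * span]),
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(f"{p0}: {exc}")
            continue
        rss = float(((hue - _logistic(coral, *popt)) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailureError(
            "saturating logistic failed from all starting points: " + "; ".join(errors)
        )
    popt, rss = best
    p = 3
    tss = float(((hue - hue.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if tss > 0 else float("nan")
    # F for the regression against the mean-only model
    df_model, df_resid = p - 1, n - p
    f = ((tss - rss) / df_model) / (rss / df_resid) if rss > 0 else float("inf")
    from scipy.stats import f as f_dist

    pval = float(f_dist.sf(f, df_model, df_resid)) if np.isfinite(f) else 0.0
    return ModelFit(
        model_label=label,
        response=response,
        predictors=("logistic(A, k, x0)",),
        coefficients={"A": float(popt[0]), "k": float(popt[1]), "x0": float(popt[2])},
        adjusted_r2=float(adj),
        f_statistic=float(f),
        df_model=df_model,
        df_residual=df_resid,
        p_value=pval,
        aic=_aic_ls(n, rss, p),
        n=n,
        rss=rss,
    )


def compare_aic(fits: Sequence[ModelFit]) -> ModelComparison:
    """Rank fits by AIC (``n·log(RSS/n) + 2k`` convention).

    All fits must share the response and sample size.  Ties break to the
    first listed label.
    """
    fits = tuple(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if len({f.response for f in fits}) != 1:
        raise ValueError("fits have different responses")
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits have different sample sizes")
    aics = np.array([f.aic for f in fits])
    best_i = int(np.argmin(aics))  # first minimum wins ties
    delta = {f.model_label: float(f.aic - aics[best_i]) for f in fits}
    return ModelComparison(fits=fits, delta_aic=delta, best=fits[best_i].model_label)


def _family_comparison(table: pd.DataFrame, response_col: str) -> ModelComparison:
    coral = table["coral_richness"].to_numpy(float)
    hue = table["hue_diversity"].to_numpy(float)
    y = table[response_col].to_numpy(float)
    fits = [
        fit_linear(hue, y, label="hue_only", response=response_col),
        fit_quadratic(coral, y, label="coral_poly2", response=response_col),
        fit_poly2_plus_hue(coral, hue, y, label="combined", response=response_col),
    ]
    return compare_aic(fits)


def fit_family_models(
    table: pd.DataFrame, families: Iterable[str]
) -> dict[str, ModelComparison]:
    """Per-family model suite: hue-only, coral-poly2-only, and combined.

    ``table`` is an assembled ecoregion table with ``fish_<family>`` columns.
    Families whose response is degenerate (constant richness) get fits with
    NaN statistics and an explanatory note rather than an exception.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 ecoregions")
    out: dict[str, ModelComparison] = {}
    for fam in families:
        col = fam if fam in table.columns else f"fish_{fam}"
        if col not in table.columns:
            raise KeyError(f"family {fam!r} not in table")
        out[fam] = _family_comparison(table, col)
    return out


def family_ranking(comparisons: Mapping[str, ModelComparison]) -> pd.DataFrame:
    """Families ordered by combined-model adjusted R² (descending)."""
    rows = []
    for fam, comp in comparisons.items():
        combined = comp.fit("combined")
        rows.append(
            {
                "family": fam,
                "adjusted_r2_combined": combined.adjusted_r2,
                "adjusted_r2_hue_only": comp.fit("hue_only").adjusted_r2,
                "adjusted_r2_coral_poly2": comp.fit("coral_poly2").adjusted_r2,
                "best_by_aic": comp.best,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "adjusted_r2_combined", ascending=False, ignore_index=True
    )
    return df


def fit_regional_models(
    table: pd.DataFrame,
    region_col: str = "ocean_region",
    response_col: str = "fish_total",
    min_n: int = 6,
) -> dict[str, ModelFit]:
    """Combined poly2+hue model refit within each ocean region.

    Regions with fewer observations than model parameters + 1 are returned
    as NaN fits carrying a ``degenerate`` note; regions below ``min_n`` are
    flagged ``underpowered`` but still fitted when the df allow.
    """
    out: dict[str, ModelFit] = {}
    for region, sub in table.groupby(region_col, sort=True):
        n = len(sub)
        if n <= 4:  # 4 coefficients incl. intercept
            out[str(region)] = ModelFit(
                model_label=f"combined[{region}]",
                response=response_col,
                predictors=("hue", "poly1", "poly2"),
                coefficients={},
                adjusted_r2=float("nan"),
                f_statistic=float("nan"),
                df_model=3,
                df_residual=n - 4,
                p_value=float("nan"),
                aic=float("nan"),
                n=n,
                notes=(f"degenerate: n={n} <= parameters",),
            )
            continue
        try:
            fit = fit_poly2_plus_hue(
                sub["coral_richness"], sub["hue_diversity"], sub[response_col],
                label=f"combined[{region}]", response=response_col,
            )
        except SingularDesignError as exc:
            out[str(region)] = ModelFit(
                model_label=f"combined[{region}]",
                response=response_col,
                predictors=("hue", "poly1", "poly2"),
                coefficients={},
                adjusted_r2=float("nan"),
                f_statistic=float("nan"),
                df_model=3,
                df_residual=n - 4,
                p_value=float("nan"),
                aic=float("nan"),
                n=n,
                notes=(f"degenerate: {exc}",),
            )
            continue
        if n < min_n:
            fit = ModelFit(**{**fit.__dict__, "notes": fit.notes + ("underpowered",)})
        out[str(region)] = fit
    return out


def fit_global_suite(table: pd.DataFrame, response_col: str = "fish_total") -> dict:
    """The full global analysis on an assembled ecoregion table.

    Returns the four headline fits plus the AIC comparison of the separate
    and combined predictors of fish richness.
    """
    coral = table["coral_richness"].to_numpy(float)
    hue = table["hue_diversity"].to_numpy(float)
    fish = table[response_col].to_numpy(float)
    linear = fit_linear(coral, fish, label="fish~coral_linear", response=response_col)
    quad = fit_quadratic(hue, fish, label="fish~hue_quadratic", response=response_col)
    logistic = fit_saturating(coral, hue)
    combined = fit_poly2_plus_hue(coral, hue, fish, label="combined", response=response_col)
    comparison = compare_aic([linear, quad, combined])
    return {
        "linear_coral": linear,
        "quadratic_hue": quad,
        "saturating_hue_on_coral": logistic,
        "combined": combined,
        "aic_comparison": comparison,
    }
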