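"""Reaction-norm regression and group-level tests.

The core question for a stimulus->response relation (dowel luminance vs
larval luminance, dowel greenness vs larval greenness) is whether the
response is a continuous reaction norm and, if so, its shape: polynomial
models of order 1-4 are fitted by least squares, compared by
extra-sum-of-squares F tests, and the lowest adequate order selected.
Reference curves for the two idealised alternatives — a straight line
(continuous reaction norm) and a step (two-state polyphenism) — are
provided for comparison.

Group-level machinery covers the four experiments: one-way ANOVA across
treatments, a balanced nested ANOVA with replicate box nested within
treatment (treatment tested over the box-within-treatment mean square), and
the Brown-Forsythe variant of Levene's test (deviations from group medians)
for the heterogeneous-environment variance signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ResponseRecord",
    "records_to_frame",
    "ReactionNormFit",
    "ModelSelection",
    "GroupTestResult",
    "fit_polynomials",
    "compare_nested_fits",
    "select_best",
    "reference_responses",
    "one_way_anova",
    "nested_anova",
    "levene_test",
    "drop_most_variable_and_retest",
    "PolynomialReactionNorm",
]

ALPHA = 0.05


@dataclass
class ResponseRecord:
    """One specimen's (stimulus, response) observation with its design cell."""

    specimen_id: str
    treatment_code: str
    replicate_box: str
    stimulus: float
    response: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.stimulus) or not np.isfinite(self.response):
            raise ValueError(
                f"specimen {self.specimen_id}: non-finite stimulus/response")


def records_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "treatment": [r.treatment_code for r in records],
            "box": [r.replicate_box for r in records],
            "stimulus": [r.stimulus for r in records],
            "response": [r.response for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Polynomial reaction norms
# ---------------------------------------------------------------------------

@dataclass
class ReactionNormFit:
    """OLS polynomial fit of response on stimulus.

    Coefficients are on the raw stimulus scale, ascending order
    (beta_0 ... beta_order); the fit itself is performed in a shifted/scaled
    variable for conditioning.
    """

    order: int
    coefficients: np.ndarray
    coef_se: np.ndarray
    coef_cov: np.ndarray
    r2: float
    adj_r2: float
    rss: float
    tss: float
    residuals: np.ndarray
    n: int

    @property
    def dof(self) -> int:
        return self.n - (self.order + 1)

    def predict(self, x) -> np.ndarray:
        return P.polyval(np.asarray(x, dtype=float), self.coefficients)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Two-sided t confidence intervals for the raw coefficients,
        shape (order+1, 2)."""
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.dof)
        lo = self.coefficients - tcrit * self.coef_se
        hi = self.coefficients + tcrit * self.coef_se
        return np.column_stack([lo, hi])


def _as_xy(data, y=None) -> tuple[np.ndarray, np.ndarray]:
    if y is not None:
        return np.asarray(data, float), np.asarray(y, float)
    recs = list(data)
    return (np.array([r.stimulus for r in recs]),
            np.array([r.response for r in recs]))


def _fit_one(x: np.ndarray, y: np.ndarray, order: int) -> ReactionNormFit:
    # fit in t = (x - off)/scl for conditioning, then map back to raw scale
    off = 0.5 * (x.min() + x.max())
    scl = 0.5 * (x.max() - x.min())
    t = (x - off) / scl
    X = np.vander(t, order + 1, increasing=True)
    c, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ c
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    n, p = y.size, order + 1
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p and tss > 0 else r2

    # raw coefficients: t^k = ((x - off)/scl)^k expanded in powers of x
    T = np.zeros((p, p))
    base = np.array([-off / scl, 1.0 / scl])
    for k in range(p):
        T[: k + 1, k] = P.polypow(base, k) if k else [1.0]
    coefs = T @ c
    sigma2 = rss / (n - p) if n > p else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = T @ (sigma2 * XtX_inv) @ T.T
    se = np.sqrt(np.diag(cov))
    return ReactionNormFit(order, coefs, se, cov, r2, adj, rss, tss, resid, n)


def fit_polynomials(data, y=None, orders=(1, 2, 3, 4)) -> list[ReactionNormFit]:
    """Fit polynomial models of the given orders to (stimulus, response) data.

    ``data`` is either a list of :class:`ResponseRecord` or an x array (with
    ``y`` supplied).  An order needing more distinct stimulus values than
    available (fewer than order+2) is skipped with a warning.
    """
    x, yv = _as_xy(data, y)
    if x.size != yv.size or x.size < 3:
        raise ValueError("need matching x/y with at least 3 observations")
    n_distinct = np.unique(x).size
    fits = []
    for order in sorted(orders):
        if n_distinct < order + 2:
            warnings.warn(
                f"order {order} skipped: needs >= {order + 2} distinct "
                f"stimulus values, have {n_distinct}",
                UserWarning, stacklevel=2,
            )
            continue
        fits.append(_fit_one(x, yv, int(order)))
    if not fits:
        raise ValueError("no polynomial order could be fitted")
    return fits


def _extra_ss_f(small: ReactionNormFit, big: ReactionNormFit):
    """Extra-sum-of-squares F for nested fits; returns (F, df1, df2, p, degenerate)."""
    df1 = small.dof - big.dof
    df2 = big.dof
    if df1 <= 0 or df2 <= 0:
        raise ValueError("fits are not strictly nested")
    # residuals below numerical noise (relative to total SS) count as zero
    floor = 1e-12 * max(small.tss, big.tss)
    small_zero = small.rss <= floor
    big_zero = big.rss <= floor
    if big_zero:
        if small_zero:
            return 0.0, df1, df2, 1.0, False    # both fits already perfect
        return np.inf, df1, df2, 0.0, True
    f = ((small.rss - big.rss) / df1) / (big.rss / df2)
    f = max(f, 0.0)
    return f, df1, df2, float(sps.f.sf(f, df1, df2)), False


def compare_nested_fits(fits: list[ReactionNormFit]) -> pd.DataFrame:
    """Extra-sum-of-squares F tests between successive polynomial orders.

    A perfect higher-order fit (zero residual) is reported as F = inf with
    the ``degenerate`` flag set.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    orders = [f.order for f in fits]
    if orders != sorted(orders) or len(set(orders)) != len(orders):
        raise ValueError("fits must have strictly increasing orders")
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits are not on identical data")
    rows = []
    for small, big in zip(fits[:-1], fits[1:]):
        f, df1, df2, p, degen = _extra_ss_f(small, big)
        rows.append({
            "order_small": small.order, "order_big": big.order,
            "f": f, "df_num": df1, "df_den": df2, "p": p,
            "degenerate": degen,
        })
    return pd.DataFrame(rows)


@dataclass
class ModelSelection:
    """Chosen polynomial order with the rationale record."""

    order: int
    fit: ReactionNormFit
    alpha: float
    checks: pd.DataFrame
    rationale: str
    diagnostics: dict = field(default_factory=dict)


def _runs_z(resid: np.ndarray) -> float:
    """Wald-Wolfowitz runs z on residual signs (a curvature screen)."""
    signs = np.sign(resid)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0.0
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2 * n1 * n2 / n + 1
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
    return float((runs - mu) / np.sqrt(var)) if var > 0 else 0.0


def select_best(fits: list[ReactionNormFit],
                comparisons: pd.DataFrame | None = None,
                alpha: float = ALPHA) -> ModelSelection:
    """Lowest polynomial order not significantly improved by any higher order.

    For each candidate order, extra-sum-of-squares F tests against every
    higher fitted order are run at ``alpha``; the first candidate with no
    significant improvement wins.  Adjusted R^2 and residual-runs
    diagnostics are attached but not decisive (the original criterion also
    weighed visual fit, which is not automatable).
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to select among")
    fits = sorted(fits, key=lambda f: f.order)
    rows = []
    chosen = fits[-1]
    for i, cand in enumerate(fits):
        improved = False
        for big in fits[i + 1:]:
            f, df1, df2, p, degen = _extra_ss_f(cand, big)
            rows.append({"order": cand.order, "vs_order": big.order,
                         "f": f, "p": p, "degenerate": degen})
            if p < alpha:
                improved = True
        if not improved:
            chosen = cand
            break
    checks = pd.DataFrame(rows)
    rationale = (
        f"order {chosen.order}: no higher order (up to {fits[-1].order}) "
        f"gives a significant extra-sum-of-squares improvement at "
        f"alpha={alpha}; adjusted R^2 = {chosen.adj_r2:.4f}"
    )
    diag = {"adj_r2": {f.order: f.adj_r2 for f in fits},
            "residual_runs_z": {f.order: _runs_z(f.residuals) for f in fits}}
    return ModelSelection(chosen.order, chosen, alpha, checks, rationale, diag)


def reference_responses(stimulus_grid, extreme_low, extreme_high) -> pd.DataFrame:
    """Idealised reference curves between two extreme (stimulus, response) points.

    ``linear``: straight line joining the extremes (idealised continuous
    reaction norm).  ``stepped``: extreme-low response below the stimulus
    midpoint and extreme-high at/above it (two-state polyphenism).
    """
    x_lo, y_lo = map(float, extreme_low)
    x_hi, y_hi = map(float, extreme_high)
    if x_lo == x_hi:
        raise ValueError("extreme stimuli must differ")
    if x_lo > x_hi:
        (x_lo, y_lo), (x_hi, y_hi) = (x_hi, y_hi), (x_lo, y_lo)
    grid = np.asarray(stimulus_grid, dtype=float)
    slope = (y_hi - y_lo) / (x_hi - x_lo)
    linear = y_lo + slope * (grid - x_lo)
    mid = 0.5 * (x_lo + x_hi)
    stepped = np.where(grid < mid, y_lo, y_hi)
    return pd.DataFrame({"stimulus": grid, "linear": linear, "stepped": stepped})


# ---------------------------------------------------------------------------
# Group-level tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    statistic: float
    df: tuple[int, int]
    p_value: float
    groups: pd.DataFrame          # per-group n, mean, var, median
    method: str
    degenerate: bool = False
    note: str = ""


def _group_arrays(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = enumerate(groups)
    out = {str(k): np.asarray(v, dtype=float).ravel() for k, v in items}
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in out.items():
        if v.size < 2:
            raise ValueError(f"group '{k}': need n >= 2")
    return out


def _group_table(arrs: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": list(arrs),
            "n": [a.size for a in arrs.values()],
            "mean": [a.mean() for a in arrs.values()],
            "var": [a.var(ddof=1) for a in arrs.values()],
            "median": [np.median(a) for a in arrs.values()],
        }
    ).set_index("group")


def one_way_anova(groups) -> GroupTestResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom.  Zero
    within-group variance everywhere is flagged degenerate (F = inf when
    means differ, 0 when they do not).
    """
    arrs = _group_arrays(groups)
    k = len(arrs)
    all_y = np.concatenate(list(arrs.values()))
    n_total = all_y.size
    grand = all_y.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values())
    df = (k - 1, n_total - k)
    if ssw <= 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return GroupTestResult(f, df, p, _group_table(arrs), "one-way ANOVA",
                               degenerate=True,
                               note="zero within-group variance")
    f = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(f, *df))
    return GroupTestResult(float(f), df, p, _group_table(arrs),
                           "one-way ANOVA")


def nested_anova(records: list[ResponseRecord]) -> GroupTestResult:
    """Nested ANOVA: treatment tested over replicate-box-within-treatment.

    F = MS_treatment / MS_box(treatment) with (k-1, B-k) degrees of freedom,
    the expected-mean-squares test for a balanced two-stage design (box as
    the unit of replication for the treatment effect).  If every treatment
    has a single box there is no box stratum; falls back to a one-way ANOVA
    on individuals with a warning.
    """
    df_ = records_to_frame(records)
    k = df_["treatment"].nunique()
    if k < 2:
        raise ValueError("need >= 2 treatments")
    boxes_per = df_.groupby("treatment")["box"].nunique()
    if (boxes_per < 2).all():
        warnings.warn(
            "single replicate box per treatment: no box stratum, "
            "falling back to one-way ANOVA", UserWarning, stacklevel=2)
        groups = {t: g["response"].to_numpy()
                  for t, g in df_.groupby("treatment")}
        return one_way_anova(groups)

    grand = df_["response"].mean()
    trt = df_.groupby("treatment")["response"].agg(["mean", "size"])
    ss_treat = float((trt["size"] * (trt["mean"] - grand) ** 2).sum())
    cell = df_.groupby(["treatment", "box"])["response"].agg(["mean", "size"])
    cell = cell.join(trt["mean"].rename("trt_mean"), on="treatment")
    ss_box = float((cell["size"] * (cell["mean"] - cell["trt_mean"]) ** 2).sum())
    n_boxes = len(cell)
    df_pair = (k - 1, n_boxes - k)
    groups_tbl = _group_table(
        {t: g["response"].to_numpy() for t, g in df_.groupby("treatment")})
    ms_box = ss_box / df_pair[1] if df_pair[1] > 0 else 0.0
    if ms_box <= 0:
        f = np.inf if ss_treat > 0 else 0.0
        return GroupTestResult(f, df_pair, 0.0 if ss_treat > 0 else 1.0,
                               groups_tbl, "nested ANOVA", degenerate=True,
                               note="zero box-within-treatment variance")
    f = (ss_treat / df_pair[0]) / ms_box
    p = float(sps.f.sf(f, *df_pair))
    return GroupTestResult(float(f), df_pair, p, groups_tbl, "nested ANOVA")


def levene_test(groups, center: str = "median") -> GroupTestResult:
    """Homogeneity-of-variance test (Brown-Forsythe by default).

    One-way ANOVA on absolute deviations from each group's median (or mean
    for ``center='mean'``).  Zero deviation variance within all groups (e.g.
    every group a symmetric pair) is flagged degenerate.
    """
    arrs = _group_arrays(groups)
    centre_fn = np.median if center == "median" else np.mean
    devs = {k: np.abs(a - centre_fn(a)) for k, a in arrs.items()}
    res = one_way_anova(devs)
    return GroupTestResult(res.statistic, res.df, res.p_value,
                           _group_table(arrs),
                           f"Levene ({center}-centred)",
                           degenerate=res.degenerate, note=res.note)


def drop_most_variable_and_retest(groups, center: str = "median") -> GroupTestResult:
    """Remove the group with the largest sample variance, then re-run the
    variance-homogeneity test on the remainder.

    Ties in variance are broken deterministically toward the first group in
    sorted label order.
    """
    arrs = _group_arrays(groups)
    if len(arrs) < 3:
        raise ValueError("need >= 3 groups to drop one and retest")
    labels = sorted(arrs)
    variances = np.array([arrs[k].var(ddof=1) for k in labels])
    drop = labels[int(np.argmax(variances))]
    kept = {k: v for k, v in arrs.items() if k != drop}
    res = levene_test(kept, center=center)
    res.note = (res.note + "; " if res.note else "") + \
        f"dropped most variable group '{drop}'"
    return res


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class PolynomialReactionNorm(BaseEstimator, RegressorMixin):
    """Polynomial reaction-norm regressor with nested-F order selection.

    Fits polynomial models of order 1..``max_order`` to a 1-D stimulus and
    selects the lowest order not significantly improved by any higher order
    (extra-sum-of-squares F at ``alpha``), unless ``order`` pins the degree.

    Parameters
    ----------
    max_order : int, default 4
        Highest polynomial order to consider.
    order : int or None, default None
        Fix the order instead of selecting it.
    alpha : float, default 0.05
        Significance level for the nested model comparisons.

    Attributes
    ----------
    order_ : int
        Selected (or fixed) polynomial order.
    coef_ : ndarray of shape (order_+1,)
        Raw-scale coefficients, ascending powers.
    fit_ : ReactionNormFit
        Full fit record of the chosen order.
    fits_ : list of ReactionNormFit
        All candidate fits.
    comparison_ : DataFrame
        Successive-order extra-sum-of-squares table.
    selection_ : ModelSelection or None
        Selection record (None when ``order`` was fixed).
    """

    def __init__(self, max_order: int = 4, order: int | None = None,
                 alpha: float = ALPHA):
        self.max_order = max_order
        self.order = order
        self.alpha = alpha

    def _validate_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("stimulus must be a single column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        return X

    def fit(self, X, y):
        x = self._validate_x(X)
        y = np.asarray(y, dtype=float).ravel()
        orders = range(1, self.max_order + 1)
        self.fits_ = fit_polynomials(x, y, orders=orders)
        self.comparison_ = (compare_nested_fits(self.fits_)
                            if len(self.fits_) > 1 else None)
        if self.order is not None:
            match = [f for f in self.fits_ if f.order == self.order]
            if not match:
                raise ValueError(f"order {self.order} could not be fitted")
            self.selection_ = None
            self.fit_ = match[0]
        else:
            self.selection_ = select_best(self.fits_, alpha=self.alpha)
            self.fit_ = self.selection_.fit
        self.order_ = self.fit_.order
        self.coef_ = self.fit_.coefficients
        self.r2_ = self.fit_.r2
        self.adj_r2_ = self.fit_.adj_r2
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise AttributeError("estimator is not fitted")
        return self.fit_.predict(self._validate_x(X))
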