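"""Two-group comparison tests for PMR data.

The testing family regresses the PMR outcome (raw or ln(PMR+1)) on a binary
group indicator by weighted least squares, where the weights come from
:mod:`pmrwls.weighting`:

=============  =======================================================
``ols_pmr``    unit weights on raw PMR (ordinary least squares)
``ols_log``    unit weights on ln(PMR+1)
``ols_thresh`` 0/1 weights — drop specimens below a DNA-quantity cutoff
``wls_q``      inverse-variance weights from k quantile groups
``wls_w``      inverse-variance weights from width-w sliding windows
=============  =======================================================

Any method may additionally be run on the log scale.  Weights are treated as
known constants: the sampling uncertainty of the empirical variance estimates
is not propagated into the test.  The group contrast is assessed by a
two-sided t-test on the group coefficient with ``n_effective - 2`` degrees of
freedom, ``n_effective`` counting positively weighted observations — so a 0/1
threshold fit is numerically identical to OLS on the retained subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import weighting
from .weighting import WeightScheme, observations_to_frame

__all__ = [
    "MethodSpec",
    "TestOutcome",
    "UnestimableContrastError",
    "DegenerateFitError",
    "log_transform",
    "weighted_group_fit",
    "fit_group_comparison",
    "run_method_suite",
    "default_method_suite",
]

_METHOD_NAMES = ("ols_pmr", "ols_log", "ols_thresh", "wls_q", "wls_w")


class UnestimableContrastError(ValueError):
    """A group has no positively weighted observations."""


class DegenerateFitError(ValueError):
    """The weighted residual variance is zero; no t-test is possible."""


@dataclass(frozen=True)
class MethodSpec:
    """One analysis method with its tuning parameters.

    ``k`` (quantile groups), ``window`` and ``threshold`` are only consulted
    by the corresponding methods.  ``log_scale`` fits ln(PMR+1) instead of
    raw PMR; ``ols_log`` is shorthand for ``ols_pmr`` with ``log_scale``.
    """

    name: str
    k: int = 5
    window: int = 41
    threshold: float = 1.0
    log_scale: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in _METHOD_NAMES:
            raise ValueError(f"unknown method {self.name!r}; one of {_METHOD_NAMES}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def uses_log(self) -> bool:
        return self.log_scale or self.name == "ols_log"

    def label(self) -> str:
        base = {
            "ols_pmr": "PMR",
            "ols_log": "ln(PMR+1)",
            "ols_thresh": f"PMR[h>{self.threshold:g}]",
            "wls_q": f"WLS-Q(k={self.k})",
            "wls_w": f"WLS-W(w={self.window})",
        }[self.name]
        if self.log_scale and self.name != "ols_log":
            base += "-log"
        return base


@dataclass(frozen=True)
class TestOutcome:
    """Group-difference estimate (group 2 minus group 1) with its test."""

    estimate: float
    std_error: float
    t_statistic: float
    p_value: float
    df: float
    n_effective: int
    method: MethodSpec


def log_transform(pmr):
    """ln(PMR + 1): maps 0 to 0, compresses the right skew of PMR."""
    arr = np.asarray(pmr, dtype=float)
    if (arr < 0).any():
        raise ValueError("PMR values must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(pmr) else out


def weighted_group_fit(
    y: np.ndarray, group_indicator: np.ndarray, weights: np.ndarray
) -> tuple[float, float, float, float, float, int]:
    """Weighted least squares of y on an intercept and a 0/1 group indicator.

    Closed form for the two-parameter design: the coefficient is the
    difference in weighted group means, its standard error uses the weighted
    residual mean square on ``n_effective - 2`` degrees of freedom.  Returns
    ``(estimate, std_error, t, p, df, n_effective)``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(group_indicator, dtype=float)
    w = np.asarray(weights, dtype=float)
    live = w > 0
    n_eff = int(live.sum())
    if n_eff < 3:
        raise UnestimableContrastError("fewer than 3 positively weighted observations")
    in2 = live & (x == 1)
    in1 = live & (x == 0)
    w1, w2 = w[in1].sum(), w[in2].sum()
    if w1 <= 0 or w2 <= 0:
        raise UnestimableContrastError("a group has no positively weighted observations")
    m1 = float(np.dot(w[in1], y[in1]) / w1)
    m2 = float(np.dot(w[in2], y[in2]) / w2)
    estimate = m2 - m1
    fitted = np.where(x == 1, m2, m1)
    df = n_eff - 2
    rss = float(np.dot(w[live], (y[live] - fitted[live]) ** 2))
    sigma2 = rss / df
    if sigma2 <= 0.0:
        raise DegenerateFitError("zero weighted residual variance")
    std_error = float(np.sqrt(sigma2 * (1.0 / w1 + 1.0 / w2)))
    t_stat = estimate / std_error
    p_value = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return estimate, std_error, t_stat, p_value, df, n_eff


def _scheme_for(method: MethodSpec, frame, orientation: str) -> WeightScheme:
    if method.name in ("ols_pmr", "ols_log"):
        return weighting.uniform_weights(frame)
    if method.name == "ols_thresh":
        return weighting.threshold_weights(frame, method.threshold, orientation)
    analysis_frame = frame
    if method.uses_log:
        # variance of the analysis-scale outcome drives the weights
        analysis_frame = frame.assign(pmr=log_transform(frame["pmr"].to_numpy()))
    if method.name == "wls_q":
        return weighting.quantile_variances(analysis_frame, method.k, orientation)
    return weighting.window_variances(analysis_frame, method.window, orientation)


def _encode_groups(group_col: np.ndarray) -> np.ndarray:
    levels = np.unique(group_col)
    if len(levels) != 2:
        raise ValueError(f"group must have exactly two levels, found {len(levels)}")
    return (group_col == levels[1]).astype(float)


def fit_group_comparison(
    obs, method: MethodSpec, orientation: str = "quantity"
) -> TestOutcome:
    """Fit one method to a dataset and test the group contrast.

    ``obs`` is a DataFrame (columns pmr, surrogate, group) or a sequence of
    :class:`~pmrwls.weighting.PmrObservation`.  Groups are coded by sorted
    level order; the estimate is the second level minus the first, on the
    analysis scale (raw PMR, or ln(PMR+1) for log-scale methods).
    """
    frame = observations_to_frame(obs)
    indicator = _encode_groups(frame["group"].to_numpy())
    scheme = _scheme_for(method, frame, orientation)
    y = frame["pmr"].to_numpy(dtype=float)
    if method.uses_log:
        y = log_transform(y)
    est, se, t_stat, p, df, n_eff = weighted_group_fit(y, indicator, scheme.weights)
    return TestOutcome(
        estimate=est,
        std_error=se,
        t_statistic=t_stat,
        p_value=p,
        df=df,
        n_effective=n_eff,
        method=method,
    )


def default_method_suite(
    alpha: float = 0.05, k: int = 5, window: int = 41
) -> list[MethodSpec]:
    """The six standard methods: PMR, ln(PMR+1), PMR[h>1], PMR[h>10],
    WLS-Q and WLS-W."""
    return [
        MethodSpec("ols_pmr", alpha=alpha),
        MethodSpec("ols_log", alpha=alpha),
        MethodSpec("ols_thresh", threshold=1.0, alpha=alpha),
        MethodSpec("ols_thresh", threshold=10.0, alpha=alpha),
        MethodSpec("wls_q", k=k, alpha=alpha),
        MethodSpec("wls_w", window=window, alpha=alpha),
    ]


def run_method_suite(
    obs, methods: list[MethodSpec] | None = None, orientation: str = "quantity"
) -> list[TestOutcome | Exception]:
    """Run several methods on one dataset.

    Per-method failures are returned in place of outcomes rather than
    aborting the remaining methods.
    """
    if methods is None:
        methods = default_method_suite()
    frame = observations_to_frame(obs)
    results: list[TestOutcome | Exception] = []
    for method in methods:
        try:
            results.append(fit_group_comparison(frame, method, orientation))
        except Exception as exc:  # reported, not fatal
            results.append(exc)
    return results
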