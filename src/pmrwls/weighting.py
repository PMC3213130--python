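"""Empirical variance estimation and regression weights for PMR data.

PMR measurements are heteroscedastic: their variance grows as input DNA
quantity shrinks, because fewer genome fragments are sampled.  The weights
implemented here estimate Var(PMR) as a function of a DNA-quantity surrogate
and convert it to inverse-variance regression weights:

* quantile weights — observations are ranked by effective DNA quantity and
  split into ``k`` contiguous, nearly equal groups (quintiles by default);
  each observation receives the sample variance of PMR within its group;
* sliding-window weights — each observation receives the PMR variance of a
  centered window of ``w`` ranked neighbours (the window slides to stay
  inside the data at the extremes, so the lowest- and highest-ranked
  observations share the variance of the bottom-most / top-most ``w``);
* threshold weights — 0/1 weights reproducing the practice of simply
  excluding specimens below a minimum genome count;
* uniform weights — ordinary least squares.

The surrogate orientation must be declared: genome counts increase with DNA
quantity, while PCR cycle-threshold C(t) values decrease with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PmrObservation",
    "WeightScheme",
    "rank_by_surrogate",
    "quantile_variances",
    "window_variances",
    "threshold_weights",
    "uniform_weights",
    "observations_to_frame",
]

#: relative/absolute floor applied to estimated variances before inversion;
#: keeps weights finite when a bin of all-identical PMRs has zero variance.
VARIANCE_FLOOR_ABS = 1e-12
VARIANCE_FLOOR_REL = 1e-8

_ORIENTATIONS = ("quantity", "ct")


@dataclass(frozen=True)
class PmrObservation:
    """One specimen: PMR value, DNA-quantity surrogate and group label."""

    pmr: float
    surrogate: float
    group: object
    id: object = None

    def __post_init__(self) -> None:
        if self.pmr < 0:
            raise ValueError("pmr must be non-negative")
        if not np.isfinite(self.surrogate):
            raise ValueError("surrogate must be finite")


@dataclass(frozen=True)
class WeightScheme:
    """Per-observation variances/weights produced by one weighting method.

    ``weights`` are aligned with the *input* observation order, not the
    surrogate ranking.  For inverse-variance methods ``weights`` equals
    ``1 / max(variance, floor)``; threshold schemes carry 0/1 weights and no
    variances.
    """

    method: str
    weights: np.ndarray
    variances: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be finite and non-negative")
        object.__setattr__(self, "weights", w)
        if self.variances is not None:
            object.__setattr__(
                self, "variances", np.asarray(self.variances, dtype=float)
            )

    def to_frame(self, ids=None, surrogate=None) -> pd.DataFrame:
        """Per-sample audit table (id, surrogate, variance, weight)."""
        n = len(self.weights)
        return pd.DataFrame(
            {
                "id": ids if ids is not None else np.arange(n),
                "surrogate": surrogate if surrogate is not None else np.nan,
                "variance": self.variances if self.variances is not None else np.nan,
                "weight": self.weights,
            }
        )


def observations_to_frame(obs) -> pd.DataFrame:
    """Coerce a DataFrame or iterable of PmrObservation to a tidy frame."""
    if isinstance(obs, pd.DataFrame):
        missing = {"pmr", "surrogate", "group"} - set(obs.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        frame = obs.reset_index(drop=True)
        if "id" not in frame.columns:
            frame = frame.assign(id=np.arange(len(frame)))
        return frame
    rows = list(obs)
    if not rows:
        raise ValueError("empty observation list")
    return pd.DataFrame(
        {
            "id": [o.id if o.id is not None else i for i, o in enumerate(rows)],
            "pmr": [o.pmr for o in rows],
            "surrogate": [o.surrogate for o in rows],
            "group": [o.group for o in rows],
        }
    )


def _check_orientation(orientation: str) -> None:
    if orientation not in _ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}"
        )


def rank_by_surrogate(
    surrogate: Sequence[float] | np.ndarray, orientation: str = "quantity"
) -> np.ndarray:
    """Indices ordering observations by increasing effective DNA quantity.

    For ``orientation='ct'`` the surrogate is inverted (high C(t) = little
    DNA).  Ties are broken by input position (stable sort).
    """
    _check_orientation(orientation)
    key = np.asarray(surrogate, dtype=float)
    if key.size == 0:
        raise ValueError("empty surrogate array")
    if orientation == "ct":
        key = -key
    return np.argsort(key, kind="stable")


def _floor_and_invert(variances_ranked: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map ranked variances back to input order and invert with flooring."""
    floor = max(VARIANCE_FLOOR_ABS, VARIANCE_FLOOR_REL * float(variances_ranked.max(initial=0.0)))
    variances = np.empty_like(variances_ranked)
    variances[order] = variances_ranked
    weights = 1.0 / np.maximum(variances, floor)
    return variances, weights


def quantile_group_sizes(n: int, k: int) -> np.ndarray:
    """Contiguous group sizes: floor(n/k) each, remainder added one-per-group
    starting from the lowest-quantity group."""
    base, extra = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:extra] += 1
    return sizes


def quantile_variances_ranked(pmr_ranked: np.ndarray, k: int) -> np.ndarray:
    """Per-rank PMR variances from k contiguous quantile groups."""
    n = len(pmr_ranked)
    if k < 1:
        raise ValueError("k must be positive")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} observations for k={k} groups")
    variances = np.empty(n)
    start = 0
    for size in quantile_group_sizes(n, k):
        block = pmr_ranked[start : start + size]
        variances[start : start + size] = block.var(ddof=1)
        start += size
    return variances


def window_variances_ranked(pmr_ranked: np.ndarray, w: int) -> np.ndarray:
    """Per-rank PMR variances from sliding windows of width w (odd).

    Interior rank r uses ranks [r-m, r+m] with m=(w-1)/2; the lowest m ranks
    share the variance of ranks [0, w-1] and the highest m that of
    [n-w, n-1].
    """
    n = len(pmr_ranked)
    if w < 1 or w % 2 == 0:
        raise ValueError("window width must be an odd positive integer")
    if n < w:
        raise ValueError(f"need at least w={w} observations")
    windows = np.lib.stride_tricks.sliding_window_view(pmr_ranked, w)
    centered = windows.var(axis=1, ddof=1)  # variance for centers m..n-1-m
    m = (w - 1) // 2
    variances = np.empty(n)
    variances[m : n - m] = centered
    variances[:m] = centered[0]
    variances[n - m :] = centered[-1]
    return variances


def quantile_variances(obs, k: int = 5, orientation: str = "quantity") -> WeightScheme:
    """Inverse-variance weights from k quantile groups of DNA quantity."""
    frame = observations_to_frame(obs)
    order = rank_by_surrogate(frame["surrogate"].to_numpy(), orientation)
    ranked = frame["pmr"].to_numpy(dtype=float)[order]
    variances_ranked = quantile_variances_ranked(ranked, k)
    variances, weights = _floor_and_invert(variances_ranked, order)
    return WeightScheme(method=f"quantile(k={k})", weights=weights, variances=variances)


def window_variances(obs, w: int = 41, orientation: str = "quantity") -> WeightScheme:
    """Inverse-variance weights from sliding windows over ranked quantity."""
    frame = observations_to_frame(obs)
    order = rank_by_surrogate(frame["surrogate"].to_numpy(), orientation)
    ranked = frame["pmr"].to_numpy(dtype=float)[order]
    variances_ranked = window_variances_ranked(ranked, w)
    variances, weights = _floor_and_invert(variances_ranked, order)
    return WeightScheme(method=f"window(w={w})", weights=weights, variances=variances)


def threshold_weights(
    obs, min_quantity: float, orientation: str = "quantity"
) -> WeightScheme:
    """0/1 weights keeping only specimens above a minimum DNA quantity.

    For quantity-oriented surrogates the rule is ``surrogate > min_quantity``;
    for C(t)-oriented surrogates it is ``surrogate < min_quantity`` (fewer
    cycles = more DNA).
    """
    _check_orientation(orientation)
    frame = observations_to_frame(obs)
    s = frame["surrogate"].to_numpy(dtype=float)
    keep = (s > min_quantity) if orientation == "quantity" else (s < min_quantity)
    if not keep.any():
        raise ValueError("threshold excludes every observation")
    return WeightScheme(
        method=f"threshold(t={min_quantity})", weights=keep.astype(float)
    )


def uniform_weights(obs) -> WeightScheme:
    """Unit weights: plain OLS as a weighting scheme."""
    frame = observations_to_frame(obs)
    return WeightScheme(method="uniform", weights=np.ones(len(frame)))
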