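"""Replicate engine for false-positive-rate and power experiments.

A study repeatedly simulates two-group PMR datasets under a scenario, applies
a suite of analysis methods to every replicate, and aggregates per-method
rejection rates at a chosen significance level.  Null scenarios estimate the
false-positive rate (nominally alpha); alternative scenarios estimate power.

Reproducibility contract: every replicate draws from an independent
substream derived from the study seed via ``numpy.random.SeedSequence``, so
results are identical run-to-run and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import weighting
from .analysis import MethodSpec, default_method_suite, log_transform, weighted_group_fit
from .sampling import SimConstants
from .scenarios import (
    QuantityModel,
    ScenarioSpec,
    get_scenario,
    null_labels,
    alternative_labels,
    simulate_dataset_arrays,
    split_group_sizes,
)

__all__ = [
    "StudyConfig",
    "MethodResult",
    "StudyResult",
    "run_study",
    "power_table",
    "fpr_table",
    "window_size_sensitivity",
]


@dataclass(frozen=True)
class StudyConfig:
    """One cell of a simulation study: scenario x methods x replicates."""

    scenario: str | ScenarioSpec
    n_total: int = 200
    ratio: str = "1:1"
    replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0
    methods: tuple[MethodSpec, ...] | None = None
    constants: SimConstants = field(default_factory=SimConstants)
    quantity_model: QuantityModel = field(default_factory=QuantityModel)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def resolve_scenario(self) -> ScenarioSpec:
        spec = (
            self.scenario
            if isinstance(self.scenario, ScenarioSpec)
            else get_scenario(self.scenario)
        )
        n1, n2 = split_group_sizes(self.n_total, self.ratio)
        return spec.with_sizes(n1, n2)

    def resolve_methods(self) -> list[MethodSpec]:
        if self.methods is None:
            return default_method_suite(alpha=self.alpha)
        return list(self.methods)


@dataclass(frozen=True)
class MethodResult:
    """Aggregated rejections for one method within a study."""

    method: MethodSpec
    rejection_count: int
    failures: int
    replicates: int

    @property
    def evaluated(self) -> int:
        return self.replicates - self.failures

    @property
    def rejection_rate(self) -> float:
        return self.rejection_count / self.evaluated if self.evaluated else float("nan")

    @property
    def mc_std_error(self) -> float:
        """Binomial Monte-Carlo standard error of the rejection rate."""
        r, n = self.rejection_rate, self.evaluated
        return float(np.sqrt(r * (1.0 - r) / n)) if n else float("nan")


@dataclass(frozen=True)
class StudyResult:
    """Per-method rejection rates for one scenario/config."""

    config: StudyConfig
    scenario_label: str
    results: tuple[MethodResult, ...]

    def rate(self, label: str) -> float:
        for res in self.results:
            if res.method.label() == label:
                return res.rejection_rate
        raise KeyError(f"no method labelled {label!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario_label,
                "method": [r.method.label() for r in self.results],
                "rejections": [r.rejection_count for r in self.results],
                "failures": [r.failures for r in self.results],
                "replicates": [r.replicates for r in self.results],
                "rejection_rate": [r.rejection_rate for r in self.results],
                "mc_std_error": [r.mc_std_error for r in self.results],
            }
        )


def _suite_pvalues(
    pmr: np.ndarray,
    genomes: np.ndarray,
    indicator: np.ndarray,
    methods: list[MethodSpec],
) -> list[float | None]:
    """p-values for every method on one simulated dataset.

    Shares the quantity ranking (and any weight scheme appearing more than
    once) across methods.  Simulated genome counts are the surrogate, so the
    orientation is quantity-like and thresholds cut on true genome count.
    Returns ``None`` where a method failed.
    """
    order = np.argsort(genomes, kind="stable")
    ranked_cache: dict[bool, np.ndarray] = {}
    weight_cache: dict[tuple, np.ndarray] = {}

    def outcome(use_log: bool) -> np.ndarray:
        if use_log not in ranked_cache:
            ranked_cache[use_log] = log_transform(pmr) if use_log else pmr
        return ranked_cache[use_log]

    def weights_for(method: MethodSpec) -> np.ndarray:
        if method.name in ("ols_pmr", "ols_log"):
            return np.ones_like(pmr)
        if method.name == "ols_thresh":
            return (genomes > method.threshold).astype(float)
        key = (method.name, method.k if method.name == "wls_q" else method.window, method.uses_log)
        if key not in weight_cache:
            ranked = outcome(method.uses_log)[order]
            if method.name == "wls_q":
                var_ranked = weighting.quantile_variances_ranked(ranked, method.k)
            else:
                var_ranked = weighting.window_variances_ranked(ranked, method.window)
            _, w = weighting._floor_and_invert(var_ranked, order)
            weight_cache[key] = w
        return weight_cache[key]

    pvalues: list[float | None] = []
    for method in methods:
        try:
            y = outcome(method.uses_log)
            w = weights_for(method)
            *_, p, _, _ = weighted_group_fit(y, indicator, w)
            pvalues.append(p)
        except Exception:
            pvalues.append(None)
    return pvalues


def run_study(config: StudyConfig) -> StudyResult:
    """Run all replicates of one study cell and aggregate rejections."""
    spec = config.resolve_scenario()
    methods = config.resolve_methods()
    seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(config.replicates)

    rejections = np.zeros(len(methods), dtype=int)
    failures = np.zeros(len(methods), dtype=int)
    for child in streams:
        rng = np.random.default_rng(child)
        pmr, genomes, group, _ = simulate_dataset_arrays(
            spec, config.constants, config.quantity_model, rng
        )
        pvalues = _suite_pvalues(pmr, genomes, group.astype(float), methods)
        for j, p in enumerate(pvalues):
            if p is None:
                failures[j] += 1
            elif p <= config.alpha:
                rejections[j] += 1

    results = tuple(
        MethodResult(
            method=m,
            rejection_count=int(rejections[j]),
            failures=int(failures[j]),
            replicates=config.replicates,
        )
        for j, m in enumerate(methods)
    )
    fail_frac = failures.max(initial=0) / config.replicates
    if fail_frac > 0.01:
        import warnings

        warnings.warn(
            f"a method failed on {fail_frac:.1%} of replicates in "
            f"scenario {spec.label}",
            RuntimeWarning,
            stacklevel=2,
        )
    return StudyResult(config=config, scenario_label=spec.label, results=results)


def _grid_table(labels: list[str], replicates: int, seed: int, **kwargs) -> pd.DataFrame:
    frames = []
    for i, label in enumerate(labels):
        config = StudyConfig(
            scenario=label, replicates=replicates, seed=seed + i, **kwargs
        )
        frames.append(run_study(config).to_frame())
    return pd.concat(frames, ignore_index=True)


def power_table(
    replicates: int = 1000, seed: int = 0, labels: list[str] | None = None, **kwargs
) -> pd.DataFrame:
    """Rejection-rate table over the alternative scenarios (power)."""
    return _grid_table(labels or alternative_labels(), replicates, seed, **kwargs)


def fpr_table(
    replicates: int = 10_000, seed: int = 0, labels: list[str] | None = None, **kwargs
) -> pd.DataFrame:
    """Rejection-rate table over the null scenarios (false-positive rate)."""
    return _grid_table(labels or null_labels(), replicates, seed, **kwargs)


def window_size_sensitivity(
    n: int,
    w: int,
    replicates: int = 1000,
    seed: int = 0,
    scenario: str = "null-b.i",
    alpha: float = 0.05,
) -> StudyResult:
    """Null rejection rate of window-based WLS at a given sample and window
    size.

    Window-based weights need enough observations per window to stabilize
    the variance estimates; too small a window at a small sample size
    inflates the type-I error.
    """
    config = StudyConfig(
        scenario=scenario,
        n_total=n,
        replicates=replicates,
        seed=seed,
        alpha=alpha,
        methods=(MethodSpec("wls_w", window=w, alpha=alpha),),
    )
    return run_study(config)
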