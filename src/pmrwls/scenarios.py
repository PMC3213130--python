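"""Population-level simulation scenarios for two-group methylation studies.

A scenario describes, for each of two patient groups, the population
distribution of the true methylation proportion ``p``: a Bernoulli positivity
indicator (a tumor either carries detectable methylation or has ``p = 0``)
mixed with a Beta distribution for the methylation level of positive tumors.
Input DNA quantity is drawn from a capped lognormal: with ``L`` lognormal
(log-mean 0, log-sd 0.75), the genome count is ``Q = 10**(2.74 - L)``, so
Q never exceeds 10^2.74 ≈ 550 genomes, ~23% of specimens carry fewer than 10
genomes and ~9% fewer than 1 — the regime where fragment-sampling noise
dominates.

The registry bundles the standard nine alternative scenarios (group mean
differences of 0.07 for pure-Beta scenarios, 0.13 for Beta-Bernoulli
mixtures) and six null scenarios used to calibrate type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sampling import SimConstants, simulate_pmr_batch

__all__ = [
    "GroupDistribution",
    "ScenarioSpec",
    "QuantityModel",
    "beta_from_moments",
    "sample_true_proportions",
    "sample_dna_quantity",
    "scenario_registry",
    "null_labels",
    "alternative_labels",
    "split_group_sizes",
    "simulate_dataset",
    "simulate_dataset_arrays",
    "scenario_from_dict",
    "scenario_to_dict",
]


def beta_from_moments(mean: float, var: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a given mean and variance.

    Solves the moment equations: with ``k = mean*(1-mean)/var - 1``,
    ``alpha = mean*k`` and ``beta = (1-mean)*k``.  Raises ``ValueError`` when
    the variance is infeasible (``var >= mean*(1-mean)``).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be in (0, 1)")
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValueError(
            f"variance {var} infeasible for mean {mean}; must be in (0, {bound})"
        )
    k = bound / var - 1.0
    return mean * k, (1.0 - mean) * k


@dataclass(frozen=True)
class GroupDistribution:
    """Beta-Bernoulli mixture for true methylation proportions in one group.

    With probability ``1 - positivity_prob`` a tumor is unmethylated
    (``p = 0``); otherwise ``p`` is Beta-distributed with the given mean and
    variance.  ``positivity_prob = 1`` reduces to a pure Beta.
    """

    positivity_prob: float
    beta_mean: float
    beta_var: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.positivity_prob <= 1.0:
            raise ValueError("positivity_prob must be in [0, 1]")
        beta_from_moments(self.beta_mean, self.beta_var)  # feasibility check

    @property
    def shape_params(self) -> tuple[float, float]:
        return beta_from_moments(self.beta_mean, self.beta_var)

    @property
    def overall_mean(self) -> float:
        """Mean of p including the unmethylated fraction."""
        return self.positivity_prob * self.beta_mean

    @property
    def overall_var(self) -> float:
        """Variance of p including the unmethylated fraction."""
        pi = self.positivity_prob
        second_moment = pi * (self.beta_var + self.beta_mean**2)
        return second_moment - (pi * self.beta_mean) ** 2


@dataclass(frozen=True)
class ScenarioSpec:
    """Two-group scenario: per-group methylation distributions and sizes."""

    label: str
    group1: GroupDistribution
    group2: GroupDistribution
    n1: int = 100
    n2: int = 100

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")

    @property
    def is_null(self) -> bool:
        return self.group1 == self.group2

    @property
    def mean_difference(self) -> float:
        return self.group2.overall_mean - self.group1.overall_mean

    def with_sizes(self, n1: int, n2: int) -> "ScenarioSpec":
        return replace(self, n1=n1, n2=n2)


@dataclass(frozen=True)
class QuantityModel:
    """Capped-lognormal model of input DNA quantity (genome equivalents).

    ``log10 Q = log10_cap - L`` with ``ln L ~ Normal(log_mean, log_sd**2)``.
    Defaults give max 10^2.74 ≈ 550 genomes, P(Q < 10) ≈ 0.23 and
    P(Q < 1) ≈ 0.09.
    """

    log10_cap: float = 2.74
    log_sd: float = 0.75
    log_mean: float = 0.0

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError("log_sd must be positive")

    def cdf(self, q: float) -> float:
        """Analytic P(Q < q): Q < q  iff  L > log10_cap - log10(q)."""
        from scipy.stats import lognorm

        threshold = self.log10_cap - np.log10(q)
        if threshold <= 0:
            return 1.0
        return float(
            lognorm.sf(threshold, s=self.log_sd, scale=np.exp(self.log_mean))
        )


def sample_true_proportions(
    dist: GroupDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n true methylation proportions from a Beta-Bernoulli mixture."""
    alpha, beta = dist.shape_params
    p = rng.beta(alpha, beta, size=n)
    if dist.positivity_prob < 1.0:
        positive = rng.random(n) < dist.positivity_prob
        p = np.where(positive, p, 0.0)
    return p


def sample_dna_quantity(
    model: QuantityModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n genome-equivalent DNA quantities from the capped lognormal."""
    length_scale = rng.lognormal(model.log_mean, model.log_sd, size=n)
    return 10.0 ** (model.log10_cap - length_scale)


# Registry construction ------------------------------------------------------

_VARIANCE_PATTERNS = {"i": (0.01, 0.01), "ii": (0.04, 0.04), "iii": (0.01, 0.04)}


def _build_registry() -> dict[str, ScenarioSpec]:
    registry: dict[str, ScenarioSpec] = {}

    # Alternatives: a (low means), b (moderate means), both pure Beta;
    # c adds a positivity-probability difference on top of the b means.
    mean_families = {"a": (0.2, 0.27), "b": (0.4, 0.47), "c": (0.4, 0.47)}
    for family, (m1, m2) in mean_families.items():
        pi1, pi2 = (0.5, 0.7) if family == "c" else (1.0, 1.0)
        for roman, (v1, v2) in _VARIANCE_PATTERNS.items():
            label = f"{family}.{roman}"
            registry[label] = ScenarioSpec(
                label=label,
                group1=GroupDistribution(pi1, m1, v1),
                group2=GroupDistribution(pi2, m2, v2),
            )

    # Nulls: the cross of Beta means {0.2, 0.4} x variances {0.01, 0.04}
    # plus Beta-Bernoulli mixtures of the moderate-mean Betas at pi = 0.67.
    for family, mean in (("a", 0.2), ("b", 0.4)):
        for roman, var in (("i", 0.01), ("ii", 0.04)):
            label = f"null-{family}.{roman}"
            g = GroupDistribution(1.0, mean, var)
            registry[label] = ScenarioSpec(label=label, group1=g, group2=g)
    for roman, var in (("i", 0.01), ("ii", 0.04)):
        label = f"null-c.{roman}"
        g = GroupDistribution(0.67, 0.4, var)
        registry[label] = ScenarioSpec(label=label, group1=g, group2=g)

    return registry


_REGISTRY = _build_registry()


def scenario_registry() -> dict[str, ScenarioSpec]:
    """All built-in scenarios: 9 alternatives (a.i…c.iii) and 6 nulls."""
    return dict(_REGISTRY)


def get_scenario(label: str) -> ScenarioSpec:
    try:
        return _REGISTRY[label]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown scenario {label!r}; known labels: {known}") from None


def alternative_labels() -> list[str]:
    return [lbl for lbl in _REGISTRY if not lbl.startswith("null-")]


def null_labels() -> list[str]:
    return [lbl for lbl in _REGISTRY if lbl.startswith("null-")]


def split_group_sizes(n_total: int, ratio: str = "1:1") -> tuple[int, int]:
    """Group sizes for a total sample size under a 1:1, 1:2 or 2:1 ratio.

    Group 1 takes the nearest integer share when the split is not exact
    (e.g. 200 at 1:2 -> (67, 133)).
    """
    try:
        r1, r2 = (int(part) for part in ratio.split(":"))
    except ValueError:
        raise ValueError(f"invalid ratio {ratio!r}; expected like '1:2'") from None
    if r1 < 1 or r2 < 1:
        raise ValueError("ratio parts must be positive")
    n1 = int(round(n_total * r1 / (r1 + r2)))
    n2 = n_total - n1
    if n1 < 1 or n2 < 1:
        raise ValueError("total too small for the requested ratio")
    return n1, n2


# Dataset simulation ---------------------------------------------------------


def simulate_dataset_arrays(
    spec: ScenarioSpec,
    consts: SimConstants,
    qmodel: QuantityModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one dataset; returns (pmr, genomes, group, true_p) arrays.

    Group membership is deterministic by count: the first ``n1`` tumors are
    group 1 (coded 0) and the remaining ``n2`` are group 2 (coded 1), so every
    replicate has exact group sizes.
    """
    n = spec.n1 + spec.n2
    p = np.empty(n)
    p[: spec.n1] = sample_true_proportions(spec.group1, spec.n1, rng)
    p[spec.n1 :] = sample_true_proportions(spec.group2, spec.n2, rng)
    genomes = sample_dna_quantity(qmodel, n, rng)
    group = np.repeat([0, 1], [spec.n1, spec.n2])
    pmr = simulate_pmr_batch(genomes, p, consts, rng)
    return pmr, genomes, group, p


def simulate_dataset(
    spec: ScenarioSpec,
    consts: SimConstants | None = None,
    qmodel: QuantityModel | None = None,
    rng: np.random.Generator | None = None,
    include_truth: bool = False,
) -> pd.DataFrame:
    """Simulate one two-group PMR dataset as a tidy DataFrame.

    Columns: ``id``, ``pmr``, ``surrogate`` (the simulated genome count, a
    quantity-oriented surrogate), ``group`` (1 or 2); with ``include_truth``,
    the latent ``true_p`` is appended for auditing.
    """
    consts = consts or SimConstants()
    qmodel = qmodel or QuantityModel()
    rng = rng if rng is not None else np.random.default_rng()
    pmr, genomes, group, p = simulate_dataset_arrays(spec, consts, qmodel, rng)
    frame = pd.DataFrame(
        {
            "id": [f"{spec.label}-{i:04d}" for i in range(len(pmr))],
            "pmr": pmr,
            "surrogate": genomes,
            "group": group + 1,
        }
    )
    if include_truth:
        frame["true_p"] = p
    frame.attrs["orientation"] = "quantity"
    frame.attrs["scenario"] = spec.label
    return frame


# Config (de)serialization ---------------------------------------------------


def _group_to_dict(g: GroupDistribution) -> dict:
    return {
        "positivity_prob": g.positivity_prob,
        "beta_mean": g.beta_mean,
        "beta_var": g.beta_var,
    }


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "label": spec.label,
        "group1": _group_to_dict(spec.group1),
        "group2": _group_to_dict(spec.group2),
        "n1": spec.n1,
        "n2": spec.n2,
    }


def scenario_from_dict(data: dict) -> ScenarioSpec:
    return ScenarioSpec(
        label=data["label"],
        group1=GroupDistribution(**data["group1"]),
        group2=GroupDistribution(**data["group2"]),
        n1=int(data.get("n1", 100)),
        n2=int(data.get("n2", 100)),
    )
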