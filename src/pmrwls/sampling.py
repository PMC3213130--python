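"""Binomial fragment-sampling model of MethyLight PMR measurements.

MethyLight quantifies locus-specific DNA methylation as a Percent Methylated
Reference (PMR): the methylated-allele fraction of a tumor aliquot divided by
that of a fully methylated (M.SssI-treated) reference, times 100.  Because
archival specimens yield variable, often tiny, amounts of amplifiable DNA, the
measurement is a ratio of counts obtained by *sampling fragments* of the
genome, and its precision degrades sharply as input DNA decreases.

The generative model implemented here treats a specimen as a pool of
``h * f`` fragments (``h`` haploid genome equivalents, ``f`` fragments per
genome).  The number of methylated target alleles captured, ``B``, is binomial
with size ``G = round(h * f)`` and success probability ``p / f``, where ``p``
is the true proportion of methylated target alleles.  The reference aliquot
contributes ``B_r ~ Binomial(G_r, c / f)`` with ``G_r`` fixed at the reference
genome count times ``f`` and ``c`` the bisulfite-conversion / M.SssI
efficiency (1 under complete conversion).  The observable is

    PMR = 100 * (B / G) / (B_r / G_r)

which is 0 exactly when ``B = 0`` (a false-negative when ``p > 0``) and may
legitimately exceed 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimConstants",
    "SpecimenTruth",
    "FragmentDraw",
    "DegenerateReferenceError",
    "DegenerateSpecimenError",
    "compute_pmr",
    "sample_fragment_draw",
    "prob_zero_detection",
    "prob_zero_detection_exact",
    "simulate_pmr",
    "simulate_pmr_batch",
]


class DegenerateReferenceError(RuntimeError):
    """Raised when the reference draw yields zero methylated fragments."""


class DegenerateSpecimenError(ValueError):
    """Raised when a PMR is requested for a specimen with no fragments."""


@dataclass(frozen=True)
class SimConstants:
    """Fragmentation and reference constants shared by a whole study.

    Parameters
    ----------
    fragments_per_genome
        Number of measurable DNA fragments per haploid genome (``f``).  The
        default 10⁴ reflects ALU-based quantification of fragmented DNA.
    reference_genomes
        Haploid genome equivalents in the M.SssI-treated reference aliquot.
    conversion_efficiency
        Proportion of the reference target that is actually methylated;
        1.0 means complete M.SssI treatment.  Values below 1 bias PMR upward.
    """

    fragments_per_genome: int = 10_000
    reference_genomes: float = 5_500.0
    conversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.fragments_per_genome < 1:
            raise ValueError("fragments_per_genome must be >= 1")
        if not self.reference_genomes > 0:
            raise ValueError("reference_genomes must be positive")
        if not 0.0 < self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency must be in (0, 1]")

    @property
    def reference_fragments(self) -> int:
        """Fixed fragment count of the reference aliquot, ``G_r``."""
        return int(round(self.reference_genomes * self.fragments_per_genome))


@dataclass(frozen=True)
class SpecimenTruth:
    """Latent state of one specimen: genome count ``h`` and methylation ``p``."""

    genomes: float
    methylation_proportion: float

    def __post_init__(self) -> None:
        if self.genomes < 0:
            raise ValueError("genomes must be non-negative")
        if not 0.0 <= self.methylation_proportion <= 1.0:
            raise ValueError("methylation_proportion must be in [0, 1]")


@dataclass(frozen=True)
class FragmentDraw:
    """Realized fragment counts for one tumor/reference reaction pair."""

    methylated_tumor: int
    fragments_tumor: int
    methylated_reference: int
    fragments_reference: int

    def __post_init__(self) -> None:
        if self.methylated_tumor > self.fragments_tumor:
            raise ValueError("methylated_tumor cannot exceed fragments_tumor")
        if self.methylated_reference > self.fragments_reference:
            raise ValueError(
                "methylated_reference cannot exceed fragments_reference"
            )
        if min(
            self.methylated_tumor,
            self.fragments_tumor,
            self.methylated_reference,
            self.fragments_reference,
        ) < 0:
            raise ValueError("fragment counts must be non-negative")


def compute_pmr(draw: FragmentDraw) -> float:
    """Percent Methylated Reference from realized fragment counts.

    ``PMR = 100 * (B/G) / (B_r/G_r)``.  Returns exactly 0.0 iff ``B == 0``.
    Raises :class:`DegenerateSpecimenError` if the tumor aliquot has no
    fragments, and :class:`DegenerateReferenceError` if methylated alleles
    were observed in the tumor but none in the reference (undefined ratio).
    """
    if draw.fragments_tumor == 0:
        raise DegenerateSpecimenError("tumor aliquot contains no fragments")
    if draw.fragments_reference == 0:
        raise DegenerateReferenceError("reference aliquot contains no fragments")
    if draw.methylated_tumor == 0:
        return 0.0
    if draw.methylated_reference == 0:
        raise DegenerateReferenceError(
            "no methylated fragments in reference; PMR undefined"
        )
    tumor_frac = draw.methylated_tumor / draw.fragments_tumor
    ref_frac = draw.methylated_reference / draw.fragments_reference
    return 100.0 * tumor_frac / ref_frac


def sample_fragment_draw(
    truth: SpecimenTruth,
    consts: SimConstants,
    rng: np.random.Generator,
    max_reference_retries: int = 100,
) -> FragmentDraw:
    """Draw tumor and reference fragment counts for one specimen.

    ``G = round(h * f)``, ``B ~ Binomial(G, p/f)``; the reference fragment
    count is fixed at its expectation ``G_r = round(reference_genomes * f)``
    while ``B_r ~ Binomial(G_r, c/f)`` is drawn per reaction.  A zero ``B_r``
    (probability ~exp(-5500) at default constants) is redrawn up to
    ``max_reference_retries`` times before raising, so the PMR ratio stays
    defined without noticeably biasing the reference distribution.
    """
    f = consts.fragments_per_genome
    g_tumor = int(round(truth.genomes * f))
    b_tumor = int(rng.binomial(g_tumor, truth.methylation_proportion / f)) if g_tumor else 0

    g_ref = consts.reference_fragments
    p_ref = consts.conversion_efficiency / f
    b_ref = int(rng.binomial(g_ref, p_ref))
    retries = 0
    while b_ref == 0 and retries < max_reference_retries:
        b_ref = int(rng.binomial(g_ref, p_ref))
        retries += 1
    if b_ref == 0:
        raise DegenerateReferenceError(
            f"reference draw produced 0 methylated fragments in "
            f"{max_reference_retries + 1} attempts; reference too small"
        )
    return FragmentDraw(b_tumor, g_tumor, b_ref, g_ref)


def prob_zero_detection(truth: SpecimenTruth) -> float:
    """Probability of a false-negative PMR of zero, ``(1 - p)**h``.

    This is the asymptotic (fragment-count-free) form; it treats each of the
    ``h`` genomes as an independent Bernoulli(p) detection opportunity.  See
    :func:`prob_zero_detection_exact` for the finite-fragment binomial form.
    """
    return (1.0 - truth.methylation_proportion) ** truth.genomes


def prob_zero_detection_exact(truth: SpecimenTruth, consts: SimConstants) -> float:
    """Exact zero-PMR probability under the binomial model.

    ``Pr(B = 0) = (1 - p/f)**round(h*f)`` — agrees with ``(1-p)**h`` as
    ``f`` grows, to within ~0.01 for p <= 0.3 at the default f = 10^4.
    """
    f = consts.fragments_per_genome
    g = int(round(truth.genomes * f))
    return (1.0 - truth.methylation_proportion / f) ** g


def simulate_pmr(
    truth: SpecimenTruth,
    consts: SimConstants,
    rng: np.random.Generator,
) -> float:
    """Simulate one PMR measurement for a specimen.

    Composition of :func:`sample_fragment_draw` and :func:`compute_pmr`.
    A specimen whose aliquot rounds to zero fragments cannot capture any
    methylated allele, so its PMR is 0 by construction.
    """
    draw = sample_fragment_draw(truth, consts, rng)
    if draw.fragments_tumor == 0:
        return 0.0
    return compute_pmr(draw)


def simulate_pmr_batch(
    genomes: np.ndarray,
    proportions: np.ndarray,
    consts: SimConstants,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized PMR simulation for arrays of specimens.

    Equivalent in distribution to calling :func:`simulate_pmr` per specimen;
    one reference reaction is drawn per specimen.  Specimens with zero
    rounded fragment count yield PMR = 0.
    """
    genomes = np.asarray(genomes, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    if genomes.shape != proportions.shape:
        raise ValueError("genomes and proportions must have the same shape")
    f = consts.fragments_per_genome
    g = np.rint(genomes * f).astype(np.int64)
    b = rng.binomial(g, proportions / f)

    g_ref = consts.reference_fragments
    b_ref = rng.binomial(g_ref, consts.conversion_efficiency / f, size=g.shape)
    for _ in range(100):
        zero = b_ref == 0
        if not zero.any():
            break
        b_ref[zero] = rng.binomial(g_ref, consts.conversion_efficiency / f, size=int(zero.sum()))
    else:
        raise DegenerateReferenceError("reference draws persistently zero")

    pmr = np.zeros_like(genomes, dtype=float)
    live = (b > 0) & (g > 0)
    pmr[live] = 100.0 * (b[live] / g[live]) / (b_ref[live] / g_ref)
    return pmr
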