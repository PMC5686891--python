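"""Demographic, mutational, and balanced-locus parameter containers.

Times are in generations before present, sizes are effective numbers of
haploid lineages (both study species are highly selfing, and published
allele counts are out of 81 and 23 haploid genomes), and rates are per
lineage per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "EpochSchedule",
    "Migration",
    "DemographicModel",
    "MutationModel",
    "BalancedLocus",
    "model_m1",
    "model_m2",
    "GENERATIONS_PER_YEAR",
]

#: Both species are annuals; calendar years and generations are interchanged 1:1.
GENERATIONS_PER_YEAR = 1.0


@dataclass(frozen=True)
class EpochSchedule:
    """Piecewise-constant population-size history for one species.

    ``epochs`` is an ordered list of ``(start_time, size)`` pairs: the
    population has ``size`` haploid lineages from ``start_time`` (inclusive,
    generations before present) until the next epoch's start. The first
    start time must be 0.
    """

    epochs: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(n <= 0 for _, n in self.epochs):
            raise ValueError("population sizes must be positive")

    @property
    def starts(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs], dtype=np.float64)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs], dtype=np.float64)

    def size_at(self, t: float) -> float:
        """Population size at time ``t`` generations before present."""
        idx = int(np.searchsorted(self.starts, t, side="right")) - 1
        return float(self.sizes[max(idx, 0)])


@dataclass(frozen=True)
class Migration:
    """Ancient gene flow between the two species.

    Rates are forward-in-time per-lineage migration probabilities per
    generation; the flow is only active inside ``window`` (generations
    before present), which must lie within ``(0, split_time]``.
    """

    rate_a_to_c: float
    rate_c_to_a: float
    window: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.rate_a_to_c < 0 or self.rate_c_to_a < 0:
            raise ValueError("migration rates must be non-negative")
        lo, hi = self.window
        if not (0 < lo < hi):
            raise ValueError("migration window must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class DemographicModel:
    """Two-species divergence model with piecewise-constant sizes.

    ``schedule_a``/``schedule_c`` describe each species back to
    ``split_time``, after which the merged ancestral population has constant
    size ``ancestral_size``. Optional ancient ``migration`` is restricted to
    a window before the split.
    """

    schedule_a: EpochSchedule
    schedule_c: EpochSchedule
    split_time: float
    ancestral_size: float
    migration: Optional[Migration] = None

    def __post_init__(self) -> None:
        if self.split_time < 0:
            raise ValueError("split_time must be non-negative")
        if self.ancestral_size <= 0:
            raise ValueError("ancestral_size must be positive")
        if self.migration is not None:
            lo, hi = self.migration.window
            if hi > self.split_time:
                raise ValueError("migration window must lie within (0, split_time]")

    def without_migration(self) -> "DemographicModel":
        return DemographicModel(
            self.schedule_a, self.schedule_c, self.split_time, self.ancestral_size
        )


@dataclass(frozen=True)
class MutationModel:
    """Finite-sites mutation model with a CpG rate class.

    A site belongs to the CpG class iff the trinucleotide centred on it in
    the ancestral reference contains a CG dinucleotide overlapping the focal
    base; those sites mutate at ``mu_base * cpg_multiplier``.
    """

    mu_base: float = 7e-9
    cpg_multiplier: float = 3.5
    #: stationary base composition used to draw ancestral reference sequence
    base_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.mu_base <= 0:
            raise ValueError("mu_base must be positive")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or min(self.base_freqs) < 0:
            raise ValueError("base_freqs must be a probability vector")


@dataclass(frozen=True)
class BalancedLocus:
    """Mechanistic stand-in for a site under long-term balancing selection.

    Lineages carry one of two allelic classes with frequencies ``(f, 1-f)``
    held constant in both species and the ancestor. Coalescence is confined
    to a class (rate scaled by ``1/(f_class * N)``), lineages switch classes
    at ``exchange_rate``, and classes only merge at ``origin_time``, which
    must pre-date the species split — this is what generates genealogies
    that cluster by allele rather than by species.
    """

    position: int
    class_frequency: float
    origin_time: float
    exchange_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.class_frequency < 1):
            raise ValueError("class_frequency must lie in (0, 1)")
        if self.exchange_rate < 0:
            raise ValueError("exchange_rate must be non-negative")
        if self.position < 0:
            raise ValueError("position must be non-negative")


# Fitted divergence histories for the A. thaliana / C. rubella pair.
# M1: no gene flow. Sizes are haploid lineage counts; times in generations.
_T_SPLIT = 8.0e6
_T_ARAB = 5.84e6  # A. thaliana separates from the rest of its genus
_T_CAPS = 0.40e6  # C. rubella bottleneck at speciation from C. grandiflora


def model_m1() -> DemographicModel:
    """Divergence model without gene flow (the better-fitting model)."""
    return DemographicModel(
        schedule_a=EpochSchedule(((0.0, 519_000.0), (_T_ARAB, 2_230_000.0))),
        schedule_c=EpochSchedule(((0.0, 129_000.0), (_T_CAPS, 4_037_000.0))),
        split_time=_T_SPLIT,
        ancestral_size=4_930_000.0,
    )


def model_m2() -> DemographicModel:
    """Divergence model with weak ancient gene flow before the within-genus
    split of the first species (window (5.84, 8] Myr ago)."""
    return DemographicModel(
        schedule_a=EpochSchedule(((0.0, 519_000.0), (_T_ARAB, 3_270_000.0))),
        schedule_c=EpochSchedule(((0.0, 129_000.0), (_T_CAPS, 1_972_000.0))),
        split_time=_T_SPLIT,
        ancestral_size=4_930_000.0,
        migration=Migration(
            rate_a_to_c=7e-14, rate_c_to_a=1e-8, window=(_T_ARAB, _T_SPLIT)
        ),
    )
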