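"""Ecological divergence between haplotype groups.

Accessions are split into two groups by the alleles they carry at a gene's
paired trans-species polymorphic sites; this module asks whether the two
groups occupy different ecological niches. Occurrence records are spatially
thinned (>= 5 km apart), a Gaussian environmental-envelope suitability
surface is fitted per group over a landscape of cells x standardized
factors, niche overlap is summarized by Warren's I, and significance comes
from comparing the observed I against permuted group assignments (three
permutation strategies, one-sample t-test as well as a permutation rank p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SuitabilityGrid",
    "NicheComparison",
    "haversine_km",
    "thin_samples",
    "fit_suitability",
    "warrens_i",
    "niche_identity_test",
    "STRATEGIES",
]

EARTH_RADIUS_KM = 6371.0

STRATEGIES = (
    "label_permutation",
    "mixed_resample_real_sizes",
    "mixed_resample_equal_sizes",
    "within_group_resample",
)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def thin_samples(
    samples: pd.DataFrame,
    min_km: float = 5.0,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized greedy spatial thinning.

    Repeatedly drops one sample among those with the most neighbors closer
    than ``min_km`` (ties broken uniformly at random) until all pairs are at
    least ``min_km`` apart; the best (largest-retention) of ``n_reps``
    repetitions is returned. ``samples`` needs ``latitude``/``longitude``
    columns."""
    lat = samples["latitude"].to_numpy(np.float64)
    lon = samples["longitude"].to_numpy(np.float64)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    n = len(samples)
    dist = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    close = (dist < min_km) & ~np.eye(n, dtype=bool)
    rng = np.random.default_rng(seed)
    best: Optional[np.ndarray] = None
    for _ in range(max(n_reps, 1)):
        keep = np.ones(n, dtype=bool)
        deg = close.sum(axis=1).astype(np.int64)
        while True:
            active_deg = np.where(keep, deg, -1)
            dmax = active_deg.max()
            if dmax <= 0:
                break
            cands = np.flatnonzero(active_deg == dmax)
            drop = int(rng.choice(cands))
            keep[drop] = False
            deg[close[drop] & keep] -= 1
            deg[drop] = 0
        if best is None or keep.sum() > best.sum():
            best = keep
    return samples.loc[best].copy()


@dataclass
class SuitabilityGrid:
    """Normalized habitat-suitability surface over landscape cells."""

    cell_ids: np.ndarray
    suitability: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        s = float(self.suitability.sum())
        if abs(s - 1.0) > 1e-12:
            raise ValueError("suitability must be normalized to 1")
        if np.any(self.suitability < 0):
            raise ValueError("suitability must be non-negative")


def fit_suitability(
    sample_factors: pd.DataFrame,
    landscape: pd.DataFrame,
    threshold: Optional[float] = None,
) -> SuitabilityGrid:
    """Gaussian environmental envelope over a landscape.

    Per-factor mean and variance are estimated from the group's samples
    (factors treated as independent); each cell's suitability is the product
    of factor normal densities, normalized over cells. With ``threshold``
    (e.g. 0.5), support is restricted to cells whose max-normalized
    suitability reaches it before renormalizing — the "high probability
    niche" variant."""
    if len(sample_factors) < 3:
        raise ValueError("need at least 3 samples to fit an envelope")
    cols = list(landscape.columns)
    mu = sample_factors[cols].mean(axis=0).to_numpy(np.float64)
    sd = sample_factors[cols].std(axis=0, ddof=1).to_numpy(np.float64)
    sd = np.where(sd > 1e-9, sd, 1e-9)
    cells = landscape.to_numpy(np.float64)
    logd = -0.5 * (((cells - mu) / sd) ** 2).sum(axis=1) - np.log(sd).sum()
    logd -= logd.max()
    suit = np.exp(logd)
    if threshold is not None:
        suit = np.where(suit / suit.max() >= threshold, suit, 0.0)
    total = suit.sum()
    if total <= 0:
        raise ValueError("degenerate suitability surface")
    suit = suit / total
    suit = suit / suit.sum()  # exact renormalization
    return SuitabilityGrid(cell_ids=landscape.index.to_numpy(), suitability=suit)


def warrens_i(g1: SuitabilityGrid, g2: SuitabilityGrid) -> float:
    """Warren's niche-identity statistic I = 1 − ½ Σ (√p1 − √p2)², ranging
    from 0 (no overlap) to 1 (identical niches)."""
    if len(g1.suitability) != len(g2.suitability):
        raise ValueError("grids must share the same cell set")
    h2 = 0.5 * float(((np.sqrt(g1.suitability) - np.sqrt(g2.suitability)) ** 2).sum())
    return 1.0 - h2


@dataclass
class NicheComparison:
    observed_i: float
    permuted_i: np.ndarray
    strategy: str
    p_t_test: float
    p_permutation: float
    n_permutations: int
    seed: int


def niche_identity_test(
    sample_factors: pd.DataFrame,
    groups: Sequence,
    landscape: pd.DataFrame,
    strategy: str = "label_permutation",
    n_perm: int = 100,
    seed: int = 0,
    threshold: Optional[float] = None,
) -> NicheComparison:
    """Warren's I niche-identity test under one of four permutation schemes.

    * ``label_permutation`` — pool all samples and redraw two groups of the
      real sizes without replacement (the classic identity test);
    * ``mixed_resample_real_sizes`` — pool and draw two groups of the real
      sizes with replacement;
    * ``mixed_resample_equal_sizes`` — pool and draw two groups of the
      smaller group's size;
    * ``within_group_resample`` — redraw subsets *within* each true group
      (a robustness check of the observed I itself: significant divergence
      should NOT appear here).

    Returns the observed I, the permuted I values, a one-sample t-test p of
    the observed value against the permuted distribution, and the
    permutation-rank p (fraction of permuted I <= observed, for the
    one-sided "lower identity than random" alternative).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if landscape.std(axis=0).max() <= 0:
        raise ValueError("degenerate landscape: all cells identical")
    groups = pd.Series(list(groups), index=sample_factors.index)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    idx1 = sample_factors.index[groups == labels[0]]
    idx2 = sample_factors.index[groups == labels[1]]
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError("both groups need at least 3 samples")

    def i_for(ix1, ix2) -> float:
        s1 = fit_suitability(sample_factors.loc[ix1], landscape, threshold)
        s2 = fit_suitability(sample_factors.loc[ix2], landscape, threshold)
        return warrens_i(s1, s2)

    i_obs = i_for(idx1, idx2)
    rng = np.random.default_rng(seed)
    pooled = np.array(list(idx1) + list(idx2))
    n1, n2 = len(idx1), len(idx2)
    n_eq = min(n1, n2)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        if strategy == "label_permutation":
            order = rng.permutation(len(pooled))
            a, b = pooled[order[:n1]], pooled[order[n1:]]
        elif strategy == "mixed_resample_real_sizes":
            a = rng.choice(pooled, size=n1, replace=True)
            b = rng.choice(pooled, size=n2, replace=True)
        elif strategy == "mixed_resample_equal_sizes":
            a = rng.choice(pooled, size=n_eq, replace=True)
            b = rng.choice(pooled, size=n_eq, replace=True)
        else:  # within_group_resample
            a = rng.choice(np.array(idx1), size=n1, replace=True)
            b = rng.choice(np.array(idx2), size=n2, replace=True)
        perms[k] = i_for(a, b)

    if np.allclose(perms, perms[0]):
        p_t = 1.0 if np.isclose(i_obs, perms[0]) else 0.0
    else:
        p_t = float(sps.ttest_1samp(perms, i_obs).pvalue)
    p_perm = float((np.count_nonzero(perms <= i_obs) + 1) / (n_perm + 1))
    return NicheComparison(
        observed_i=i_obs, permuted_i=perms, strategy=strategy,
        p_t_test=p_t, p_permutation=p_perm, n_permutations=n_perm, seed=seed,
    )
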