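"""Diversity statistics and the hypothesis-testing layer.

Covers per-window nucleotide diversity and minor-allele frequencies, the
rank-sum comparison of candidate windows against a simulated neutral
background, Benjamini–Hochberg FDR correction, the chi-square test for
population-structure confounding, and the generic two-group divergence scan
used both for ecological factors and for expression (FPKM) tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simdata import GenotypeAlignment

__all__ = [
    "TestResult",
    "nucleotide_diversity",
    "maf",
    "ranksum_background_test",
    "bh_fdr",
    "chisq_association",
    "group_divergence_scan",
    "gene_window_diversity",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    q_value: Optional[float] = None
    n1: Optional[int] = None
    n2: Optional[int] = None


def nucleotide_diversity(
    aln_or_geno, species: Optional[str] = None
) -> float:
    """Mean pairwise per-site difference fraction (π).

    Accepts a GenotypeAlignment (optionally restricted to one species) or a
    raw (n, L) base-code matrix. Gap/N columns are deleted pairwise: each
    sample pair is compared over its own set of jointly called sites."""
    if isinstance(aln_or_geno, GenotypeAlignment):
        geno = aln_or_geno.geno
        if species is not None:
            geno = geno[aln_or_geno.species_slice(species)]
    else:
        geno = np.asarray(aln_or_geno)
    n = geno.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            keep = (geno[i] < 4) & (geno[j] < 4)
            m = int(keep.sum())
            if m == 0:
                continue
            total += float(np.count_nonzero(geno[i][keep] != geno[j][keep])) / m
            pairs += 1
    if pairs == 0:
        return float("nan")
    return total / (n * (n - 1) / 2)


def maf(count: int, n: int) -> float:
    """Minor allele frequency min(count, n-count)/n (full precision; round
    only for presentation)."""
    if not (0 <= count <= n):
        raise ValueError("count must lie in [0, n]")
    return min(count, n - count) / n


def ranksum_background_test(
    observed: Sequence[float],
    background: Sequence[float],
    alternative: str = "greater",
) -> TestResult:
    """Wilcoxon–Mann–Whitney rank-sum test of observed values against a
    simulated background (exact enumeration when combined n <= 20 and no
    ties, normal approximation with tie correction otherwise)."""
    observed = np.asarray(observed, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if len(observed) == 0 or len(background) == 0:
        raise ValueError("both samples must be non-empty")
    if np.array_equal(np.sort(observed), np.sort(background)):
        # identical samples: U sits exactly at its null mean
        return TestResult(
            test_name="wilcoxon-mann-whitney",
            statistic=len(observed) * len(background) / 2.0,
            p_value=1.0, n1=len(observed), n2=len(background),
        )
    method = "auto" if len(observed) + len(background) <= 20 else "asymptotic"
    res = sps.mannwhitneyu(observed, background, alternative=alternative, method=method)
    return TestResult(
        test_name="wilcoxon-mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(observed),
        n2=len(background),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (R p.adjust "fdr")."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def chisq_association(table: np.ndarray, correction: bool = False) -> TestResult:
    """Pearson chi-square association between structure group and allele
    class (no continuity correction by default); genes whose trans-species
    sites associate with structure at FDR < 0.05 are excluded downstream."""
    table = np.asarray(table, dtype=np.float64)
    if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
        chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    else:
        chi2, p = 0.0, 1.0
    return TestResult(test_name="chi-square", statistic=float(chi2), p_value=float(p))


def group_divergence_scan(
    values: pd.DataFrame,
    groups: Sequence,
    alternative: str = "two-sided",
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-variable rank-sum divergence between two sample groups with BH
    correction over the variable set.

    ``values`` is samples x variables; ``groups`` assigns each sample to one
    of exactly two labels. Used identically for ecological factors and for
    expression tables. Returns one row per variable (statistic, p, q)."""
    groups = pd.Series(list(groups), index=values.index)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for var in values.columns:
        col = values[var]
        g1 = col[(groups == labels[0]) & col.notna()]
        g2 = col[(groups == labels[1]) & col.notna()]
        if len(g1) < min_group or len(g2) < min_group:
            rows.append({"variable": var, "statistic": np.nan, "p": np.nan,
                         "n1": len(g1), "n2": len(g2)})
            continue
        if np.array_equal(np.sort(g1), np.sort(g2)) or (g1.nunique() == 1 and g2.nunique() == 1 and g1.iloc[0] == g2.iloc[0]):
            stat, p = len(g1) * len(g2) / 2.0, 1.0
        else:
            res = sps.mannwhitneyu(g1, g2, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"variable": var, "statistic": stat, "p": p,
                     "n1": len(g1), "n2": len(g2)})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def gene_window_diversity(
    aln: GenotypeAlignment,
    allelic_windows: Sequence[Tuple[int, int]],
) -> Tuple[float, float]:
    """Gene-level π per species, averaged over exactly the allelic-tree
    windows (the windows that passed the full scan criteria), matching how
    per-gene diversity is summarized for candidate genes."""
    if not allelic_windows:
        return float("nan"), float("nan")
    pis_a, pis_c = [], []
    for start, end in allelic_windows:
        sub = aln.geno[:, start:end]
        pis_a.append(nucleotide_diversity(sub[: aln.n_a]))
        pis_c.append(nucleotide_diversity(sub[aln.n_a:]))
    return float(np.nanmean(pis_a)), float(np.nanmean(pis_c))
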