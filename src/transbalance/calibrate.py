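"""Neutrality calibration for the trans-species polymorphism scan.

Three questions are answered here. (1) How likely is a *neutral* shared
polymorphism to be identical by descent given the demographic model — via
the classic survival probability P = exp(-T/2N_A) · exp(-T/2N_C) and its
piecewise generalization Σ Δt_i/(2 N_i)? (2) How long an unbroken ancestral
tract would survive recombination over the divergence time? (3) Empirically,
how often does the full scan criteria chain fire on purely neutral windows
(the mass-simulation false-positive experiment)?
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import _kernels
from ._kernels import INF
from .models import DemographicModel, MutationModel
from .simdata import GenotypeAlignment, _default_samples, _model_arrays, _wrap_alignment
from .tspscan import scan_gene

__all__ = [
    "NeutralTSPReport",
    "FalsePositiveReport",
    "neutral_tsp_probability",
    "expected_neutral_tsp_count",
    "expected_tract_length",
    "false_positive_scan",
]


@dataclass
class NeutralTSPReport:
    """Identity-by-descent survival probability of a neutral polymorphism.

    ``exponent_a``/``exponent_c`` are the per-species coalescent exponents
    (T/(2N) in constant mode, Σ Δt_i/(2 N_i) up to the split in piecewise
    mode); P = exp(-(exponent_a + exponent_c)).
    """

    variant: str  # "constant" or "piecewise"
    exponent_a: float
    exponent_c: float
    probability: float


def _piecewise_exponent(starts: np.ndarray, sizes: np.ndarray, T: float) -> float:
    """∫_0^T dt / (2 N(t)) for a piecewise-constant size history."""
    total = 0.0
    for i in range(len(starts)):
        lo = starts[i]
        hi = starts[i + 1] if i + 1 < len(starts) else T
        hi = min(hi, T)
        if hi <= lo:
            continue
        total += (hi - lo) / (2.0 * sizes[i])
    return total


def neutral_tsp_probability(model: DemographicModel, mode: str = "piecewise") -> NeutralTSPReport:
    """Probability that a neutral polymorphism survives the species split in
    both lineages.

    ``constant`` mode applies the survival formula with the two current
    sizes; ``piecewise`` mode replaces each T/(2N) exponent with the epoch
    sum Σ Δt_i/(2 N_i) integrated up to the split time."""
    T = model.split_time
    if mode == "constant":
        ea = T / (2.0 * model.schedule_a.sizes[0])
        ec = T / (2.0 * model.schedule_c.sizes[0])
    elif mode == "piecewise":
        ea = _piecewise_exponent(model.schedule_a.starts, model.schedule_a.sizes, T)
        ec = _piecewise_exponent(model.schedule_c.starts, model.schedule_c.sizes, T)
    else:
        raise ValueError("mode must be 'constant' or 'piecewise'")
    return NeutralTSPReport(
        variant=mode, exponent_a=ea, exponent_c=ec,
        probability=math.exp(-(ea + ec)),
    )


def expected_neutral_tsp_count(probability: float, aligned_sites: int) -> float:
    """Expected genome-wide count of neutral trans-species polymorphisms:
    the per-site survival probability times the number of aligned sites."""
    if not (0.0 <= probability <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    return probability * aligned_sites


def expected_tract_length(r: float, T: float) -> float:
    """Expected unbroken ancestral tract length around a trans-species
    polymorphism, in bp.

    Over 2T generations of independent ancestry on both sides of the focal
    site, the distance to the first recombination on either side is
    exponential with rate r·2T per bp; the two-sided expected total is
    2/(r·2T). Returns inf when r == 0."""
    if r < 0 or T < 0:
        raise ValueError("rate and time must be non-negative")
    if r == 0 or T == 0:
        return float("inf")
    return 2.0 / (r * 2.0 * T)


@dataclass
class FalsePositiveReport:
    """Criteria-chain counts of the neutral mass simulation: each stage is a
    subset of the previous one."""

    model_id: str
    n_windows: int
    n_with_shared_snp: int
    n_with_two_shared: int
    n_with_ld_pair: int
    n_allelic_tree: int
    seed: int
    n_a: int = 81
    n_c: int = 23

    def as_dict(self) -> Dict[str, int]:
        return {
            "model": self.model_id,
            "n_windows": self.n_windows,
            "with_shared_snp": self.n_with_shared_snp,
            "with_two_shared": self.n_with_two_shared,
            "with_ld_pair": self.n_with_ld_pair,
            "allelic_tree": self.n_allelic_tree,
            "seed": self.seed,
        }


def _chunk_seed(seed: int, chunk: int) -> int:
    # simple splitmix-style derivation, kept under 2^31
    x = (seed * 0x9E3779B1 + chunk * 0x85EBCA77 + 0x165667B1) & 0x7FFFFFFF
    return x or 1


def false_positive_scan(
    model: DemographicModel,
    mut: MutationModel,
    n_windows: int,
    n_a: int = 81,
    n_c: int = 23,
    length: int = 100,
    maf_min: float = 0.05,
    r2_min: float = 0.5,
    seed: int = 0,
    chunk_size: int = 20_000,
    model_id: str = "M1",
    manifest_path: Optional[Path] = None,
) -> FalsePositiveReport:
    """Run the full scan criteria chain over neutral 100-bp windows.

    Windows are simulated in chunks with per-chunk derived seeds (the run is
    resumable from the manifest); each window is screened for >=2 shared
    bi-allelic SNPs with MAF > ``maf_min`` in both species and an LD pair
    with r^2 > ``r2_min`` in both species; survivors get the neighbor-joining
    topology classification. Under the fitted demographies no neutral window
    is expected to yield an allelic tree."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    base_cum = np.cumsum(np.asarray(mut.base_freqs, dtype=np.float64))
    arrays = _model_arrays(model)
    c1 = c2 = c3 = c4 = 0
    done = 0
    chunk = 0
    while done < n_windows:
        todo = min(chunk_size, n_windows - done)
        s1, s2, s3, kept, n_kept = _kernels.neutral_window_screen_batch(
            np.uint32(_chunk_seed(seed, chunk)), todo, n_a, n_c, length,
            *arrays, mut.mu_base, mut.cpg_multiplier, base_cum,
            maf_min, r2_min, 256,
        )
        c1 += s1
        c2 += s2
        c3 += s3
        for w in range(n_kept):
            aln = _wrap_alignment(kept[w].copy(), n_a, n_c)
            report = scan_gene(aln, maf_min=maf_min, r2_min=r2_min)
            if report.is_candidate:
                c4 += 1
        done += todo
        chunk += 1
        if manifest_path is not None:
            Path(manifest_path).write_text(json.dumps({
                "model": model_id, "seed": seed, "windows_done": done,
                "with_shared_snp": c1, "with_two_shared": c2,
                "with_ld_pair": c3, "allelic_tree": c4,
            }))
    return FalsePositiveReport(
        model_id=model_id, n_windows=n_windows,
        n_with_shared_snp=c1, n_with_two_shared=c2,
        n_with_ld_pair=c3, n_allelic_tree=c4,
        seed=seed, n_a=n_a, n_c=n_c,
    )
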