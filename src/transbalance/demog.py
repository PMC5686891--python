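"""Joint-SFS demographic inference by simulation-based composite likelihood.

The two-species divergence model is fitted to the joint site frequency
spectrum of putatively neutral (fourfold-degenerate-like) sites: expected
cell probabilities come from Monte-Carlo coalescent simulation (branch-length
accumulation), the composite log-likelihood sums observed cell counts times
log probabilities, models are compared by AIC/Akaike weights, and confidence
intervals come from a gene-level block bootstrap.

Folding convention: the joint SFS is folded *jointly* — cell (i, j) is merged
with its complement (n_A - i, n_C - j) — so fixed inter-species differences
stay distinct from monomorphic sites and the divergence time remains
identifiable without ancestral-allele polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from . import _kernels
from ._kernels import INF
from .models import DemographicModel, EpochSchedule, Migration, MutationModel
from .simdata import _model_arrays

__all__ = [
    "JointSFS",
    "ModelFit",
    "joint_sfs",
    "fold_joint",
    "expected_sfs",
    "composite_loglik",
    "M1Template",
    "M2Template",
    "fit_model",
    "compare_models_aic",
    "block_bootstrap_ci",
    "simulate_site_spectrum",
]


@dataclass
class JointSFS:
    """Two-dimensional site frequency spectrum.

    ``counts[i, j]`` is the number of sites with (minor) allele count i in
    species A and j in species C; monomorphic sites sit in cell (0, 0).
    """

    counts: np.ndarray
    n_a: int
    n_c: int
    folded: bool = True

    def polymorphic_mask(self) -> np.ndarray:
        mask = np.ones_like(self.counts, dtype=bool)
        mask[0, 0] = False
        if not self.folded:
            mask[self.n_a, self.n_c] = False
        return mask

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


def fold_joint(counts: np.ndarray) -> np.ndarray:
    """Fold an unfolded joint SFS: merge (i, j) with (n_a-i, n_c-j), keeping
    the lexicographically smaller cell. Idempotent."""
    n_a = counts.shape[0] - 1
    n_c = counts.shape[1] - 1
    out = np.zeros_like(counts)
    for i in range(n_a + 1):
        for j in range(n_c + 1):
            ci, cj = n_a - i, n_c - j
            if (i, j) <= (ci, cj):
                out[i, j] += counts[i, j]
            else:
                out[ci, cj] += counts[i, j]
    return out


def joint_sfs(
    sites: Sequence[Tuple[int, int]], n_a: int, n_c: int, fold: bool = True
) -> JointSFS:
    """Tabulate per-site derived/alt allele counts ``(count_a, count_c)``
    into the joint SFS. Monomorphic-in-both sites land in (0, 0)."""
    counts = np.zeros((n_a + 1, n_c + 1), dtype=np.int64)
    for ca, cc in sites:
        if not (0 <= ca <= n_a and 0 <= cc <= n_c):
            raise ValueError(f"allele count ({ca},{cc}) outside panel sizes")
        counts[ca, cc] += 1
    if fold:
        counts = fold_joint(counts)
    return JointSFS(counts=counts, n_a=n_a, n_c=n_c, folded=fold)


def expected_sfs(
    model: DemographicModel,
    mut: MutationModel,
    n_a: int,
    n_c: int,
    n_sims: int = 100_000,
    seed: int = 0,
    fold: bool = True,
) -> np.ndarray:
    """Monte-Carlo expected cell probabilities of the joint SFS.

    Per simulated genealogy, a site is monomorphic with probability
    exp(-mu L) and otherwise its mutation lands on a branch proportional to
    length; cell probabilities average these over ``n_sims`` genealogies.
    The monomorphic mass sits in cell (0, 0) and — because mu is known —
    anchors the absolute scale of sizes and times. Unobserved polymorphic
    cells get a floor of 1/(10 n_sims) before renormalization so the
    composite likelihood stays finite."""
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    acc = _kernels.sfs_branch_batch(
        np.uint32(seed), n_sims, n_a, n_c, *_model_arrays(model), mut.mu_base
    )
    if fold:
        acc = fold_joint(acc)
    probs = acc / n_sims
    floor = 1.0 / (10.0 * n_sims)
    mask = np.ones_like(probs, dtype=bool)
    mask[0, 0] = False
    if not fold:
        mask[n_a, n_c] = False
    poly_mass = probs[mask].sum()
    probs[mask & (probs < floor)] = floor
    probs[mask] *= poly_mass / probs[mask].sum()
    return probs


def composite_loglik(
    obs: JointSFS, probs: np.ndarray, min_support: int = 6,
    include_monomorphic: bool = True,
) -> float:
    """Sum over unmasked cells of m_ij * ln p_ij; polymorphic cells observed
    fewer than ``min_support`` times are ignored.

    The monomorphic (0, 0) cell is included whenever the expected spectrum
    carries mass there: without that term the composite likelihood is
    invariant to rescaling all sizes and times together and the fit cannot
    identify the absolute scale."""
    if obs.counts.shape != probs.shape:
        raise ValueError("spectrum shapes do not match")
    mask = obs.polymorphic_mask() & (obs.counts >= min_support) & (probs > 0)
    m = obs.counts[mask].astype(np.float64)
    ll = float(np.sum(m * np.log(probs[mask])))
    if include_monomorphic and probs[0, 0] > 0 and obs.counts[0, 0] > 0:
        ll += float(obs.counts[0, 0]) * float(np.log(probs[0, 0]))
    return ll


def simulate_site_spectrum(
    model: DemographicModel,
    mut: MutationModel,
    n_sites: int,
    n_a: int,
    n_c: int,
    seed: int = 0,
    fold: bool = True,
) -> JointSFS:
    """Simulate an observed joint SFS of independent neutral sites (each
    site draws its own genealogy; at most one mutation per site)."""
    counts = _kernels.site_sfs_sample_batch(
        np.uint32(seed), n_sites, n_a, n_c, *_model_arrays(model), mut.mu_base
    )
    if fold:
        counts = fold_joint(counts)
    return JointSFS(counts=counts, n_a=n_a, n_c=n_c, folded=fold)


# ---------------------------------------------------------------------------
# model templates: map a free-parameter vector to a DemographicModel


@dataclass
class M1Template:
    """No-gene-flow template. Free parameters (log10 scale): current size of
    each species and the split time; epoch-change times and the remaining
    sizes are held at the template's values."""

    base: DemographicModel
    k: int = 3

    def build(self, theta: np.ndarray) -> DemographicModel:
        n_a_cur, n_c_cur, t_split = 10.0 ** np.asarray(theta)
        sched_a = self.base.schedule_a
        sched_c = self.base.schedule_c
        new_a = EpochSchedule(
            ((0.0, n_a_cur),) + tuple(sched_a.epochs[1:])
        )
        new_c = EpochSchedule(
            ((0.0, n_c_cur),) + tuple(sched_c.epochs[1:])
        )
        # keep epoch boundaries inside the split
        t_split = max(t_split, max(new_a.starts.max(), new_c.starts.max()) + 1.0)
        return DemographicModel(
            schedule_a=new_a,
            schedule_c=new_c,
            split_time=t_split,
            ancestral_size=self.base.ancestral_size,
        )


@dataclass
class M2Template:
    """Adds two ancient-migration rates (log10) to the M1 parameters; the
    migration window tracks [last epoch change of species A, split]."""

    base: DemographicModel
    k: int = 5

    def build(self, theta: np.ndarray) -> DemographicModel:
        m1 = M1Template(self.base).build(np.asarray(theta)[:3])
        r_ac, r_ca = 10.0 ** np.asarray(theta)[3:5]
        lo = float(m1.schedule_a.starts.max())
        if lo <= 0:
            lo = m1.split_time / 2.0
        if r_ac <= 1e-30 and r_ca <= 1e-30:
            return m1
        return DemographicModel(
            schedule_a=m1.schedule_a,
            schedule_c=m1.schedule_c,
            split_time=m1.split_time,
            ancestral_size=m1.ancestral_size,
            migration=Migration(rate_a_to_c=r_ac, rate_c_to_a=r_ca,
                                window=(lo, m1.split_time)),
        )


@dataclass
class ModelFit:
    template_name: str
    estimates: Dict[str, float]
    theta: np.ndarray
    max_loglik: float
    k: int
    aic: float
    n_starts: int
    trajectories: List[Tuple[np.ndarray, float]]
    akaike_weight: Optional[float] = None
    bootstrap_ci: Optional[Dict[str, Tuple[float, float]]] = None
    converged: bool = True


def _estimates_from_theta(theta: np.ndarray, names: Sequence[str]) -> Dict[str, float]:
    return {nm: float(10.0 ** th) for nm, th in zip(names, theta)}


def fit_model(
    obs: JointSFS,
    template,
    bounds: Sequence[Tuple[float, float]],
    mut: MutationModel = MutationModel(),
    n_starts: int = 50,
    n_sims: int = 20_000,
    seed: int = 0,
    min_support: int = 6,
    maxiter: int = 200,
) -> ModelFit:
    """Maximize the composite log-likelihood by multi-start Nelder–Mead on
    log10-transformed parameters.

    The expected SFS inside one fit always uses the same simulation seed
    (common random numbers), which makes the Monte-Carlo objective a
    deterministic function of the parameters and the fit reproducible.
    Parameters with zero-width bounds (lo == hi) are held fixed and consume
    no randomness, so a nesting model with its extra parameters pinned
    reproduces the reduced model's fit exactly under the same seed."""
    bounds = np.asarray(bounds, dtype=np.float64)
    free = bounds[:, 0] < bounds[:, 1]
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(0, 2**31))

    def full_theta(theta_free: np.ndarray) -> np.ndarray:
        theta = bounds[:, 0].copy()
        theta[free] = np.clip(theta_free, bounds[free, 0], bounds[free, 1])
        return theta

    def objective(theta_free: np.ndarray) -> float:
        model = template.build(full_theta(theta_free))
        probs = expected_sfs(
            model, mut, obs.n_a, obs.n_c, n_sims=n_sims, seed=sim_seed,
            fold=obs.folded,
        )
        return -composite_loglik(obs, probs, min_support=min_support)

    trajectories = []
    best = None
    converged = False
    for _ in range(n_starts):
        x0 = rng.uniform(bounds[free, 0], bounds[free, 1])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2},
        )
        trajectories.append((full_theta(res.x), -res.fun))
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = full_theta(best.x)
    names = ["N_A_current", "N_C_current", "T_split", "mig_a_to_c", "mig_c_to_a"][
        : len(theta_hat)
    ]
    max_ll = -float(best.fun)
    k = template.k if hasattr(template, "k") else len(theta_hat)
    return ModelFit(
        template_name=type(template).__name__,
        estimates=_estimates_from_theta(theta_hat, names),
        theta=theta_hat,
        max_loglik=max_ll,
        k=k,
        aic=2 * k - 2 * max_ll,
        n_starts=n_starts,
        trajectories=trajectories,
        converged=converged,
    )


def compare_models_aic(fits: Sequence[ModelFit]) -> List[ModelFit]:
    """AIC = 2k − 2·maxlogCL; Akaike weights w_i ∝ exp(−ΔAIC_i / 2)."""
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return [replace(f, akaike_weight=float(wi)) for f, wi in zip(fits, w)]


def block_bootstrap_ci(
    blocks: Sequence[Sequence[Tuple[int, int]]],
    fit_procedure: Callable[[Sequence[Tuple[int, int]]], Dict[str, float]],
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> Dict[str, Tuple[float, float]]:
    """Percentile confidence intervals from a gene-level block bootstrap.

    ``blocks`` are per-gene site collections; each replicate resamples genes
    with replacement, pools their sites, and re-runs ``fit_procedure`` (any
    callable returning a name->estimate dict)."""
    rng = np.random.default_rng(seed)
    n = len(blocks)
    reps: Dict[str, List[float]] = {}
    for _ in range(n_boot):
        pick = rng.integers(0, n, size=n)
        sites: List[Tuple[int, int]] = []
        for b in pick:
            sites.extend(blocks[b])
        est = fit_procedure(sites)
        for key, val in est.items():
            reps.setdefault(key, []).append(val)
    alpha = (1.0 - level) / 2.0
    return {
        key: (
            float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1.0 - alpha)),
        )
        for key, vals in reps.items()
    }
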