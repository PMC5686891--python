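"""Sliding-window allelic-tree scan.

The scan slides 100-bp windows (1-bp step) over genic alignments, keeps
windows with at least 95 effectively aligned sites per species that cover at
least two shared SNPs in strong linkage disequilibrium (r^2 > 0.5) in both
species, builds a neighbor-joining tree from Kimura two-parameter distances,
and classifies the topology: windows whose samples cluster by allele across
the species boundary (rather than by species) are trans-species-polymorphism
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .orthoshare import SharedSNP, find_shared_snps
from .simdata import GenotypeAlignment

__all__ = [
    "WindowCandidate",
    "WindowClassification",
    "TreeStructure",
    "window_iter",
    "ld_r2",
    "k2p_distance",
    "k2p_distance_matrix",
    "p_distance_matrix",
    "nj_tree",
    "classify_topology",
    "scan_gene",
    "GeneScanReport",
]

_TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


@dataclass
class WindowCandidate:
    start: int  # 0-based column
    end: int    # exclusive
    valid: bool
    aligned_a: int
    aligned_c: int
    shared_columns: List[int]


@dataclass
class TreeStructure:
    """Unrooted NJ tree over the window's samples.

    ``edges`` are (node_u, node_v, length); leaves are nodes 0..n_leaves-1
    in input order; ``clusters`` maps each internal edge to the leaf set on
    its far side (the source of the bipartition set).
    """

    n_leaves: int
    labels: List[str]
    edges: List[Tuple[int, int, float]]
    clusters: Dict[int, FrozenSet[int]]  # internal node -> leaf set below it
    parent_len: Dict[int, float]  # node -> length of the edge above it

    def bipartitions(self, min_branch: float = 1e-12) -> Set[FrozenSet[int]]:
        """Nontrivial bipartitions supported by an internal edge of positive
        length (zero-length edges are treated as polytomies), normalized to
        the side not containing leaf 0."""
        full = frozenset(range(self.n_leaves))
        out: Set[FrozenSet[int]] = set()
        for node, leafset in self.clusters.items():
            if len(leafset) < 2 or len(leafset) > self.n_leaves - 2:
                continue
            if self.parent_len.get(node, 0.0) <= min_branch:
                continue
            side = leafset if 0 not in leafset else full - leafset
            out.add(frozenset(side))
        return out

    def newick(self) -> str:
        adj: Dict[int, List[Tuple[int, float]]] = {}
        for u, v, ln in self.edges:
            adj.setdefault(u, []).append((v, ln))
            adj.setdefault(v, []).append((u, ln))
        root = max(adj)

        def rec(node: int, parent: int) -> str:
            kids = [(v, ln) for v, ln in adj[node] if v != parent]
            if not kids:
                return self.labels[node]
            inner = ",".join(f"{rec(v, node)}:{ln:.6g}" for v, ln in kids)
            return f"({inner})"

        return rec(root, -1) + ";"


def window_iter(
    aln: GenotypeAlignment,
    shared_columns: Sequence[int],
    size: int = 100,
    step: int = 1,
    min_aligned: int = 95,
) -> Iterator[WindowCandidate]:
    """Yield every window covering at least one shared SNP, flagged valid iff
    it has >= ``min_aligned`` effectively aligned (A/C/G/T in every sample)
    columns in each species."""
    if aln.length < size:
        return
    shared = np.asarray(sorted(shared_columns), dtype=np.int64)
    geno = aln.geno
    n_a = aln.n_a
    ok_a = np.all(geno[:n_a] < 4, axis=0).astype(np.int64)
    ok_c = np.all(geno[n_a:] < 4, axis=0).astype(np.int64)
    cum_a = np.concatenate([[0], np.cumsum(ok_a)])
    cum_c = np.concatenate([[0], np.cumsum(ok_c)])
    for start in range(0, aln.length - size + 1, step):
        end = start + size
        lo = np.searchsorted(shared, start, side="left")
        hi = np.searchsorted(shared, end, side="left")
        if hi == lo:
            continue
        aligned_a = int(cum_a[end] - cum_a[start])
        aligned_c = int(cum_c[end] - cum_c[start])
        yield WindowCandidate(
            start=start,
            end=end,
            valid=aligned_a >= min_aligned and aligned_c >= min_aligned,
            aligned_a=aligned_a,
            aligned_c=aligned_c,
            shared_columns=[int(c) for c in shared[lo:hi]],
        )


def ld_r2(
    aln: GenotypeAlignment, col1: int, col2: int
) -> Tuple[Optional[float], Optional[float]]:
    """Haploid r^2 between two columns, per species.

    r^2 = D^2 / (p(1-p) q(1-q)) from haplotype counts; samples missing
    (gap/N) at either column are excluded; None if a column is not
    bi-allelic within the species after exclusion."""
    out = []
    for sl in (aln.species_slice("A"), aln.species_slice("C")):
        a = aln.geno[sl, col1]
        b = aln.geno[sl, col2]
        keep = (a < 4) & (b < 4)
        a, b = a[keep], b[keep]
        ua, ub = np.unique(a), np.unique(b)
        if len(ua) != 2 or len(ub) != 2 or len(a) == 0:
            out.append(None)
            continue
        p = float(np.mean(a == ua[0]))
        q = float(np.mean(b == ub[0]))
        pab = float(np.mean((a == ua[0]) & (b == ub[0])))
        d = pab - p * q
        out.append(d * d / (p * (1 - p) * q * (1 - q)))
    return tuple(out)


def k2p_distance(seq1: np.ndarray, seq2: np.ndarray) -> float:
    """Kimura two-parameter distance with pairwise deletion of gap/N
    columns; NaN when the log arguments are non-positive (saturation)."""
    s1 = np.asarray(seq1)
    s2 = np.asarray(seq2)
    if s1.shape != s2.shape:
        raise ValueError("sequences must have equal length")
    keep = (s1 < 4) & (s2 < 4)
    s1, s2 = s1[keep], s2[keep]
    n = len(s1)
    if n == 0:
        return float("nan")
    diff = s1 != s2
    transitions = diff & ((s1 ^ s2) == 2)  # A^G == 2, C^T == 2
    p = float(np.count_nonzero(transitions)) / n
    q = float(np.count_nonzero(diff) - np.count_nonzero(transitions)) / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return float("nan")
    return -0.5 * np.log(arg1) - 0.25 * np.log(arg2)


def k2p_distance_matrix(geno: np.ndarray) -> np.ndarray:
    """Vectorized all-pairs K2P over a (n, L) base-code matrix."""
    n, L = geno.shape
    valid = geno < 4
    keep = valid[:, None, :] & valid[None, :, :]
    n_kept = keep.sum(axis=2)
    diff = (geno[:, None, :] != geno[None, :, :]) & keep
    xor = geno[:, None, :] ^ geno[None, :, :]
    ts = (diff & (xor == 2)).sum(axis=2)
    tv = diff.sum(axis=2) - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ts / n_kept
        q = tv / n_kept
        arg1 = 1.0 - 2.0 * p - q
        arg2 = 1.0 - 2.0 * q
        d = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
    d[(arg1 <= 0) | (arg2 <= 0) | (n_kept == 0)] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def p_distance_matrix(geno: np.ndarray) -> np.ndarray:
    valid = geno < 4
    keep = valid[:, None, :] & valid[None, :, :]
    n_kept = keep.sum(axis=2)
    diff = ((geno[:, None, :] != geno[None, :, :]) & keep).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / n_kept
    d[n_kept == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> TreeStructure:
    """Saitou–Nei neighbor joining with deterministic first-minimum
    tie-breaking in leaf-label (input) order."""
    n = dist.shape[0]
    if n < 4:
        raise ValueError("need at least 4 leaves")
    if np.any(np.isnan(dist)):
        raise ValueError("undefined distances")
    D = dist.astype(np.float64).copy()
    active = list(range(n))
    clusters: Dict[int, FrozenSet[int]] = {i: frozenset([i]) for i in range(n)}
    edges: List[Tuple[int, int, float]] = []
    parent_len: Dict[int, float] = {}
    next_node = n
    while len(active) > 2:
        r = len(active)
        sums = D.sum(axis=0)
        q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        li = max(li, 0.0)
        lj = max(dij - li, 0.0)
        u, v = active[i], active[j]
        edges.append((u, next_node, li))
        edges.append((v, next_node, lj))
        parent_len[u] = li
        parent_len[v] = lj
        clusters[next_node] = clusters[u] | clusters[v]
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        active[i] = next_node
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        del active[j]
        next_node += 1
    u, v = active
    final_len = max(D[0, 1], 0.0)
    edges.append((u, v, final_len))
    parent_len[u] = final_len
    parent_len[v] = final_len
    return TreeStructure(
        n_leaves=n, labels=list(labels), edges=edges,
        clusters={k: s for k, s in clusters.items() if k >= n},
        parent_len=parent_len,
    )


def classify_topology(
    tree: TreeStructure,
    species: Sequence[str],
    allele_partitions: Sequence[FrozenSet[int]],
) -> str:
    """Classify a window tree as species_tree / allelic_tree / unresolved.

    species_tree: some supported bipartition splits the samples exactly by
    species. allelic_tree: not species_tree, and some supported bipartition
    equals the allele partition of a qualifying shared SNP with both species
    present on both sides.
    """
    n = tree.n_leaves
    full = frozenset(range(n))
    species_a = frozenset(i for i in range(n) if species[i] == "A")
    norm = lambda s: s if 0 not in s else full - s
    bips = tree.bipartitions()
    if len(species_a) >= 2 and len(full - species_a) >= 2 and norm(species_a) in bips:
        return "species_tree"
    for part in allele_partitions:
        part = frozenset(part)
        other = full - part
        if not part or not other:
            continue
        both_sides = (
            any(species[i] == "A" for i in part)
            and any(species[i] == "C" for i in part)
            and any(species[i] == "A" for i in other)
            and any(species[i] == "C" for i in other)
        )
        if not both_sides:
            continue
        if len(part) < 2 or len(other) < 2:
            continue
        if norm(part) in bips:
            return "allelic_tree"
    return "unresolved"


@dataclass
class WindowClassification:
    start: int
    end: int
    valid: bool
    aligned_a: int
    aligned_c: int
    shared_columns: List[int]
    qualifying_columns: List[int]
    r2_pairs: Dict[Tuple[int, int], Tuple[float, float]]
    topology: str
    tree: Optional[TreeStructure] = None


@dataclass
class GeneScanReport:
    gene_id_a: str
    gene_id_c: str
    is_candidate: bool
    windows: List[WindowClassification]
    n_shared_snps: int

    @property
    def allelic_windows(self) -> List[WindowClassification]:
        return [w for w in self.windows if w.topology == "allelic_tree"]

    @property
    def supporting_span(self) -> Optional[Tuple[int, int]]:
        aw = self.allelic_windows
        if not aw:
            return None
        return min(w.start for w in aw), max(w.end for w in aw)


def _classify_window(
    aln: GenotypeAlignment,
    win: WindowCandidate,
    r2_min: float,
    max_missing_frac: float,
    keep_tree: bool,
) -> WindowClassification:
    # pairwise LD among shared SNPs in the window
    r2_pairs: Dict[Tuple[int, int], Tuple[float, float]] = {}
    qualifying: Set[int] = set()
    cols = win.shared_columns
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            ra, rc = ld_r2(aln, cols[a], cols[b])
            if ra is not None and rc is not None:
                r2_pairs[(cols[a], cols[b])] = (ra, rc)
                if ra > r2_min and rc > r2_min:
                    qualifying.update((cols[a], cols[b]))
    base = dict(
        start=win.start, end=win.end, valid=win.valid,
        aligned_a=win.aligned_a, aligned_c=win.aligned_c,
        shared_columns=cols, qualifying_columns=sorted(qualifying),
        r2_pairs=r2_pairs,
    )
    if not win.valid or len(qualifying) < 2:
        return WindowClassification(**base, topology="invalid" if not win.valid else "unresolved")

    sub = aln.geno[:, win.start: win.end]
    # drop samples with too much missing data inside the window
    missing = (sub >= 4).mean(axis=1)
    keep_rows = np.where(missing <= max_missing_frac)[0]
    sub = sub[keep_rows]
    species = [aln.samples[i][0] for i in keep_rows]
    labels = [f"{aln.samples[i][0]}|{aln.samples[i][1]}" for i in keep_rows]
    if len(keep_rows) < 4 or len(set(species)) < 2:
        return WindowClassification(**base, topology="unresolved")

    dist = k2p_distance_matrix(sub)
    if np.any(np.isnan(dist)):
        dist = p_distance_matrix(sub)  # saturation fallback
        if np.any(np.isnan(dist)):
            return WindowClassification(**base, topology="unresolved")
    tree = nj_tree(dist, labels)
    row_of = {int(r): i for i, r in enumerate(keep_rows)}
    partitions = []
    for col in sorted(qualifying):
        column = aln.geno[keep_rows, col]
        alleles = np.unique(column[column < 4])
        if len(alleles) != 2:
            continue
        partitions.append(
            frozenset(i for i in range(len(keep_rows)) if column[i] == alleles[0])
        )
    topo = classify_topology(tree, species, partitions)
    return WindowClassification(**base, topology=topo, tree=tree if keep_tree else None)


def scan_gene(
    aln: GenotypeAlignment,
    shared_snps: Optional[Sequence[SharedSNP]] = None,
    size: int = 100,
    step: int = 1,
    r2_min: float = 0.5,
    maf_min: float = 0.05,
    min_aligned: int = 95,
    max_missing_frac: float = 0.2,
    keep_trees: bool = False,
) -> GeneScanReport:
    """Scan one gene alignment; the gene is a trans-species-polymorphism
    candidate iff at least one valid window classifies as an allelic tree."""
    if shared_snps is None:
        shared_snps = find_shared_snps(aln, maf_min=maf_min).snps
    shared_cols = [s.column for s in shared_snps]
    windows: List[WindowClassification] = []
    for win in window_iter(aln, shared_cols, size=size, step=step, min_aligned=min_aligned):
        if len(win.shared_columns) < 2:
            continue  # a single shared SNP can never qualify
        windows.append(
            _classify_window(aln, win, r2_min, max_missing_frac, keep_trees)
        )
    is_candidate = any(w.topology == "allelic_tree" for w in windows)
    return GeneScanReport(
        gene_id_a=aln.gene_id_a,
        gene_id_c=aln.gene_id_c,
        is_candidate=is_candidate,
        windows=windows,
        n_shared_snps=len(shared_cols),
    )


def bootstrap_support(
    aln: GenotypeAlignment,
    window: WindowClassification,
    partition: FrozenSet[int],
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of column-bootstrap replicates whose NJ tree contains the
    given leaf bipartition (computed only for final candidates)."""
    rng = np.random.default_rng(seed)
    sub = aln.geno[:, window.start: window.end]
    labels = [f"{sp}|{sid}" for sp, sid in aln.samples]
    n = sub.shape[0]
    full = frozenset(range(n))
    norm = lambda s: s if 0 not in s else full - s
    target = norm(frozenset(partition))
    hits = 0
    for _ in range(n_reps):
        cols = rng.integers(0, sub.shape[1], size=sub.shape[1])
        boot = sub[:, cols]
        dist = k2p_distance_matrix(boot)
        if np.any(np.isnan(dist)):
            dist = p_distance_matrix(boot)
            if np.any(np.isnan(dist)):
                continue
        if target in nj_tree(dist, labels).bipartitions():
            hits += 1
    return hits / n_reps
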