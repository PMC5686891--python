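"""Reliable shared-SNP identification over orthologous alignments.

Implements the filter cascade used to go from raw variant calls to reliable
shared bi-allelic SNPs: annotation-threshold filters (MQ, QD, DP, FS,
ReadPosRankSum), a local SNP-density rule, a k-mer uniqueness (mappability)
mask, a copy-number flag from normalized read depth, codon-based site
annotation, and the shared-SNP / fourfold-degenerate-site extractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simdata import BASES, GenotypeAlignment

__all__ = [
    "VariantCallRecord",
    "FilterThresholds",
    "SharedSNP",
    "MappabilityMask",
    "apply_variant_filters",
    "mappability_mask",
    "mappability_mask_bruteforce",
    "find_shared_snps",
    "classify_site",
    "cnv_filter",
    "extract_fourfold_sites",
    "GeneModel",
]

_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class VariantCallRecord:
    """One called variant with the annotations the quality filters use.

    Missing annotations (None) fail the corresponding filter: only records
    positively passing every threshold are kept.
    """

    position: int
    ref: str
    alts: Tuple[str, ...]
    genotypes: Tuple[Optional[int], ...] = ()
    mq: Optional[float] = None
    qd: Optional[float] = None
    dp: Optional[float] = None  # site-level depth (mean across samples)
    fs: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None


@dataclass(frozen=True)
class FilterThresholds:
    """Hard thresholds of the variant quality cascade."""

    min_mq: float = 20.0
    min_qd: float = 2.0
    min_read_pos_rank_sum: float = -8.0
    min_dp: float = 3.0
    max_fs: float = 30.0
    density_max_snps: int = 3
    density_window: int = 10


def _passes(value: Optional[float], low: Optional[float], high: Optional[float]) -> bool:
    if value is None:
        return False
    if low is not None and value < low:
        return False
    if high is not None and value > high:
        return False
    return True


def apply_variant_filters(
    records: Sequence[VariantCallRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> Tuple[List[VariantCallRecord], Dict[str, int]]:
    """Apply annotation thresholds, then the SNP-density rule.

    The density rule removes *all* SNPs in any window of ``density_window``
    consecutive bp that contains more than ``density_max_snps`` surviving
    SNPs; it is applied to the post-threshold survivors. Returns the kept
    records and per-filter removal counts.
    """
    positions = [r.position for r in records]
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("records must be sorted by position")
    counts = {k: 0 for k in ("MQ", "QD", "ReadPosRankSum", "DP", "FS", "density")}
    survivors: List[VariantCallRecord] = []
    for rec in records:
        failed = False
        if not _passes(rec.mq, thresholds.min_mq, None):
            counts["MQ"] += 1
            failed = True
        if not _passes(rec.qd, thresholds.min_qd, None):
            counts["QD"] += 1
            failed = True
        if not _passes(rec.read_pos_rank_sum, thresholds.min_read_pos_rank_sum, None):
            counts["ReadPosRankSum"] += 1
            failed = True
        if not _passes(rec.dp, thresholds.min_dp, None):
            counts["DP"] += 1
            failed = True
        if not _passes(rec.fs, None, thresholds.max_fs):
            counts["FS"] += 1
            failed = True
        if not failed:
            survivors.append(rec)

    pos = np.array([r.position for r in survivors], dtype=np.int64)
    drop = np.zeros(len(survivors), dtype=bool)
    w = thresholds.density_window
    for i in range(len(survivors)):
        # window of w consecutive bp starting at pos[i]
        j = np.searchsorted(pos, pos[i] + w, side="left")
        if j - i > thresholds.density_max_snps:
            drop[i:j] = True
    counts["density"] = int(drop.sum())
    kept = [r for r, d in zip(survivors, drop) if not d]
    return kept, counts


# ---------------------------------------------------------------------------
# mappability


@dataclass
class MappabilityMask:
    """Per-position unique-mappability flags for a genome.

    A position is uniquely mappable iff every k-mer overlapping it occurs
    exactly once in the genome (both strands) at up to ``max_mismatch``
    mismatches.
    """

    mask: Dict[str, np.ndarray]
    k: int = 50
    max_mismatch: int = 2

    def is_mappable(self, contig: str, position: int) -> bool:
        """1-based position query."""
        return bool(self.mask[contig][position - 1])


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(s))


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 9, dtype=np.int8)  # 9 = degenerate, never matches
    for i, c in enumerate(seq.upper()):
        if c in "ACGT":
            out[i] = _CODE[c]
    return out


def _kmer_unique_flags(genome: Dict[str, str], k: int, max_mismatch: int) -> Dict[str, np.ndarray]:
    """For each k-mer start, is it unique at <= max_mismatch mismatches?

    Pigeonhole search: a k-mer matching another location with <= m mismatches
    shares at least one of m+1 exact seed segments with it, so exact seed
    hits enumerate all candidate locations.
    """
    # concatenate forward and reverse-complement strands
    entries = []  # (contig, strand, offset-in-cat)
    parts = []
    offset = 0
    catalog = []
    for contig, seq in genome.items():
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            parts.append(_encode(s))
            catalog.append((contig, strand, offset, len(s)))
            offset += len(s)
    cat = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)

    n_seeds = max_mismatch + 1
    bounds = [round(i * k / n_seeds) for i in range(n_seeds + 1)]
    # seed index: dict from seed bytes -> list of k-mer start positions in cat
    starts = []  # all valid k-mer start positions (within one strand segment)
    for contig, strand, off, ln in catalog:
        starts.extend(range(off, off + ln - k + 1))
    starts = np.array(starts, dtype=np.int64)

    seed_index: List[Dict[bytes, List[int]]] = []
    for si in range(n_seeds):
        lo, hi = bounds[si], bounds[si + 1]
        idx: Dict[bytes, List[int]] = {}
        for st in starts:
            key = cat[st + lo: st + hi].tobytes()
            idx.setdefault(key, []).append(int(st))
        seed_index.append(idx)

    def hamming_le(a: int, b: int, limit: int) -> bool:
        d = int(np.count_nonzero(cat[a: a + k] != cat[b: b + k]))
        # degenerate bases (code 9) never match anything, including themselves
        return d <= limit

    # map cat position back to (contig, strand, local pos)
    def locate(st: int):
        for contig, strand, off, ln in catalog:
            if off <= st < off + ln:
                local = st - off
                if strand == "-":
                    local = ln - k - local  # forward-strand start of the hit
                return contig, local
        raise AssertionError

    unique: Dict[str, np.ndarray] = {
        contig: np.zeros(max(len(seq) - k + 1, 0), dtype=bool)
        for contig, seq in genome.items()
    }
    for contig, seq in genome.items():
        ln = len(seq)
        enc_off = next(o for c, s, o, l in catalog if c == contig and s == "+")
        for local in range(ln - k + 1):
            st = enc_off + local
            if np.any(cat[st: st + k] == 9):
                continue  # degenerate bases: treated as never-matching
            hits = set()
            for si in range(n_seeds):
                lo, hi = bounds[si], bounds[si + 1]
                key = cat[st + lo: st + hi].tobytes()
                for cand in seed_index[si].get(key, ()):  # exact seed hits
                    if hamming_le(st, cand, max_mismatch):
                        hits.add(locate(cand))
            # the k-mer always hits itself on the forward strand
            unique[contig][local] = len(hits) <= 1
    return unique


def mappability_mask(genome: Dict[str, str], k: int = 50, max_mismatch: int = 2) -> MappabilityMask:
    """Build the per-position unique-mappability mask of a genome."""
    for contig, seq in genome.items():
        if len(seq) < k:
            raise ValueError(f"contig {contig} shorter than k={k}")
    kmer_ok = _kmer_unique_flags(genome, k, max_mismatch)
    mask = {}
    for contig, seq in genome.items():
        ln = len(seq)
        ok = kmer_ok[contig]
        pos_ok = np.zeros(ln, dtype=bool)
        # position p is mappable iff every k-mer overlapping p is unique
        csum = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        for p in range(ln):
            lo = max(0, p - k + 1)
            hi = min(p, ln - k)
            if hi < lo:
                pos_ok[p] = False
                continue
            n_window = hi - lo + 1
            pos_ok[p] = (csum[hi + 1] - csum[lo]) == n_window
        mask[contig] = pos_ok
    return MappabilityMask(mask=mask, k=k, max_mismatch=max_mismatch)


def mappability_mask_bruteforce(genome: Dict[str, str], k: int = 50, max_mismatch: int = 2) -> MappabilityMask:
    """Exhaustive-pairwise oracle for :func:`mappability_mask` (small genomes)."""
    entries = []
    for contig, seq in genome.items():
        enc_f = _encode(seq)
        enc_r = _encode(_revcomp(seq))
        for local in range(len(seq) - k + 1):
            entries.append((contig, "+", local, enc_f[local: local + k]))
            entries.append((contig, "-", local, enc_r[local: local + k]))
    kmer_ok: Dict[str, np.ndarray] = {
        c: np.zeros(max(len(s) - k + 1, 0), dtype=bool) for c, s in genome.items()
    }
    for contig, seq in genome.items():
        enc_f = _encode(seq)
        ln = len(seq)
        for local in range(ln - k + 1):
            mer = enc_f[local: local + k]
            if np.any(mer == 9):
                continue
            hits = set()
            for c2, strand, l2, mer2 in entries:
                if np.count_nonzero(mer != mer2) <= max_mismatch:
                    fwd = l2 if strand == "+" else len(genome[c2]) - k - l2
                    hits.add((c2, fwd))
            kmer_ok[contig][local] = len(hits) <= 1
    mask = {}
    for contig, seq in genome.items():
        ln = len(seq)
        ok = kmer_ok[contig]
        pos_ok = np.zeros(ln, dtype=bool)
        for p in range(ln):
            lo = max(0, p - k + 1)
            hi = min(p, ln - k)
            pos_ok[p] = hi >= lo and bool(np.all(ok[lo: hi + 1]))
        mask[contig] = pos_ok
    return MappabilityMask(mask=mask, k=k, max_mismatch=max_mismatch)


# ---------------------------------------------------------------------------
# shared SNPs


@dataclass
class SharedSNP:
    """An orthologous site bi-allelic in both species with the same allele pair."""

    gene_id_a: str
    gene_id_c: str
    column: int
    chrom_a: str
    pos_a: int
    chrom_c: str
    pos_c: int
    allele1: str
    allele2: str
    count_a: Tuple[int, int]  # (allele1, allele2) counts in species A
    count_c: Tuple[int, int]
    maf_a: float
    maf_c: float
    annotation: Optional[str] = None  # S / M / intron
    cpg: Optional[bool] = None

    def frequency_strings(self) -> Tuple[str, str]:
        """Allele-2 frequencies as printed "k/n" strings."""
        na = sum(self.count_a)
        nc = sum(self.count_c)
        return f"{self.count_a[1]}/{na}", f"{self.count_c[1]}/{nc}"


@dataclass
class SharedSNPScan:
    snps: List[SharedSNP]
    n_fixed_differences: int
    n_private_a: int
    n_private_c: int
    n_multiallelic_skipped: int


def find_shared_snps(
    aln: GenotypeAlignment, maf_min: float = 0.05
) -> SharedSNPScan:
    """Columns bi-allelic in both species with the identical allele pair and
    MAF > ``maf_min`` in each; also counts fixed differences and private
    polymorphisms. Columns with >2 alleles in a species are skipped."""
    geno = aln.geno
    n_a = aln.n_a
    snps: List[SharedSNP] = []
    fixed = private_a = private_c = multi = 0
    for col in range(aln.length):
        col_a = geno[:n_a, col]
        col_c = geno[n_a:, col]
        al_a = np.unique(col_a[col_a < 4])
        al_c = np.unique(col_c[col_c < 4])
        if len(al_a) == 0 or len(al_c) == 0:
            continue
        if len(al_a) > 2 or len(al_c) > 2:
            multi += 1
            continue
        if len(al_a) == 1 and len(al_c) == 1:
            if al_a[0] != al_c[0]:
                fixed += 1
            continue
        if len(al_a) == 2 and len(al_c) == 1:
            private_a += 1
            continue
        if len(al_a) == 1 and len(al_c) == 2:
            private_c += 1
            continue
        if not np.array_equal(al_a, al_c):
            continue  # polymorphic in both but different pairs
        a1, a2 = int(al_a[0]), int(al_a[1])
        ca = (int((col_a == a1).sum()), int((col_a == a2).sum()))
        cc = (int((col_c == a1).sum()), int((col_c == a2).sum()))
        maf_a = min(ca) / sum(ca)
        maf_c = min(cc) / sum(cc)
        if maf_a > maf_min and maf_c > maf_min:
            snps.append(
                SharedSNP(
                    gene_id_a=aln.gene_id_a,
                    gene_id_c=aln.gene_id_c,
                    column=col,
                    chrom_a=aln.chrom_a,
                    pos_a=int(aln.pos_a[col]),
                    chrom_c=aln.chrom_c,
                    pos_c=int(aln.pos_c[col]),
                    allele1=BASES[a1],
                    allele2=BASES[a2],
                    count_a=ca,
                    count_c=cc,
                    maf_a=maf_a,
                    maf_c=maf_c,
                )
            )
    return SharedSNPScan(snps, fixed, private_a, private_c, multi)


def shared_snps_table(scan_results: Iterable[SharedSNPScan]) -> pd.DataFrame:
    rows = []
    for res in scan_results:
        for s in res.snps:
            fa, fc = s.frequency_strings()
            rows.append(
                {
                    "gene_id_a": s.gene_id_a,
                    "gene_id_c": s.gene_id_c,
                    "column": s.column,
                    "pos_a": f"{s.chrom_a}:{s.pos_a}",
                    "pos_c": f"{s.chrom_c}:{s.pos_c}",
                    "A1": s.allele1,
                    "A2": s.allele2,
                    "A2_freq_A": fa,
                    "A2_freq_C": fc,
                    "MAF_A": round(s.maf_a, 3),
                    "MAF_C": round(s.maf_c, 3),
                    "annotation": s.annotation,
                    "CpG": s.cpg,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site annotation


_CODON_TABLE = {}


def _codon_table() -> Dict[str, str]:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        _CODON_TABLE = dict(fwd)
        for stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@dataclass
class GeneModel:
    """Minimal gene model: ordered CDS intervals (1-based inclusive, + strand
    in alignment coordinates); columns inside the gene span but outside CDS
    are intronic."""

    gene_id: str
    span: Tuple[int, int]
    cds: Tuple[Tuple[int, int], ...]

    def cds_positions(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(a, b + 1) for a, b in self.cds]
        ) if self.cds else np.empty(0, dtype=np.int64)


def classify_site(
    gene: GeneModel,
    position: int,
    ref_seq: str,
    allele1: str,
    allele2: str,
) -> Tuple[str, bool]:
    """Classify a substitution as S (synonymous), M (missense) or intron,
    plus the CpG flag from the trinucleotide centred on the site.

    ``ref_seq`` is the gene-span reference sequence (1-based coordinates
    align with the gene model's intervals).
    """
    lo, hi = gene.span
    if not (lo <= position <= hi):
        raise ValueError(f"position {position} outside gene span {gene.span}")
    focal = ref_seq[position - 1]
    nxt = ref_seq[position] if position < len(ref_seq) else ""
    prv = ref_seq[position - 2] if position >= 2 else ""
    cpg = (focal == "C" and nxt == "G") or (focal == "G" and prv == "C")
    cds_pos = gene.cds_positions()
    idx = np.searchsorted(cds_pos, position)
    if idx >= len(cds_pos) or cds_pos[idx] != position:
        return "intron", cpg
    frame = idx % 3
    codon_idx = idx - frame
    codon_pos = cds_pos[codon_idx: codon_idx + 3]
    if len(codon_pos) < 3:
        raise ValueError("truncated terminal codon")
    table = _codon_table()

    def codon_with(base: str) -> str:
        chars = [ref_seq[p - 1] for p in codon_pos]
        chars[frame] = base
        return "".join(chars)

    aa1 = table.get(codon_with(allele1))
    aa2 = table.get(codon_with(allele2))
    if aa1 is None or aa2 is None:
        raise ValueError("degenerate codon")
    return ("S" if aa1 == aa2 else "M"), cpg


# ---------------------------------------------------------------------------
# CNV filter


def cnv_filter(depth_table: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Flag genes whose normalized read depth indicates copy-number change
    (< 0.5: deletion, > 1.5: duplication, in either species).

    ``depth_table`` must have columns ``gene_id``, ``depth_a``, ``depth_c``.
    Genes missing from the table are flagged ``unknown`` (not passed)."""
    table = depth_table.set_index("gene_id")
    rows = []
    for gid in genes:
        if gid not in table.index:
            rows.append({"gene_id": gid, "flag": "unknown"})
            continue
        da = float(table.loc[gid, "depth_a"])
        dc = float(table.loc[gid, "depth_c"])
        if da < 0 or dc < 0:
            raise ValueError("depths must be non-negative")
        if da < 0.5 or dc < 0.5:
            flag = "deletion"
        elif da > 1.5 or dc > 1.5:
            flag = "duplication"
        else:
            flag = "pass"
        rows.append({"gene_id": gid, "flag": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fourfold degenerate sites

_FOURFOLD_PREFIXES = {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}


def extract_fourfold_sites(
    aln: GenotypeAlignment, cds_columns: Sequence[int]
) -> List[int]:
    """Third-codon-position columns fourfold degenerate in both species.

    ``cds_columns`` are the alignment columns of the coding sequence in
    reading-frame order; codons interrupted by gaps/missing data in any
    sample are skipped, and only fixed or bi-allelic columns are emitted.
    """
    cds = np.asarray(cds_columns, dtype=np.int64)
    if len(cds) % 3:
        cds = cds[: len(cds) - len(cds) % 3]
    geno = aln.geno
    n_a = aln.n_a
    out: List[int] = []
    for ci in range(0, len(cds), 3):
        cols = cds[ci: ci + 3]
        codon_block = geno[:, cols]
        if np.any(codon_block >= 4):
            continue  # gap or missing inside the codon
        third = cols[2]

        def prefix_set(rows):
            pre = {(int(r[0]), int(r[1])) for r in rows}
            return {BASES[a] + BASES[b] for a, b in pre}

        pre_a = prefix_set(codon_block[:n_a])
        pre_c = prefix_set(codon_block[n_a:])
        if not all(p in _FOURFOLD_PREFIXES for p in pre_a | pre_c):
            continue
        alleles = np.unique(geno[:, third])
        if len(alleles) > 2:
            continue
        out.append(int(third))
    return out
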