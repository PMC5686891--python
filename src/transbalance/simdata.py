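"""Synthetic two-species panels from a structured coalescent.

This module is the test substrate for the whole scan: it simulates haploid
sequence panels for the two selfing species under a piecewise-constant
divergence model (optionally with ancient gene flow), finite-sites CpG-aware
mutation, and — as a positive control — a mechanistic balanced locus whose
allelic classes persist through the species split and generate genuine
allele-clustered genealogies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import INF
from .models import BalancedLocus, DemographicModel, MutationModel

__all__ = [
    "GenotypeAlignment",
    "simulate_neutral_window",
    "simulate_balanced_window",
    "simulate_ortholog_set",
    "write_panel",
    "read_panel",
    "tmrca",
    "BASES",
]

BASES = "ACGT-N"
_CODE = {b: i for i, b in enumerate(BASES)}
GAP, MISSING = 4, 5


@dataclass
class GenotypeAlignment:
    """Per-gene aligned haploid panel for both species.

    ``geno`` is an (n_samples, n_columns) uint8 matrix over the alphabet
    ``ACGT-N``; ``samples`` holds ``(species, sample_id)`` pairs, species
    "A" rows first; the coordinate maps give, per alignment column, the
    1-based position in each species (−1 where the species has a gap).
    """

    gene_id_a: str
    gene_id_c: str
    geno: np.ndarray
    samples: List[Tuple[str, str]]
    chrom_a: str
    pos_a: np.ndarray
    chrom_c: str
    pos_c: np.ndarray

    def __post_init__(self) -> None:
        n, L = self.geno.shape
        if len(self.samples) != n:
            raise ValueError("sample list does not match genotype matrix")
        if len(self.pos_a) != L or len(self.pos_c) != L:
            raise ValueError("coordinate maps must cover every column")
        for pos in (self.pos_a, self.pos_c):
            real = pos[pos >= 0]
            if np.any(np.diff(real) <= 0):
                raise ValueError("coordinates must strictly increase over non-gap columns")
        species = [s for s, _ in self.samples]
        if sorted(set(species)) not in (["A"], ["C"], ["A", "C"]):
            raise ValueError("species labels must be 'A' or 'C'")

    @property
    def n_a(self) -> int:
        return sum(1 for s, _ in self.samples if s == "A")

    @property
    def n_c(self) -> int:
        return sum(1 for s, _ in self.samples if s == "C")

    @property
    def length(self) -> int:
        return self.geno.shape[1]

    def species_slice(self, species: str) -> slice:
        if species == "A":
            return slice(0, self.n_a)
        return slice(self.n_a, self.n_a + self.n_c)

    def sequences(self) -> Dict[str, str]:
        """Sample id -> sequence string, ids prefixed ``species|id``."""
        out = {}
        for row, (sp, sid) in enumerate(self.samples):
            out[f"{sp}|{sid}"] = "".join(BASES[b] for b in self.geno[row])
        return out


def _model_arrays(model: DemographicModel):
    mig = model.migration
    if mig is None:
        back_a, back_c, lo, hi = 0.0, 0.0, INF, INF
    else:
        # forward C->A flow means a lineage sampled in A traces back into C
        back_a = mig.rate_c_to_a
        back_c = mig.rate_a_to_c
        lo, hi = mig.window
    return (
        model.schedule_a.starts, model.schedule_a.sizes,
        model.schedule_c.starts, model.schedule_c.sizes,
        float(model.split_time), float(model.ancestral_size),
        back_a, back_c, lo, hi,
    )


def _default_samples(n_a: int, n_c: int) -> List[Tuple[str, str]]:
    return [("A", f"A{i:03d}") for i in range(n_a)] + [
        ("C", f"C{i:03d}") for i in range(n_c)
    ]


def _wrap_alignment(geno, n_a, n_c, gene_idx=0, gene_id_a=None, gene_id_c=None):
    L = geno.shape[1]
    offset = gene_idx * 100_000
    return GenotypeAlignment(
        gene_id_a=gene_id_a or f"SIMA{gene_idx:05d}",
        gene_id_c=gene_id_c or f"SIMC{gene_idx:05d}",
        geno=geno,
        samples=_default_samples(n_a, n_c),
        chrom_a="simA_1",
        pos_a=np.arange(offset + 1, offset + L + 1, dtype=np.int64),
        chrom_c="simC_1",
        pos_c=np.arange(offset + 1, offset + L + 1, dtype=np.int64),
    )


def simulate_neutral_window(
    model: DemographicModel,
    mut: MutationModel,
    n_a: int,
    n_c: int,
    length: int,
    seed: int,
    return_genealogy: bool = False,
):
    """Simulate one neutral window of ``length`` bp for ``n_a + n_c`` haploid
    samples under the two-population coalescent. Identical seeds give
    identical output."""
    if n_a < 2 or n_c < 2:
        raise ValueError("need at least two samples per species")
    if length < 1:
        raise ValueError("length must be >= 1")
    tip_class = np.zeros(n_a + n_c, dtype=np.int8)
    base_cum = np.cumsum(np.asarray(mut.base_freqs, dtype=np.float64))
    geno, anc, parent, node_time = _kernels.simulate_window_geno(
        np.uint32(seed), n_a, n_c, length, *_model_arrays(model),
        tip_class, 1.0, 0.0, INF,
        mut.mu_base, mut.cpg_multiplier, base_cum,
    )
    aln = _wrap_alignment(geno, n_a, n_c)
    if return_genealogy:
        return aln, (parent, node_time)
    return aln


def simulate_balanced_window(
    model: DemographicModel,
    mut: MutationModel,
    locus: BalancedLocus,
    n_a: int,
    n_c: int,
    length: int,
    seed: int,
    return_genealogy: bool = False,
):
    """Simulate one window containing a balanced polymorphism.

    Each sampled lineage draws an allelic class (Bernoulli with the locus
    class frequency); coalescence is restricted to within (species, class)
    until classes merge at the locus origin. The balanced site itself is
    emitted as a fixed two-allele column matching the class labels.
    """
    if locus.origin_time <= model.split_time:
        raise ValueError("balanced locus must pre-date the species split")
    if locus.position >= length:
        raise ValueError("balanced position outside window")
    rng = np.random.default_rng(seed)
    tip_class = (rng.random(n_a + n_c) >= locus.class_frequency).astype(np.int8)
    base_cum = np.cumsum(np.asarray(mut.base_freqs, dtype=np.float64))
    geno, anc, parent, node_time = _kernels.simulate_window_geno(
        np.uint32(rng.integers(0, 2**31)), n_a, n_c, length,
        *_model_arrays(model),
        tip_class, locus.class_frequency, locus.exchange_rate,
        float(locus.origin_time),
        mut.mu_base, mut.cpg_multiplier, base_cum,
    )
    # emit the balanced column: class 0 keeps the ancestral base, class 1
    # carries a transversion partner
    b0 = int(anc[locus.position])
    b1 = (b0 + 2) % 4
    geno[:, locus.position] = np.where(tip_class == 0, b0, b1).astype(np.uint8)
    aln = _wrap_alignment(geno, n_a, n_c)
    if return_genealogy:
        return aln, (parent, node_time, tip_class)
    return aln, tip_class


def simulate_ortholog_set(
    model: DemographicModel,
    mut: MutationModel,
    n_genes: int,
    gene_length: int = 500,
    tsp_fraction: float = 0.0,
    n_a: int = 81,
    n_c: int = 23,
    seed: int = 0,
    locus_template: Optional[BalancedLocus] = None,
    window: int = 100,
) -> Tuple[List[GenotypeAlignment], pd.DataFrame]:
    """Simulate a reduced orthologue panel with a known truth table.

    Genes are concatenations of independent ``window``-bp coalescent tiles
    (free recombination between tiles, none within). ``round(n_genes *
    tsp_fraction)`` genes embed a balanced locus in one tile; the truth
    table records which genes and columns carry true trans-species
    polymorphisms.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= tsp_fraction <= 1):
        raise ValueError("tsp_fraction must lie in [0, 1]")
    if locus_template is None:
        locus_template = BalancedLocus(
            position=window // 2,
            class_frequency=0.5,
            origin_time=10.0 * model.split_time,
            exchange_rate=0.0,
        )
    rng = np.random.default_rng(seed)
    n_tsp = int(round(n_genes * tsp_fraction))
    tsp_genes = set(rng.choice(n_genes, size=n_tsp, replace=False).tolist())
    n_tiles = max(1, int(np.ceil(gene_length / window)))
    genes: List[GenotypeAlignment] = []
    truth_rows = []
    for g in range(n_genes):
        tiles = []
        bal_tile = int(rng.integers(n_tiles)) if g in tsp_genes else -1
        bal_col = -1
        for tile in range(n_tiles):
            tile_len = min(window, gene_length - tile * window)
            sub_seed = int(rng.integers(0, 2**31))
            if tile == bal_tile:
                locus = BalancedLocus(
                    position=min(locus_template.position, tile_len - 1),
                    class_frequency=locus_template.class_frequency,
                    origin_time=locus_template.origin_time,
                    exchange_rate=locus_template.exchange_rate,
                )
                aln, _classes = simulate_balanced_window(
                    model, mut, locus, n_a, n_c, tile_len, sub_seed
                )
                bal_col = tile * window + locus.position
            else:
                aln = simulate_neutral_window(model, mut, n_a, n_c, tile_len, sub_seed)
            tiles.append(aln.geno)
        geno = np.concatenate(tiles, axis=1)
        gid_a, gid_c = f"SIMA{g:05d}", f"SIMC{g:05d}"
        genes.append(_wrap_alignment(geno, n_a, n_c, gene_idx=g,
                                     gene_id_a=gid_a, gene_id_c=gid_c))
        if g in tsp_genes:
            truth_rows.append({"gene_id_a": gid_a, "gene_id_c": gid_c,
                               "tsp_column": bal_col})
    truth = pd.DataFrame(truth_rows, columns=["gene_id_a", "gene_id_c", "tsp_column"])
    return genes, truth


def tmrca(parent: np.ndarray, node_time: np.ndarray, i: int, j: int) -> float:
    """Time to most recent common ancestor of tips ``i`` and ``j``."""
    anc_i = set()
    k = i
    while k != -1:
        anc_i.add(k)
        k = parent[k]
    k = j
    while k != -1:
        if k in anc_i:
            return float(node_time[k])
        k = parent[k]
    raise ValueError("disconnected genealogy")


# ---------------------------------------------------------------------------
# panel I/O


def _check_unique_samples(alignments: Sequence[GenotypeAlignment]) -> None:
    for aln in alignments:
        labels = [f"{sp}|{sid}" for sp, sid in aln.samples]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate sample ids in gene {aln.gene_id_a}")


def write_panel(alignments: Sequence[GenotypeAlignment], fmt: str, outdir) -> List[Path]:
    """Write a gene set as FASTA, VCF, or a TSV genotype matrix.

    Every format round-trips through :func:`read_panel` reproducing the
    genotype states and coordinates exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_unique_samples(alignments)
    fmt = fmt.lower()
    if fmt not in {"fasta", "vcf", "tsv"}:
        raise ValueError(f"unsupported format: {fmt}")
    written = []
    manifest = []
    for aln in alignments:
        stem = outdir / f"{aln.gene_id_a}_{aln.gene_id_c}"
        manifest.append(
            {
                "gene_id_a": aln.gene_id_a,
                "gene_id_c": aln.gene_id_c,
                "chrom_a": aln.chrom_a,
                "chrom_c": aln.chrom_c,
                "file": stem.name + {"fasta": ".fasta", "vcf": ".vcf", "tsv": ".tsv"}[fmt],
            }
        )
        if fmt == "fasta":
            written.append(_write_fasta(aln, stem))
        elif fmt == "vcf":
            written.append(_write_vcf(aln, stem))
        else:
            written.append(_write_tsv(aln, stem))
        written.append(_write_coords(aln, stem))
    (outdir / "panel.json").write_text(json.dumps({"format": fmt, "genes": manifest}, indent=1))
    return written


def _write_coords(aln: GenotypeAlignment, stem: Path) -> Path:
    path = stem.with_suffix(".coords.tsv")
    df = pd.DataFrame(
        {
            "column": np.arange(aln.length),
            "chrom_a": aln.chrom_a,
            "pos_a": aln.pos_a,
            "chrom_c": aln.chrom_c,
            "pos_c": aln.pos_c,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def _write_fasta(aln: GenotypeAlignment, stem: Path) -> Path:
    path = stem.with_suffix(".fasta")
    with open(path, "w") as fh:
        for label, seq in aln.sequences().items():
            fh.write(f">{label}\n{seq}\n")
    return path


def _write_tsv(aln: GenotypeAlignment, stem: Path) -> Path:
    path = stem.with_suffix(".tsv")
    data = {"column": np.arange(aln.length)}
    for row, (sp, sid) in enumerate(aln.samples):
        data[f"{sp}|{sid}"] = [BASES[b] for b in aln.geno[row]]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    return path


def _write_vcf(aln: GenotypeAlignment, stem: Path) -> Path:
    """Haploid VCF: one record per variant column, plus a sidecar reference
    FASTA (first sample's sequence) so invariant columns round-trip."""
    path = stem.with_suffix(".vcf")
    ref_path = stem.with_suffix(".ref.fasta")
    ref = aln.geno[0]
    with open(ref_path, "w") as fh:
        fh.write(f">{aln.chrom_a}\n" + "".join(BASES[b] for b in ref) + "\n")
    # htslib forbids '|' in sample names; VCF uses a '__' separator instead
    labels = [f"{sp}__{sid}" for sp, sid in aln.samples]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={aln.chrom_a},length={int(aln.pos_a.max())}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(labels) + "\n")
        for col in range(aln.length):
            column = aln.geno[:, col]
            alleles = sorted(set(int(b) for b in column if b < 4))
            r = int(ref[col])
            alts = [a for a in alleles if a != r]
            if not alts:
                continue
            allele_order = [r] + alts
            idx = {a: i for i, a in enumerate(allele_order)}
            gts = ["." if b >= 4 else str(idx[int(b)]) for b in column]
            fh.write(
                f"{aln.chrom_a}\t{int(aln.pos_a[col])}\t.\t{BASES[r]}\t"
                + ",".join(BASES[a] for a in alts)
                + "\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"  # INFO='.'

            )
    return path


def read_panel(indir) -> List[GenotypeAlignment]:
    """Read back a panel directory written by :func:`write_panel`."""
    indir = Path(indir)
    meta = json.loads((indir / "panel.json").read_text())
    fmt = meta["format"]
    out = []
    for entry in meta["genes"]:
        stem = indir / f"{entry['gene_id_a']}_{entry['gene_id_c']}"
        coords = pd.read_csv(stem.with_suffix(".coords.tsv"), sep="\t")
        if fmt == "fasta":
            labels, rows = _read_fasta(stem.with_suffix(".fasta"))
        elif fmt == "tsv":
            labels, rows = _read_tsv(stem.with_suffix(".tsv"))
        else:
            labels, rows = _read_vcf(stem)
        sep = "__" if fmt == "vcf" else "|"
        samples = [tuple(lbl.split(sep, 1)) for lbl in labels]
        out.append(
            GenotypeAlignment(
                gene_id_a=entry["gene_id_a"],
                gene_id_c=entry["gene_id_c"],
                geno=rows,
                samples=samples,
                chrom_a=entry["chrom_a"],
                pos_a=coords["pos_a"].to_numpy(np.int64),
                chrom_c=entry["chrom_c"],
                pos_c=coords["pos_c"].to_numpy(np.int64),
            )
        )
    return out


def _read_fasta(path: Path):
    from Bio import SeqIO

    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append([_CODE[ch] for ch in str(rec.seq).upper()])
    return labels, np.array(rows, dtype=np.uint8)


def _read_tsv(path: Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    labels = [c for c in df.columns if c != "column"]
    rows = np.array([[_CODE[ch] for ch in df[lbl]] for lbl in labels], dtype=np.uint8)
    return labels, rows


def _read_vcf(stem: Path):
    import pysam

    from Bio import SeqIO

    ref_rec = next(SeqIO.parse(str(stem.with_suffix(".ref.fasta")), "fasta"))
    ref = np.array([_CODE[ch] for ch in str(ref_rec.seq).upper()], dtype=np.uint8)
    coords = pd.read_csv(stem.with_suffix(".coords.tsv"), sep="\t")
    pos_to_col = {int(p): i for i, p in enumerate(coords["pos_a"]) if p >= 0}
    vf = pysam.VariantFile(str(stem.with_suffix(".vcf")))
    labels = list(vf.header.samples)
    geno = np.tile(ref, (len(labels), 1))
    for rec in vf:
        col = pos_to_col[rec.pos]
        alleles = [rec.ref] + list(rec.alts or ())
        for i, lbl in enumerate(labels):
            gt = rec.samples[lbl]["GT"][0]
            geno[i, col] = MISSING if gt is None else _CODE[alleles[gt]]
    return labels, geno
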