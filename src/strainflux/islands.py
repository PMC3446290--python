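"""Compositional genomic-island detection.

A gene is flagged *foreign* when both of its compositional signatures
are aberrant relative to the genome: its G+C fraction deviates from the
all-gene mean by more than ``gc_sigma_threshold`` standard deviations
(two-sided; horizontally acquired DNA can be GC-richer or GC-poorer than
the host), and a chi-square goodness-of-fit of its sense-codon counts
against the genome-wide codon frequencies gives P below
``codon_p_threshold``.  A sliding window of ``window_genes`` genes (step
one gene) is then scanned; windows holding at least ``min_foreign``
flagged genes are island hits, and hits whose gene ranges overlap or
abut are merged into maximal islands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from strainflux.models import AnalysisConfig

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class IslandDataError(Exception):
    pass


@dataclass
class GeneComposition:
    """Per-gene compositional summary feeding the island scan.

    Coordinates are 1-based inclusive genomic positions; ``codon_counts``
    covers the coding strand.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    codon_counts: dict[str, int] = field(default_factory=dict)
    gc_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise IslandDataError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise IslandDataError(f"{self.gene_id}: strand must be + or -")
        if not 0 <= self.gc_fraction <= 1:
            raise IslandDataError(f"{self.gene_id}: gc_fraction outside [0, 1]")

    @property
    def n_codons(self) -> int:
        return sum(self.codon_counts.values())


@dataclass(frozen=True)
class IslandCall:
    """A merged run of qualifying windows.

    Gene indices are 0-based half-open; ``genomic_span`` is 1-based
    inclusive (first gene's start to last gene's end).
    """

    first_gene_index: int
    last_gene_index: int  # half-open
    genomic_span: tuple[int, int]
    n_foreign: int

    @property
    def n_genes(self) -> int:
        return self.last_gene_index - self.first_gene_index


# ---------------------------------------------------------------------------
# per-gene statistics
# ---------------------------------------------------------------------------

def gc_zscores(genes: list[GeneComposition]) -> dict[str, float]:
    """Z-score of each gene's G+C fraction against the all-gene mean and
    population standard deviation.  All zeros when σ = 0."""
    if len(genes) < 2:
        raise IslandDataError("need >= 2 genes to standardize G+C content")
    gc = np.array([g.gc_fraction for g in genes])
    sigma = float(gc.std())  # population σ
    if sigma == 0.0:
        return {g.gene_id: 0.0 for g in genes}
    mean = float(gc.mean())
    return {g.gene_id: (g.gc_fraction - mean) / sigma for g in genes}


def genome_codon_frequencies(genes: list[GeneComposition]) -> dict[str, float]:
    """Genome-wide sense-codon frequencies (stop codons excluded)."""
    totals = {c: 0 for c in SENSE_CODONS}
    for g in genes:
        for codon, n in g.codon_counts.items():
            if codon in totals:
                totals[codon] += n
    grand = sum(totals.values())
    if grand == 0:
        raise IslandDataError("no sense codons in gene set")
    return {c: n / grand for c, n in totals.items()}


def codon_usage_pvalue(
    gene: GeneComposition, genome_codon_freq: dict[str, float]
) -> float:
    """Chi-square goodness-of-fit P of the gene's sense-codon counts
    against the genome-wide frequencies.

    Expected counts are gene total x genome frequency; codons with zero
    expectation are excluded and the degrees of freedom are the number of
    remaining codons minus one.  Returns the upper-tail P in [0, 1].
    """
    observed, expected = [], []
    total = sum(
        n for c, n in gene.codon_counts.items() if c in genome_codon_freq
    )
    if total == 0:
        raise IslandDataError(f"{gene.gene_id}: no sense codons")
    for codon in SENSE_CODONS:
        freq = genome_codon_freq.get(codon, 0.0)
        if freq > 0:
            observed.append(gene.codon_counts.get(codon, 0))
            expected.append(total * freq)
    chi2 = float(np.sum((np.asarray(observed) - np.asarray(expected)) ** 2 / np.asarray(expected)))
    df = len(expected) - 1
    return float(stats.chi2.sf(chi2, df))


def foreign_flags(
    genes: list[GeneComposition],
    genome_codon_freq: dict[str, float] | None = None,
    config: AnalysisConfig | None = None,
) -> list[bool]:
    """Foreign iff |G+C z| > gc_sigma_threshold AND codon-usage
    P < codon_p_threshold (both signatures must be aberrant)."""
    config = config or AnalysisConfig()
    if genome_codon_freq is None:
        genome_codon_freq = genome_codon_frequencies(genes)
    z = gc_zscores(genes)
    flags = []
    for g in genes:
        aberrant_gc = abs(z[g.gene_id]) > config.gc_sigma_threshold
        if aberrant_gc:
            p = codon_usage_pvalue(g, genome_codon_freq)
            flags.append(p < config.codon_p_threshold)
        else:
            flags.append(False)
    return flags


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def scan_islands(
    flags: list[bool],
    genes: list[GeneComposition],
    config: AnalysisConfig | None = None,
) -> list[IslandCall]:
    """Sliding-window island scan with merging of neighboring hits.

    Windows of ``window_genes`` genes slide with step 1; a window with at
    least ``min_foreign`` flagged genes qualifies.  Qualifying windows
    whose gene ranges overlap or directly abut are merged; the island's
    genomic span runs from the first to the last gene of the merged
    range.
    """
    config = config or AnalysisConfig()
    w = config.window_genes
    if len(flags) != len(genes):
        raise IslandDataError("flags and genes length mismatch")
    if w > len(genes):
        raise IslandDataError(
            f"window_genes={w} exceeds the number of genes ({len(genes)})"
        )
    counts = np.convolve(np.asarray(flags, dtype=int), np.ones(w, dtype=int), "valid")
    hits = [(i, i + w) for i, n in enumerate(counts) if n >= config.min_foreign]
    merged: list[list[int]] = []
    for start, stop in hits:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    calls = []
    for start, stop in merged:
        calls.append(
            IslandCall(
                first_gene_index=start,
                last_gene_index=stop,
                genomic_span=(genes[start].start, genes[stop - 1].end),
                n_foreign=int(sum(flags[start:stop])),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# sequence -> composition
# ---------------------------------------------------------------------------

def gene_composition_from_sequence(
    gene_id: str, start: int, end: int, strand: str, genome: str
) -> GeneComposition:
    """Build a :class:`GeneComposition` from 1-based inclusive coordinates
    on a genome string; minus-strand genes are reverse-complemented."""
    seq = genome[start - 1 : end].upper()
    if strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if set(codon) <= set(BASES):
            counts[codon] = counts.get(codon, 0) + 1
    gc = (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
    return GeneComposition(
        gene_id=gene_id,
        start=start,
        end=end,
        strand=strand,
        codon_counts=counts,
        gc_fraction=gc,
    )


def load_genome_fasta(path: str | Path) -> str:
    """First record of a FASTA file as an uppercase string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def load_gene_table(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Gene coordinates from GFF3 or a 4-column TSV (id, start, end, strand)."""
    path = Path(path)
    rows: list[tuple[str, int, int, str]] = []
    text = path.read_text()
    is_gff = path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if is_gff:
            if len(cols) < 9:
                raise IslandDataError(f"{path}: malformed GFF3 line: {line[:60]}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("Name", f"{cols[0]}:{cols[3]}-{cols[4]}"))
            rows.append((gid, int(cols[3]), int(cols[4]), cols[6]))
        else:
            if cols[0] in ("id", "gene_id"):
                continue
            if len(cols) < 4:
                raise IslandDataError(f"{path}: expected 4 columns: {line[:60]}")
            rows.append((cols[0], int(cols[1]), int(cols[2]), cols[3]))
    rows.sort(key=lambda r: r[1])
    return rows


def compose_genes(
    genome: str, gene_table: list[tuple[str, int, int, str]]
) -> list[GeneComposition]:
    return [
        gene_composition_from_sequence(gid, start, end, strand, genome)
        for gid, start, end, strand in gene_table
    ]


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def per_gene_table(
    genes: list[GeneComposition],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene TSV content: id, gc, z, chi2 P, foreign flag."""
    config = config or AnalysisConfig()
    freq = genome_codon_frequencies(genes)
    z = gc_zscores(genes)
    rows = []
    for g in genes:
        p = codon_usage_pvalue(g, freq)
        rows.append(
            {
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "gc": g.gc_fraction,
                "gc_z": z[g.gene_id],
                "codon_p": p,
                "foreign": abs(z[g.gene_id]) > config.gc_sigma_threshold
                and p < config.codon_p_threshold,
            }
        )
    return pd.DataFrame(rows)


def write_islands_gff3(
    islands: list[IslandCall], path: str | Path, seqid: str = "genome"
) -> None:
    lines = ["##gff-version 3"]
    for i, isl in enumerate(islands, start=1):
        start, end = isl.genomic_span  # already 1-based inclusive
        lines.append(
            "\t".join(
                [
                    seqid,
                    "strainflux",
                    "genomic_island",
                    str(start),
                    str(end),
                    ".",
                    ".",
                    ".",
                    f"ID=island_{i};n_genes={isl.n_genes};n_foreign={isl.n_foreign}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_islands_bed(
    islands: list[IslandCall], path: str | Path, seqid: str = "genome"
) -> None:
    lines = []
    for i, isl in enumerate(islands, start=1):
        start, end = isl.genomic_span
        lines.append(f"{seqid}\t{start - 1}\t{end}\tisland_{i}")  # BED half-open
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
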