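"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); any
zero-based half-open output (e.g. breakpoint BED) says so in its header.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """Input file cannot be parsed."""


@dataclass
class GeneModel:
    """A located, stranded, exon-structured gene on a scaffold."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: Optional[str] = None
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"{self.gene_id}: exon {s}-{e} reversed")
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"{self.gene_id}: exon {s}-{e} outside gene span {self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if self.cds_seq is not None and len(self.cds_seq) % 3 != 0:
            raise ValidationError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def cds_length(self) -> Optional[int]:
        return None if self.cds_seq is None else len(self.cds_seq)

    def to_zero_based(self) -> tuple[int, int]:
        """(start, end) as a zero-based half-open interval."""
        return self.start - 1, self.end

    @staticmethod
    def from_zero_based(gene_id, scaffold_id, start0, end0, strand, **kw) -> "GeneModel":
        return GeneModel(gene_id, scaffold_id, start0 + 1, end0, strand, **kw)


TAXON_CLASSES = ("ingroup", "outgroup", "self", "unknown")


@dataclass
class HomologyHit:
    """One query-subject search result (outfmt-6 style row)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    taxon_class: str = "unknown"
    query_cov: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValidationError(f"{self.query_id}->{self.subject_id}: negative bitscore")
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}->{self.subject_id}: negative E-value")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(f"{self.query_id}->{self.subject_id}: identity out of range")
        if self.taxon_class not in TAXON_CLASSES:
            raise ValidationError(f"unknown taxon class {self.taxon_class!r}")
        if self.subject_id == self.query_id:
            self.taxon_class = "self"


@dataclass
class VariantRecord:
    """A biallelic SNP with per-allele read depths."""

    scaffold_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    mapq: float
    qual: float
    depth_ref: int
    depth_alt: int

    def __post_init__(self) -> None:
        if self.depth_ref + self.depth_alt < 1:
            raise ValidationError(f"{self.scaffold_id}:{self.pos}: zero total depth")

    @property
    def depth(self) -> int:
        return self.depth_ref + self.depth_alt

    @property
    def maf(self) -> float:
        # integer minimum first: exactly symmetric under ref/alt swap
        return min(self.depth_alt, self.depth_ref) / self.depth


@dataclass
class DepthProfile:
    """Histogram of read depth over sites (contiguous increasing bins)."""

    bin_edges: list[float]
    counts: list[int]

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("need len(bin_edges) == len(counts) + 1")
        if any(nxt <= prev for prev, nxt in zip(self.bin_edges, self.bin_edges[1:])):
            raise ValidationError("bin edges must increase")
        if any(c < 0 for c in self.counts):
            raise ValidationError("negative bin count")


@dataclass
class TreeEvidence:
    """Topological support for foreign origin from one gene tree."""

    n_taxa: int
    analysable: bool
    clan_nonmetazoan: bool = False
    monophyly_nonmetazoan: Optional[bool] = False  # None = not applicable


@dataclass
class HgtEvidence:
    """Per-gene tiered record of horizontal-transfer evidence."""

    gene_id: str
    B_IN: float = 0.0
    B_OUT: float = 0.0
    h_U: float = 0.0
    chs_class: str = "none"  # ingroup | outgroup | none
    CHS: float = 0.0
    is_candidate: bool = False
    on_hgt_heavy_scaffold: bool = False
    linked_to_metazoan: bool = False
    n_introns: int = 0
    tree: Optional[TreeEvidence] = None


@dataclass
class GenePair:
    """A homologous gene pair with rank coordinates along its scaffolds."""

    gene_a: str
    gene_b: str
    scaffold_a: str
    scaffold_b: str
    rank_a: int
    rank_b: int
    similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a}")


@dataclass
class CollinearBlock:
    """An ordered chain of homologous gene pairs between two scaffold regions."""

    block_id: int
    scaffold_a: str
    scaffold_b: str
    pairs: list[GenePair]
    orientation: str  # same | inverted
    n_span_genes: int = 0
    CI: float = 0.0
    mean_KS: Optional[float] = None
    mean_KA: Optional[float] = None
    category: str = "unassigned"  # homolog | ohnolog | unassigned

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_collinear_genes(self) -> int:
        return 2 * len(self.pairs)

    def span_a(self) -> tuple[int, int]:
        ranks = [p.rank_a for p in self.pairs]
        return min(ranks), max(ranks)

    def span_b(self) -> tuple[int, int]:
        ranks = [p.rank_b for p in self.pairs]
        return min(ranks), max(ranks)


@dataclass
class CodonAlignment:
    """A gap-aligned CDS pair; gaps occur in whole-codon units."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValidationError("aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValidationError("aligned length not divisible by 3")

    @property
    def codon_count(self) -> int:
        """Number of ungapped aligned codon columns."""
        n = 0
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i:i + 3], self.seq_b[i:i + 3]
            if "-" not in ca and "-" not in cb:
                n += 1
        return n


@dataclass
class PairDivergence:
    """Nei-Gojobori site/difference counts and corrected rates for one pair."""

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    KS: Optional[float]
    KA: Optional[float]


@dataclass
class MafSpectrum:
    """Folded minor-allele-frequency histogram over (0, 0.5]."""

    bin_edges: list[float]
    counts: list[int]
    mode_bin: tuple[float, float]


@dataclass
class AlignmentSummary:
    """A protein-vs-genome alignment row (TBLASTN style)."""

    query_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    pct_identity: float
    query_cov: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_cov <= 1.0:
            raise ValidationError("query_cov outside [0,1]")
        if self.evalue < 0:
            raise ValidationError("negative E-value")


@dataclass
class SpeciesSummary:
    """Headline per-species numbers emitted by the end-to-end pipeline."""

    species: str
    total_genes: int = 0
    hq_genes: int = 0
    n_hgt_candidates: int = 0
    frac_hgt_candidates: Optional[float] = None
    n_hgt_linked: int = 0
    n_hgt_clan: int = 0
    n_hgt_monophyly: int = 0
    n_homolog_blocks: int = 0
    n_ohnolog_blocks: int = 0
    frac_genes_homolog_blocks: Optional[float] = None
    frac_genes_ohnolog_blocks: Optional[float] = None
    n_breakpoints: Optional[int] = None
    frac_breakpoints: Optional[float] = None
    n_tandem: Optional[int] = None
    n_palindrome: Optional[int] = None
    median_tophit_divergence_pct: Optional[float] = None
    snp_divergence_pct: Optional[float] = None
    maf_mode: Optional[tuple[float, float]] = None
    mean_ks_homolog: Optional[float] = None
    mean_ks_ohnolog: Optional[float] = None
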