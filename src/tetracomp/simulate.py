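"""Seeded generator of synthetic tetraploid genomes and all pipeline inputs.

The generator emulates a degenerate tetraploid animal genome: each
ancestral scaffold is duplicated into two OHNOLOGOUS subgenomes (divergence
``d_ohn``, the ancient duplication) and each of those into two HOMOLOGOUS
copies (divergence ``d_hom``, the former alleles), giving scaffold quartets
A1/A2/B1/B2. A chosen fraction of ancestral genes is planted as foreign
(horizontally acquired before tetraploidisation, so foreign genes occur as
quartets); inversions are planted at scaffold ends to create collinearity
breakpoints; tandem and palindromic homologous arrangements are planted on
dedicated scaffolds; and read sampling over collapsed (2x depth, binomial
allele depths) or separated (1x) haplotypes yields VCF and depth inputs.

All randomness flows through one numpy Generator with a fixed draw order,
so every output byte is a function of the parameters (seed included).
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .io_formats import (
    write_depth_profile,
    write_fasta,
    write_gff3,
    write_hits_table,
    write_vcf,
)
from .models import (
    DepthProfile,
    GeneModel,
    HomologyHit,
    ValidationError,
    VariantRecord,
)

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                 if a + b + c not in _STOPS]
from .divergence import _CODON_TABLE as _CODE  # single source for the genetic code


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimParams:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    n_scaffold_quartets: int = 4
    genes_per_scaffold: int = 200
    d_hom: float = 0.001     # homologous (allelic) divergence, subs/site
    d_ohn: float = 0.25      # ohnologous divergence, subs/site
    syn_bias: float = 0.5    # fraction of substitutions forced synonymous
    hgt_frac: float = 0.10   # fraction of ancestral genes foreign
    n_breaks: int = 12       # planted end-of-scaffold inversions
    n_palindromes: int = 3
    n_tandems: int = 2
    gene_loss_frac: float = 0.0
    depth_mean: float = 100.0
    depth_error: float = 0.005
    collapse: bool = True
    min_codons: int = 80
    max_codons: int = 250
    arrangement_genes: int = 8

    def __post_init__(self) -> None:
        for name in ("d_hom", "d_ohn", "syn_bias", "hgt_frac", "gene_loss_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")
        if self.d_hom >= self.d_ohn:
            raise ValidationError("d_hom must be < d_ohn")
        if self.d_ohn > 0.75:
            raise ValidationError("d_ohn > 0.75 is saturated")
        if min(self.n_scaffold_quartets, self.genes_per_scaffold) < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_breaks > 4 * self.n_scaffold_quartets:
            raise ValidationError(
                "n_breaks exceeds available scaffold-end slots "
                f"(4 per quartet = {4 * self.n_scaffold_quartets})"
            )
        seg = max(6, self.genes_per_scaffold // 8)
        if self.n_breaks > 0 and self.genes_per_scaffold < 3 * seg:
            raise ValidationError("too few genes per scaffold to plant inversions")


@dataclass
class TruthTable:
    """Machine-readable ground truth for one synthetic genome."""

    origin: dict[str, str] = field(default_factory=dict)       # gene -> native|foreign
    subgenome: dict[str, str] = field(default_factory=dict)    # gene -> A1|A2|B1|B2
    copy_group: dict[str, str] = field(default_factory=dict)   # gene -> group id
    groups: dict[str, list[str]] = field(default_factory=dict)
    breaks: list[dict] = field(default_factory=list)
    arrangements: list[dict] = field(default_factory=list)
    d_hom: float = 0.0
    d_ohn: float = 0.0
    realised_d_hom: float = 0.0
    realised_d_ohn: float = 0.0
    n_foreign: int = 0
    n_genes: int = 0

    @property
    def foreign_genes(self) -> set[str]:
        return {g for g, o in self.origin.items() if o == "foreign"}

    @property
    def n_palindromes(self) -> int:
        return sum(1 for a in self.arrangements if a["kind"] == "palindrome")

    @property
    def n_tandems(self) -> int:
        return sum(1 for a in self.arrangements if a["kind"] == "tandem")


@dataclass
class GenomeBundle:
    params: SimParams
    scaffolds: dict[str, str]
    genes: list[GeneModel]
    truth: TruthTable

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.scaffolds.items()}

    def gene(self, gid: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gid)


# ---------------------------------------------------------------------------
# sequence-level helpers

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _syn_alternatives(codon: str) -> list[tuple[int, str]]:
    """(position, base) single-base changes keeping the amino acid (no stops)."""
    aa = _CODE[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _CODE[alt] == aa:
                out.append((pos, b))
    return out


def mutate_cds(cds: str, d_target: float, syn_bias: float,
               rng: np.random.Generator) -> tuple[str, float]:
    """Apply ~Binomial(L, d_target) substitution events to a CDS.

    Events land uniformly (multiple hits allowed, so ``d_target`` is
    substitutions per site and a Jukes-Cantor-corrected estimate is
    asymptotically unbiased for it); with probability ``syn_bias`` an event
    is forced synonymous. No stop codons are ever introduced. Returns the
    mutated CDS and the realised per-base (hamming) divergence.
    """
    if d_target > 0.75:
        raise ValidationError("d_target > 0.75 is saturated")
    L = len(cds)
    seq = list(cds)
    n_events = int(rng.binomial(L, d_target)) if d_target > 0 else 0
    for _ in range(n_events):
        if syn_bias > 0 and rng.random() < syn_bias:
            for _try in range(50):
                ci = int(rng.integers(0, L // 3))
                codon = "".join(seq[3 * ci:3 * ci + 3])
                alts = _syn_alternatives(codon)
                if alts:
                    pos, b = alts[int(rng.integers(0, len(alts)))]
                    seq[3 * ci + pos] = b
                    break
        else:
            for _try in range(50):
                p = int(rng.integers(0, L))
                old = seq[p]
                b = _BASES[int(rng.integers(0, 4))]
                if b == old:
                    continue
                ci = p // 3
                codon = seq[3 * ci:3 * ci + 3]
                codon[p % 3] = b
                if "".join(codon) in _STOPS:
                    continue
                seq[p] = b
                break
    mutated = "".join(seq)
    realised = sum(1 for a, b in zip(cds, mutated) if a != b) / L
    return mutated, realised


def translate(cds: str) -> str:
    return "".join(_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def _place_gene(gene_id: str, scaffold_id: str, cds: str, strand: str,
                cursor: int, rng: np.random.Generator) -> tuple[GeneModel, str]:
    """Build the genomic sequence of one gene (exons + introns) starting at
    1-based position cursor+1; returns the GeneModel and the gene's genomic
    sequence."""
    n_exons = int(rng.choice([1, 2, 3, 4, 5, 6],
                             p=[0.25, 0.20, 0.20, 0.15, 0.12, 0.08]))
    n_exons = min(n_exons, len(cds) - 1) if len(cds) > 1 else 1
    if n_exons > 1:
        cuts = sorted(int(c) for c in rng.choice(np.arange(1, len(cds)),
                                                 size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0] + cuts + [len(cds)]
    pieces = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    # introns from a two-class length mixture (short vs long)
    template = []
    t_exons = []
    off = 0
    for k, piece in enumerate(pieces):
        if k > 0:
            if rng.random() < 0.5:
                ilen = max(20, int(round(rng.normal(65.0, 8.0))))
            else:
                ilen = max(50, int(round(rng.normal(320.0, 40.0))))
            intron = "".join(_BASES[i] for i in rng.integers(0, 4, size=ilen))
            template.append(intron)
            off += ilen
        t_exons.append((off, off + len(piece) - 1))
        template.append(piece)
        off += len(piece)
    t_seq = "".join(template)
    T = len(t_seq)
    if strand == "-":
        t_seq = _revcomp(t_seq)
        t_exons = sorted((T - 1 - e, T - 1 - s) for s, e in t_exons)
    start = cursor + 1
    exons = [(start + s, start + e) for s, e in t_exons]
    gene = GeneModel(gene_id=gene_id, scaffold_id=scaffold_id, start=start,
                     end=start + T - 1, strand=strand, exons=exons,
                     cds_seq=cds, protein_seq=translate(cds))
    return gene, t_seq


def cds_to_genomic(gene: GeneModel, cds_index: int) -> int:
    """Genomic (1-based) position of CDS base ``cds_index`` (0-based)."""
    exons = gene.exons
    if gene.strand == "+":
        off = cds_index
        for s, e in exons:
            span = e - s + 1
            if off < span:
                return s + off
            off -= span
    else:
        off = cds_index
        for s, e in reversed(exons):
            span = e - s + 1
            if off < span:
                return e - off
            off -= span
    raise ValidationError(f"{gene.gene_id}: CDS index {cds_index} out of range")


# ---------------------------------------------------------------------------
# genome simulation

_SUBGENOMES = ("A1", "A2", "B1", "B2")


def simulate_tetraploid(params: SimParams) -> GenomeBundle:
    """Generate the genome: scaffold quartets, planted foreign genes,
    planted inversions and same-scaffold arrangements."""
    rng = np.random.default_rng(params.seed)
    truth = TruthTable(d_hom=params.d_hom, d_ohn=params.d_ohn)
    scaffolds: dict[str, str] = {}
    genes: list[GeneModel] = []
    hom_divs: list[float] = []
    ohn_divs: list[float] = []

    # inversion slots: tails first, then heads, interleaving quartets
    slots = []
    for end in ("tail", "head"):
        for q in range(params.n_scaffold_quartets):
            for sub in ("A2", "B2"):
                slots.append((q, sub, end))
    slots = slots[:params.n_breaks]
    seg = max(6, params.genes_per_scaffold // 8)

    n = params.genes_per_scaffold
    for q in range(params.n_scaffold_quartets):
        n_codons = rng.integers(params.min_codons, params.max_codons + 1, size=n)
        anc = [random_cds(int(c), rng) for c in n_codons]
        n_foreign = int(round(params.hgt_frac * n))
        foreign_idx = set(
            int(i) for i in rng.choice(n, size=n_foreign, replace=False)
        ) if n_foreign else set()

        copies: dict[str, list[str]] = {"A1": list(anc)}
        a2, b1, b2 = [], [], []
        for c in anc:
            m, d = mutate_cds(c, params.d_hom, params.syn_bias, rng)
            a2.append(m)
            hom_divs.append(d)
        for c in anc:
            m, d = mutate_cds(c, params.d_ohn, params.syn_bias, rng)
            b1.append(m)
            ohn_divs.append(d)
        for c in b1:
            m, d = mutate_cds(c, params.d_hom, params.syn_bias, rng)
            b2.append(m)
            hom_divs.append(d)
        copies.update({"A2": a2, "B1": b1, "B2": b2})

        lost: dict[str, set[int]] = {sub: set() for sub in _SUBGENOMES}
        if params.gene_loss_frac > 0:
            for sub in _SUBGENOMES:
                draws = rng.random(n)
                lost[sub] = {i for i in range(n) if draws[i] < params.gene_loss_frac}

        for sub in _SUBGENOMES:
            scaffold_id = f"scf_q{q:02d}_{sub}"
            order = list(range(n))
            flipped: set[int] = set()
            for (sq, ssub, end) in slots:
                if sq != q or ssub != sub:
                    continue
                if end == "tail":
                    segment = order[-seg:]
                    order = order[:-seg] + segment[::-1]
                    boundary = n - seg
                else:
                    segment = order[:seg]
                    order = segment[::-1] + order[seg:]
                    boundary = seg
                flipped.update(segment)
                truth.breaks.append(
                    {"scaffold": scaffold_id, "kind": "inversion",
                     "end": end, "boundary_rank": boundary, "segment_genes": seg}
                )
            parts = []
            cursor = 0
            for idx in order:
                if idx in lost[sub]:
                    continue
                spacer_len = int(rng.integers(150, 601))
                spacer = "".join(_BASES[i] for i in rng.integers(0, 4, size=spacer_len))
                parts.append(spacer)
                cursor += spacer_len
                gid = f"q{q:02d}g{idx:03d}{sub}"
                strand = "-" if idx in flipped else "+"
                gene, gseq = _place_gene(gid, scaffold_id, copies[sub][idx],
                                         strand, cursor, rng)
                parts.append(gseq)
                cursor += len(gseq)
                genes.append(gene)
                grp = f"q{q:02d}g{idx:03d}"
                truth.origin[gid] = "foreign" if idx in foreign_idx else "native"
                truth.subgenome[gid] = sub
                truth.copy_group[gid] = grp
                truth.groups.setdefault(grp, []).append(gid)
            scaffolds[scaffold_id] = "".join(parts)

    # same-scaffold arrangements on dedicated scaffolds (their homologous
    # partners are collapsed elsewhere, so they do not perturb breakpoints)
    kinds = ["palindrome"] * params.n_palindromes + ["tandem"] * params.n_tandems
    m = params.arrangement_genes
    for k, kind in enumerate(kinds):
        scaffold_id = f"scf_arr{k:02d}"
        n_codons = rng.integers(params.min_codons, params.max_codons + 1, size=m)
        a_copies = [random_cds(int(c), rng) for c in n_codons]
        b_copies = []
        for c in a_copies:
            mut, d = mutate_cds(c, params.d_hom, params.syn_bias, rng)
            b_copies.append(mut)
            hom_divs.append(d)
        parts = []
        cursor = 0

        def _emit(gid, cds, strand, cursor, parts):
            spacer_len = int(rng.integers(150, 601))
            spacer = "".join(_BASES[i] for i in rng.integers(0, 4, size=spacer_len))
            parts.append(spacer)
            cursor += spacer_len
            gene, gseq = _place_gene(gid, scaffold_id, cds, strand, cursor, rng)
            parts.append(gseq)
            genes.append(gene)
            return cursor + len(gseq)

        for i, cds in enumerate(a_copies):
            cursor = _emit(f"arr{k:02d}g{i}a", cds, "+", cursor, parts)
        if kind == "palindrome":
            b_order = list(range(m))[::-1]
            b_strand = "-"
        else:
            b_order = list(range(m))
            b_strand = "+"
        for i in b_order:
            cursor = _emit(f"arr{k:02d}g{i}b", b_copies[i], b_strand, cursor, parts)
        for i in range(m):
            grp = f"arr{k:02d}g{i}"
            for suffix in ("a", "b"):
                gid = grp + suffix
                truth.origin[gid] = "native"
                truth.subgenome[gid] = "A1" if suffix == "a" else "A2"
                truth.copy_group[gid] = grp
                truth.groups.setdefault(grp, []).append(gid)
        truth.arrangements.append({"scaffold": scaffold_id, "kind": kind, "n_genes": m})
        scaffolds[scaffold_id] = "".join(parts)

    truth.realised_d_hom = float(np.mean(hom_divs)) if hom_divs else 0.0
    truth.realised_d_ohn = float(np.mean(ohn_divs)) if ohn_divs else 0.0
    truth.n_foreign = sum(1 for o in truth.origin.values() if o == "foreign")
    truth.n_genes = len(genes)
    return GenomeBundle(params=params, scaffolds=scaffolds, genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# downstream inputs

def simulate_hit_table(bundle: GenomeBundle, margin: float = 50.0,
                       noise_sd: float = 5.0, n_hits: int = 10,
                       seed: Optional[int] = None) -> tuple[list[HomologyHit], dict[str, str]]:
    """Protein-database hit profiles: native genes best-hit metazoan by
    ``margin`` bitscore units, foreign genes the reverse, with ~90% of hits
    count-supporting the true class (CHS >= 0.9)."""
    if noise_sd > 0 and not margin > 3 * noise_sd and margin != 0:
        raise ValidationError("need margin > 3*noise_sd (or margin == 0) for unambiguous profiles")
    rng = np.random.default_rng(bundle.params.seed + 1 if seed is None else seed)
    base = 300.0
    hits: list[HomologyHit] = []
    class_map: dict[str, str] = {}

    def _clip(x: float) -> float:
        lim = 3 * noise_sd
        return float(np.clip(x, -lim, lim))

    for g in bundle.genes:
        gid = g.gene_id
        foreign = bundle.truth.origin[gid] == "foreign"
        true_cls = "outgroup" if foreign else "ingroup"
        other_cls = "ingroup" if foreign else "outgroup"
        hits.append(HomologyHit(gid, gid, 100.0, len(g.protein_seq or ""), 0.0, 999.0))
        subj = f"u_{true_cls[:3]}_{gid}_0"
        class_map[subj] = true_cls
        hits.append(HomologyHit(gid, subj, 62.0, 200, 1e-80, base + margin, taxon_class=true_cls))
        for j in range(1, n_hits - 1):
            subj = f"u_{true_cls[:3]}_{gid}_{j}"
            class_map[subj] = true_cls
            score = max(1.0, base + margin - 2.0 * j - abs(_clip(rng.normal(0, noise_sd))))
            hits.append(HomologyHit(gid, subj, 55.0, 200, 1e-60, score, taxon_class=true_cls))
        subj = f"u_{other_cls[:3]}_{gid}_x"
        class_map[subj] = other_cls
        score = max(0.0, base + _clip(rng.normal(0, noise_sd)))
        hits.append(HomologyHit(gid, subj, 45.0, 200, 1e-40, score, taxon_class=other_cls))
    return hits, class_map


def simulate_intragenomic_hits(bundle: GenomeBundle) -> list[HomologyHit]:
    """Within-genome protein-search results: one hit per ordered pair of
    copy-group members (identity from the realised nucleotide divergence)
    plus a perfect self-hit per gene."""
    seqs = {g.gene_id: g.cds_seq for g in bundle.genes}
    hits: list[HomologyHit] = []
    for g in bundle.genes:
        hits.append(HomologyHit(g.gene_id, g.gene_id, 100.0,
                                len(g.cds_seq or ""), 0.0, 2.0 * len(g.cds_seq or "")))
    for grp in bundle.truth.groups.values():
        for a in grp:
            for b in grp:
                if a == b:
                    continue
                sa, sb = seqs[a], seqs[b]
                L = min(len(sa), len(sb))
                ident = 100.0 * sum(1 for x, y in zip(sa, sb) if x == y) / L
                hits.append(HomologyHit(a, b, round(ident, 4), L, 1e-100,
                                        round(1.5 * L * ident / 100.0, 1)))
    return hits


def homolog_pairs_from_truth(bundle: GenomeBundle) -> list[tuple[str, str, float]]:
    """(gene_a, gene_b, similarity) for every unordered copy-group pair."""
    seqs = {g.gene_id: g.cds_seq for g in bundle.genes}
    out = []
    for grp in bundle.truth.groups.values():
        for i, a in enumerate(grp):
            for b in grp[i + 1:]:
                sa, sb = seqs[a], seqs[b]
                L = min(len(sa), len(sb))
                ident = 100.0 * sum(1 for x, y in zip(sa, sb) if x == y) / L
                out.append((a, b, round(ident, 4)))
    return out


def simulate_gene_trees(bundle: GenomeBundle, discordant_frac: float = 0.0,
                        n_each: int = 15,
                        seed: Optional[int] = None) -> dict[str, str]:
    """Newick strings (one per foreign gene): the query nests inside the
    nonmetazoan clade; a chosen fraction instead nests inside the metazoan
    clade (discordant controls)."""
    rng = np.random.default_rng(bundle.params.seed + 2 if seed is None else seed)
    foreign = sorted(bundle.truth.foreign_genes)
    n_disc = int(round(discordant_frac * len(foreign)))
    disc = set(foreign[i] for i in rng.choice(len(foreign), size=n_disc, replace=False)) \
        if n_disc else set()

    def caterpillar(labels: list[str]) -> str:
        s = labels[0]
        for l in labels[1:]:
            s = f"({s},{l})"
        return s

    trees: dict[str, str] = {}
    for gid in foreign:
        nonmet = [f"NONMET_{i}" for i in range(1, n_each + 1)]
        met = [f"MET_{i}" for i in range(1, n_each + 1)]
        if gid in disc:
            left = caterpillar([gid] + met)
            right = caterpillar(nonmet)
        else:
            left = caterpillar([gid] + nonmet)
            right = caterpillar(met)
        trees[gid] = f"({left},{right});"
    return trees


def reference_scaffolds(bundle: GenomeBundle) -> tuple[list[str], list[str]]:
    """(collapsed scaffolds, separated scaffolds) of the read-mapping
    reference. Collapsed mode: one scaffold per homolog pair (A1 stands for
    A1+A2, B1 for B1+B2) at doubled depth; arrangement scaffolds are always
    separately assembled. Separated mode: every scaffold at 1x."""
    arr = [s for s in bundle.scaffolds if s.startswith("scf_arr")]
    if bundle.params.collapse:
        collapsed = [s for s in bundle.scaffolds if s.endswith(("A1", "B1"))]
        return collapsed, arr
    return [], [s for s in bundle.scaffolds]


def simulate_reads_snps(bundle: GenomeBundle,
                        seed: Optional[int] = None) -> tuple[list[VariantRecord], DepthProfile, dict]:
    """VCF records and a depth histogram from read sampling.

    Collapsed mode: every site where the two homologous copies differ
    yields a SNP with total depth ~Poisson(2 x depth_mean) and allele
    depths ~Binomial(n, 1/2); base-error records are sprinkled at rate
    ``depth_error`` with site quality below the standard filter. Separated
    mode: no homologous SNPs, all sites at 1x.
    """
    params = bundle.params
    rng = np.random.default_rng(params.seed + 3 if seed is None else seed)
    collapsed, separated = reference_scaffolds(bundle)
    collapsed_set = set(collapsed)
    genes_by_id = {g.gene_id: g for g in bundle.genes}

    records: list[VariantRecord] = []
    n_true = 0
    cds_span = 0
    for g in bundle.genes:
        if g.scaffold_id not in collapsed_set:
            continue
        cds_span += len(g.cds_seq or "")
        sub = bundle.truth.subgenome[g.gene_id]
        partner_id = g.gene_id[:-2] + ("A2" if sub == "A1" else "B2")
        partner = genes_by_id.get(partner_id)
        if partner is None:  # partner lost: region not collapsed
            continue
        ca, cb = g.cds_seq, partner.cds_seq
        for i, (x, y) in enumerate(zip(ca, cb)):
            if x == y:
                continue
            n = int(rng.poisson(2.0 * params.depth_mean))
            alt = int(rng.binomial(n, 0.5)) if n else 0
            if alt == 0 or alt == n:
                continue
            records.append(VariantRecord(
                scaffold_id=g.scaffold_id, pos=cds_to_genomic(g, i),
                ref_allele=x, alt_allele=y, mapq=60.0, qual=50.0,
                depth_ref=n - alt, depth_alt=alt,
            ))
            n_true += 1
    # base-error records (low site quality; removed by the standard filter)
    err_span = cds_span if cds_span else sum(
        len(g.cds_seq or "") for g in bundle.genes if g.scaffold_id in set(separated))
    n_err = int(rng.binomial(err_span, params.depth_error)) if err_span else 0
    err_scaffolds = collapsed or separated
    depth_factor = 2.0 if bundle.params.collapse else 1.0
    err_genes = [g for g in bundle.genes if g.scaffold_id in set(err_scaffolds)]
    for _ in range(n_err):
        g = err_genes[int(rng.integers(0, len(err_genes)))]
        i = int(rng.integers(0, len(g.cds_seq or "x")))
        ref = (g.cds_seq or "A")[i]
        alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
        n = max(2, int(rng.poisson(depth_factor * params.depth_mean)))
        alt_d = max(1, int(rng.binomial(n, 0.02)))
        alt_d = min(alt_d, n - 1)
        records.append(VariantRecord(
            scaffold_id=g.scaffold_id, pos=cds_to_genomic(g, i),
            ref_allele=ref, alt_allele=alt, mapq=60.0, qual=10.0,
            depth_ref=n - alt_d, depth_alt=alt_d,
        ))
    records.sort(key=lambda r: (r.scaffold_id, r.pos))

    # depth histogram over all reference sites
    n2 = sum(len(bundle.scaffolds[s]) for s in collapsed)
    n1 = sum(len(bundle.scaffolds[s]) for s in separated)
    draws = []
    if n2:
        draws.append(rng.poisson(2.0 * params.depth_mean, size=n2))
    if n1:
        draws.append(rng.poisson(params.depth_mean, size=n1))
    depths = np.concatenate(draws) if draws else np.zeros(1, dtype=int)
    hi = int(depths.max()) + 2
    edges = np.arange(0, hi + 2, 2)
    counts, _ = np.histogram(depths, bins=edges)
    profile = DepthProfile(bin_edges=[float(e) for e in edges],
                           counts=[int(c) for c in counts])
    mean_cov = float(depths.mean())
    meta = {"cds_span": cds_span, "n_true_snps": n_true, "n_error_records": n_err,
            "mean_cov": mean_cov,
            "reference_scaffolds": sorted(collapsed) + sorted(separated)}
    return records, profile, meta


# ---------------------------------------------------------------------------
# bundle emission

def write_bundle(bundle: GenomeBundle, outdir: str,
                 discordant_frac: float = 0.0) -> dict[str, str]:
    """Emit every pipeline input for a simulated genome under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "genome": "genome.fasta", "gff": "genes.gff3", "cds": "cds.fasta",
        "proteins": "proteins.fasta", "hits": "hits_uniref.tsv",
        "classmap": "classmap.tsv", "self_hits": "hits_self.tsv",
        "pairs": "pairs.tsv", "vcf": "variants.vcf", "depth": "depth.tsv",
        "truth": "truth.json", "trees": "trees",
    }.items()}
    write_fasta(bundle.scaffolds, paths["genome"])
    write_gff3(bundle.genes, paths["gff"], scaffold_lengths=bundle.scaffold_lengths)
    write_fasta({g.gene_id: g.cds_seq for g in bundle.genes}, paths["cds"])
    write_fasta({g.gene_id: g.protein_seq for g in bundle.genes}, paths["proteins"])
    hits, class_map = simulate_hit_table(bundle)
    write_hits_table(hits, paths["hits"])
    with open(paths["classmap"], "w") as fh:
        for subj, cls in class_map.items():
            fh.write(f"{subj}\t{cls}\n")
    write_hits_table(simulate_intragenomic_hits(bundle), paths["self_hits"])
    with open(paths["pairs"], "w") as fh:
        for a, b, sim in homolog_pairs_from_truth(bundle):
            fh.write(f"{a}\t{b}\t{sim}\n")
    os.makedirs(paths["trees"], exist_ok=True)
    for gid, nwk in simulate_gene_trees(bundle, discordant_frac=discordant_frac).items():
        with open(os.path.join(paths["trees"], f"{gid}.nwk"), "w") as fh:
            fh.write(nwk + "\n")
    records, profile, meta = simulate_reads_snps(bundle)
    ref_lengths = {s: len(bundle.scaffolds[s]) for s in meta["reference_scaffolds"]}
    write_vcf(records, paths["vcf"], contigs=ref_lengths)
    write_depth_profile(profile, paths["depth"])
    truth_doc = asdict(bundle.truth)
    truth_doc["read_meta"] = meta
    truth_doc["params"] = asdict(bundle.params)
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    return paths
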