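"""Gene-set quality control and presence/absence screens.

High-quality gene filtering (TE matches and short spurious models),
detection of unannotated protein matches (pseudogene signal), the
sex/meiosis-gene presence rule, and gene-structure summary statistics.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .models import AlignmentSummary, GeneModel, ValidationError


def hq_gene_filter(genes: Sequence[GeneModel], uniref_hit_ids: set,
                   te_hits: dict[str, float], min_len: int = 30,
                   te_evalue: float = 1e-5) -> tuple[list[GeneModel], dict]:
    """Retain high-quality genes.

    Removes (1) genes with a transposable-element match at E <= te_evalue
    and (2) genes shorter than ``min_len`` bases of CDS that also lack any
    protein-database hit. The removal reasons partition the removed set
    (TE matches take precedence).
    """
    retained: list[GeneModel] = []
    removed_te: list[str] = []
    removed_short: list[str] = []
    for g in genes:
        ev = te_hits.get(g.gene_id)
        if ev is not None and ev <= te_evalue:
            removed_te.append(g.gene_id)
            continue
        length = g.cds_length if g.cds_length is not None else (g.end - g.start + 1)
        if length < min_len and g.gene_id not in uniref_hit_ids:
            removed_short.append(g.gene_id)
            continue
        retained.append(g)
    report = {
        "input": len(genes),
        "retained": len(retained),
        "removed_te": removed_te,
        "removed_short_no_hit": removed_short,
    }
    return retained, report


def unannotated_protein_hits(alignments: Sequence[AlignmentSummary],
                             genes: Sequence[GeneModel],
                             max_evalue: float = 1e-20,
                             min_qcov: float = 0.95) -> tuple[list[AlignmentSummary], Optional[float]]:
    """Protein-vs-genome matches outside every annotated gene.

    Keeps alignments with E <= max_evalue and query coverage >= min_qcov
    that share no base with any gene interval (either strand); returns the
    retained alignments and the median percent identity (a decayed-duplicate
    / pseudogene divergence signal).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        s0, e0 = g.to_zero_based()
        trees[g.scaffold_id].addi(s0, e0)
    kept: list[AlignmentSummary] = []
    for a in alignments:
        if a.evalue > max_evalue or a.query_cov < min_qcov:
            continue
        lo, hi = min(a.start, a.end), max(a.start, a.end)
        if trees[a.scaffold_id].overlap(lo - 1, hi):
            continue
        kept.append(a)
    median = float(np.median([a.pct_identity for a in kept])) if kept else None
    return kept, median


def sex_gene_presence(group_alignments: dict[str, Sequence[AlignmentSummary]],
                      hmm_flags: Optional[dict[str, bool]] = None,
                      min_identity: float = 50.0,
                      min_qcov: float = 0.5) -> dict[str, dict]:
    """Presence table for meiosis/sex-related orthologous groups.

    A group is present when any query alignment reaches >= 50% identity
    over >= 50% of the query length (inclusive bounds) OR the group's HMM
    search is significant. Overlapping top hits across queries are recorded
    as a multi-hit note.
    """
    hmm_flags = hmm_flags or {}
    table: dict[str, dict] = {}
    for group in sorted(set(group_alignments) | set(hmm_flags)):
        alns = list(group_alignments.get(group, []))
        passing = [a for a in alns
                   if a.pct_identity >= min_identity and a.query_cov >= min_qcov]
        hmm = bool(hmm_flags.get(group, False))
        tops: dict[str, tuple] = {}
        for a in passing:
            cur = tops.get(a.query_id)
            if cur is None or a.evalue < cur[0]:
                tops[a.query_id] = (a.evalue, a.scaffold_id, min(a.start, a.end), max(a.start, a.end))
        locs = [t[1:] for t in tops.values()]
        multi = any(
            l1[0] == l2[0] and l1[1] <= l2[2] and l2[1] <= l1[2]
            for i, l1 in enumerate(locs) for l2 in locs[i + 1:]
        )
        table[group] = {
            "present": bool(passing) or hmm,
            "alignment_support": bool(passing),
            "hmm_support": hmm,
            "multi_hit": multi,
        }
    return table


def gene_structure_stats(genes: Sequence[GeneModel],
                         scaffold_lengths: Optional[dict[str, int]] = None) -> dict:
    """Summary of gene architecture.

    Intron count mean, intron length mean/median (and the raw lengths, for
    class-mixture inspection), intergenic distance mean/median (gaps
    between consecutive genes on a scaffold; overlaps clipped to 0 and
    counted), single-exon gene count/fraction, and exon/intron spans with
    genome fractions when scaffold lengths are supplied.
    """
    if not genes:
        raise ValidationError("no genes")
    intron_lengths: list[int] = []
    exon_span = 0
    single_exon = 0
    for g in genes:
        exons = g.exons or [(g.start, g.end)]
        if len(exons) == 1:
            single_exon += 1
        exon_span += sum(e - s + 1 for s, e in exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            intron_lengths.append(s2 - e1 - 1)
    intron_span = sum(intron_lengths)

    by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold_id].append(g)
    intergenic: list[int] = []
    n_overlaps = 0
    for gs in by_scaffold.values():
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        for a, b in zip(gs, gs[1:]):
            d = b.start - a.end - 1
            if d < 0:
                n_overlaps += 1
                d = 0
            intergenic.append(d)

    stats = {
        "n_genes": len(genes),
        "intron_count_mean": float(np.mean([g.n_introns for g in genes])),
        "intron_length_mean": float(np.mean(intron_lengths)) if intron_lengths else None,
        "intron_length_median": float(np.median(intron_lengths)) if intron_lengths else None,
        "intron_lengths": intron_lengths,
        "intergenic_mean": float(np.mean(intergenic)) if intergenic else None,
        "intergenic_median": float(np.median(intergenic)) if intergenic else None,
        "n_overlapping_gene_pairs": n_overlaps,
        "single_exon_count": single_exon,
        "single_exon_fraction": single_exon / len(genes),
        "exon_span_bp": exon_span,
        "intron_span_bp": intron_span,
    }
    if scaffold_lengths:
        assembly = sum(scaffold_lengths.values())
        stats["assembly_span_bp"] = assembly
        stats["exon_genome_fraction"] = exon_span / assembly
        stats["intron_genome_fraction"] = intron_span / assembly
    return stats
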