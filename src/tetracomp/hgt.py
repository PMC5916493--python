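"""Tiered horizontal-gene-transfer assessment.

Every gene is scored with the HGT index h_U = B_OUT - B_IN (best outgroup
minus best ingroup bitscore; an absent category scores 0) and Consensus Hit
Support (CHS: the fraction of classified hits agreeing with the class
holding the larger bitscore sum). Candidates pass h_U >= 30 and outgroup
CHS >= 0.90; they are then vetted against contamination-like scaffolds
(>= 95% candidate genes), annotated with physical linkage to confidently
metazoan genes and intron counts, and finally checked against gene-tree
topology (clan / monophyly with nonmetazoan leaves).
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import dendropy

from .models import (
    GeneModel,
    HgtEvidence,
    HomologyHit,
    TreeEvidence,
    ValidationError,
)

log = logging.getLogger(__name__)

HU_MIN = 30.0
CHS_MIN = 0.90
HEAVY_FRAC = 0.95
LINK_CHS_MIN = 0.90
MAX_EVALUE = 1e-5


def prepare_hits(hits: Iterable[HomologyHit], max_evalue: float = MAX_EVALUE,
                 exclude_subjects: Optional[set] = None,
                 best_per_subject: bool = True) -> dict[str, list[HomologyHit]]:
    """Group hits per query, applying the admission rules used before scoring.

    Drops self-hits, unknown-class hits (counted in the log), hits above the
    E-value threshold and hits to excluded subjects (e.g. same-phylum
    database entries); keeps only the best-scoring hit per subject.
    """
    exclude_subjects = exclude_subjects or set()
    by_query: dict[str, dict[str, HomologyHit]] = defaultdict(dict)
    n_unknown = 0
    for h in hits:
        if h.taxon_class == "self":
            continue
        if h.taxon_class == "unknown":
            n_unknown += 1
            continue
        if h.evalue > max_evalue or h.subject_id in exclude_subjects:
            continue
        cur = by_query[h.query_id].get(h.subject_id)
        if cur is None or h.bitscore > cur.bitscore or not best_per_subject:
            by_query[h.query_id][h.subject_id] = h
    if n_unknown:
        log.info("prepare_hits: excluded %d unknown-class hits", n_unknown)
    return {q: list(d.values()) for q, d in by_query.items()}


def compute_hu(hits: Sequence[HomologyHit]) -> tuple[float, float, float]:
    """(B_IN, B_OUT, h_U) for one query's classified hits.

    An absent category contributes bitscore 0, so h_U is defined for every
    gene; an empty hit list gives (0, 0, 0).
    """
    b_in = max((h.bitscore for h in hits if h.taxon_class == "ingroup"), default=0.0)
    b_out = max((h.bitscore for h in hits if h.taxon_class == "outgroup"), default=0.0)
    return b_in, b_out, b_out - b_in


def compute_chs(hits: Sequence[HomologyHit], weighting: str = "count") -> tuple[str, float]:
    """(winning class, CHS) for one query's classified hits.

    The winning class holds the larger sum of bitscores (ties go to the
    ingroup, conservative against false HGT calls); CHS is the fraction of
    classified hits in that class (``weighting='bitscore'`` uses bitscore
    mass instead of counts).
    """
    classified = [h for h in hits if h.taxon_class in ("ingroup", "outgroup")]
    if not classified:
        return "none", 0.0
    sum_in = sum(h.bitscore for h in classified if h.taxon_class == "ingroup")
    sum_out = sum(h.bitscore for h in classified if h.taxon_class == "outgroup")
    win = "ingroup" if sum_in >= sum_out else "outgroup"
    n_win = sum(1 for h in classified if h.taxon_class == win)
    if n_win == 0:  # degenerate all-zero-bitscore tie
        win = "outgroup" if win == "ingroup" else "ingroup"
        n_win = len(classified)
    if weighting == "bitscore":
        tot = sum_in + sum_out
        chs = (sum_in if win == "ingroup" else sum_out) / tot if tot > 0 else 1.0
    else:
        chs = n_win / len(classified)
    return win, chs


def score_genes(hits_by_query: dict[str, list[HomologyHit]],
                gene_ids: Iterable[str], chs_weighting: str = "count") -> dict[str, HgtEvidence]:
    """Build one HgtEvidence per gene (genes without hits score all-zero)."""
    evidence: dict[str, HgtEvidence] = {}
    for gid in gene_ids:
        ev = HgtEvidence(gene_id=gid)
        hits = hits_by_query.get(gid, [])
        if hits:
            ev.B_IN, ev.B_OUT, ev.h_U = compute_hu(hits)
            ev.chs_class, ev.CHS = compute_chs(hits, weighting=chs_weighting)
        evidence[gid] = ev
    return evidence


def classify_candidates(evidence: dict[str, HgtEvidence], hu_min: float = HU_MIN,
                        chs_min: float = CHS_MIN) -> dict[str, HgtEvidence]:
    """Flag HGT candidates: h_U >= hu_min, outgroup class, CHS >= chs_min."""
    for ev in evidence.values():
        ev.is_candidate = (
            ev.h_U >= hu_min and ev.chs_class == "outgroup" and ev.CHS >= chs_min
        )
    return evidence


def drop_hgt_heavy_scaffolds(evidence: dict[str, HgtEvidence],
                             genes: Sequence[GeneModel], frac: float = HEAVY_FRAC,
                             min_scaffold_genes: int = 1) -> tuple[dict[str, HgtEvidence], list[str]]:
    """Demote candidates on contamination-like scaffolds.

    A scaffold whose candidate fraction is >= ``frac`` (inclusive, any gene
    count >= ``min_scaffold_genes``) has all its candidates demoted with
    ``on_hgt_heavy_scaffold`` set.
    """
    by_scaffold: dict[str, list[str]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold_id].append(g.gene_id)
    dropped: list[str] = []
    for scaffold, gids in by_scaffold.items():
        if len(gids) < min_scaffold_genes:
            continue
        cands = [gid for gid in gids if evidence.get(gid) and evidence[gid].is_candidate]
        if gids and len(cands) / len(gids) >= frac and cands:
            dropped.append(scaffold)
            for gid in cands:
                evidence[gid].is_candidate = False
                evidence[gid].on_hgt_heavy_scaffold = True
    return evidence, sorted(dropped)


def annotate_linkage(evidence: dict[str, HgtEvidence], genes: Sequence[GeneModel],
                     link_chs_min: float = LINK_CHS_MIN) -> dict[str, HgtEvidence]:
    """Mark candidates physically linked to a confidently metazoan gene
    (h_U <= 0, ingroup class, CHS >= 0.90 on the same scaffold)."""
    by_scaffold: dict[str, list[str]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold_id].append(g.gene_id)
    anchored = set()
    for scaffold, gids in by_scaffold.items():
        for gid in gids:
            ev = evidence.get(gid)
            if ev and ev.h_U <= 0 and ev.chs_class == "ingroup" and ev.CHS >= link_chs_min:
                anchored.add(scaffold)
                break
    for g in genes:
        ev = evidence.get(g.gene_id)
        if ev and ev.is_candidate:
            ev.linked_to_metazoan = g.scaffold_id in anchored
    return evidence


def count_introns(gene: GeneModel) -> int:
    return gene.n_introns


def assess_tree(tree: dendropy.Tree, leaf_classes: dict[str, str]) -> TreeEvidence:
    """Topological HGT support from one gene tree.

    ``leaf_classes`` maps each leaf label to query/metazoan/nonmetazoan.
    The tree is treated as unrooted; for each edge bipartition, the side
    containing the query is tested for clan membership (>= 1 nonmetazoan,
    zero metazoan leaves) and monophyly (all nonmetazoan leaves, zero
    metazoan). Monophyly is not applicable (None) when the tree has no
    metazoan leaves; trees with fewer than 4 taxa are not analysed.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    queries = [l for l in leaves if leaf_classes.get(l) == "query"]
    if len(queries) != 1:
        raise ValidationError(f"expected exactly 1 query leaf, found {len(queries)}")
    query = queries[0]
    mets = {l for l in leaves if leaf_classes.get(l) == "metazoan"}
    nonmets = {l for l in leaves if leaf_classes.get(l) == "nonmetazoan"}
    n_taxa = len(leaves)
    if n_taxa < 4:
        return TreeEvidence(n_taxa=n_taxa, analysable=False,
                            clan_nonmetazoan=False,
                            monophyly_nonmetazoan=None if not mets else False)
    all_leaves = set(leaves)
    clan = False
    mono = False
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter() if lf.taxon}
        grp = side if query in side else all_leaves - side
        if grp == all_leaves or len(grp) < 2:
            continue
        grp_nonmets = grp & nonmets
        if grp & mets or not grp_nonmets:
            continue
        clan = True
        if grp_nonmets == nonmets:
            mono = True
    if not mets:
        return TreeEvidence(n_taxa=n_taxa, analysable=True,
                            clan_nonmetazoan=clan, monophyly_nonmetazoan=None)
    return TreeEvidence(n_taxa=n_taxa, analysable=True,
                        clan_nonmetazoan=clan, monophyly_nonmetazoan=mono)


def hgt_summary(evidence: Iterable[HgtEvidence], total_genes: int) -> dict:
    """Tiered counts and percentages (of all genes) of HGT evidence."""
    if total_genes <= 0:
        raise ValidationError("total_genes must be positive")
    evs = list(evidence)
    cands = [e for e in evs if e.is_candidate]
    linked = [e for e in cands if e.linked_to_metazoan]
    clan = [e for e in cands if e.tree and e.tree.analysable and e.tree.clan_nonmetazoan]
    mono = [e for e in clan if e.tree.monophyly_nonmetazoan is True]

    def tier(rows):
        return {"count": len(rows), "pct": 100.0 * len(rows) / total_genes}

    return {
        "total_genes": total_genes,
        "hgt_candidates": tier(cands),
        "linked_to_metazoan": tier(linked),
        "clan_support": tier(clan),
        "monophyly_support": tier(mono),
    }


_COPY_CLASS = {1: "singleton", 2: "pair", 3: "triplet", 4: "quartet"}


def copy_class_counts(candidate_ids: Iterable[str],
                      copy_groups: Iterable[Iterable[str]]) -> dict[str, int]:
    """Histogram of within-genome copy-group sizes among HGT candidates."""
    size_of: dict[str, int] = {}
    for grp in copy_groups:
        members = list(grp)
        for gid in members:
            size_of[gid] = len(members)
    hist = {v: 0 for v in _COPY_CLASS.values()}
    for gid in candidate_ids:
        size = min(size_of.get(gid, 1), 4)
        hist[_COPY_CLASS[size]] += 1
    return hist


def run_hgt_pipeline(hits: Iterable[HomologyHit], genes: Sequence[GeneModel],
                     trees: Optional[dict[str, dendropy.Tree]] = None,
                     tree_leaf_classes: Optional[dict[str, dict[str, str]]] = None,
                     hu_min: float = HU_MIN, chs_min: float = CHS_MIN,
                     heavy_frac: float = HEAVY_FRAC,
                     max_evalue: float = MAX_EVALUE,
                     exclude_subjects: Optional[set] = None,
                     chs_weighting: str = "count") -> tuple[dict[str, HgtEvidence], dict, list[str]]:
    """Score -> threshold -> scaffold filter -> linkage -> trees -> summary."""
    by_query = prepare_hits(hits, max_evalue=max_evalue, exclude_subjects=exclude_subjects)
    evidence = score_genes(by_query, [g.gene_id for g in genes], chs_weighting=chs_weighting)
    classify_candidates(evidence, hu_min=hu_min, chs_min=chs_min)
    evidence, dropped = drop_hgt_heavy_scaffolds(evidence, genes, frac=heavy_frac)
    annotate_linkage(evidence, genes)
    for g in genes:
        if g.gene_id in evidence:
            evidence[g.gene_id].n_introns = count_introns(g)
    if trees:
        for gid, tree in trees.items():
            ev = evidence.get(gid)
            if ev is None or not ev.is_candidate:
                continue
            classes = (tree_leaf_classes or {}).get(gid) or _default_leaf_classes(tree, gid)
            ev.tree = assess_tree(tree, classes)
    summary = hgt_summary(evidence.values(), total_genes=len(genes))
    return evidence, summary, dropped


def _default_leaf_classes(tree: dendropy.Tree, query_id: str) -> dict[str, str]:
    """Infer leaf classes from labels: the query id itself, MET_*/NONMET_* prefixes."""
    classes = {}
    for lf in tree.leaf_node_iter():
        if not lf.taxon:
            continue
        label = lf.taxon.label
        if label == query_id or label == "QUERY":
            classes[label] = "query"
        elif label.startswith(("MET_", "M_")):
            classes[label] = "metazoan"
        else:
            classes[label] = "nonmetazoan"
    return classes
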