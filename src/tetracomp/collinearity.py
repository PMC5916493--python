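"""Within-genome collinear-block detection and block statistics.

An MCScanX-style chainer: anchors (homologous gene pairs with gene-order
ranks) are chained by dynamic programming into maximal runs monotone in
both rank coordinates, with each step allowed fewer than ``max_gaps``
intervening genes (the larger of the two scaffolds' gaps) and blocks
requiring at least ``min_genes`` anchor pairs. Blocks carry a collinearity
index CI = collinear genes / all genes spanned, are partitioned into
homolog/ohnolog categories by mean synonymous divergence, and feed
breakpoint counting and tandem/palindrome classification.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import CollinearBlock, GeneModel, GenePair, ValidationError

log = logging.getLogger(__name__)

MIN_GENES = 5
MAX_GAPS = 10
KS_THRESHOLD = 0.3


def gene_orders(genes: Sequence[GeneModel]) -> dict[str, list[str]]:
    """Gene ids per scaffold in positional order (by start, then end, id)."""
    by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_scaffold[g.scaffold_id].append(g)
    return {
        sc: [g.gene_id for g in sorted(gs, key=lambda g: (g.start, g.end, g.gene_id))]
        for sc, gs in by_scaffold.items()
    }


def ranks_from_orders(orders: dict[str, list[str]]) -> dict[str, tuple[str, int]]:
    """gene id -> (scaffold, 0-based rank)."""
    return {gid: (sc, i) for sc, gids in orders.items() for i, gid in enumerate(gids)}


def build_pairs(raw_pairs: Iterable[tuple], orders: dict[str, list[str]]) -> list[GenePair]:
    """Attach scaffold/rank coordinates to (gene_a, gene_b[, similarity]) tuples.

    Pairs whose genes are missing from the gene order are skipped with a log.
    """
    ranks = ranks_from_orders(orders)
    out: list[GenePair] = []
    skipped = 0
    for tup in raw_pairs:
        a, b = tup[0], tup[1]
        sim = float(tup[2]) if len(tup) > 2 and tup[2] is not None else None
        if a not in ranks or b not in ranks or a == b:
            skipped += 1
            continue
        sa, ra = ranks[a]
        sb, rb = ranks[b]
        out.append(GenePair(a, b, sa, sb, ra, rb, similarity=sim))
    if skipped:
        log.info("build_pairs: skipped %d pairs with unknown/self genes", skipped)
    return out


def _canonical(pair: GenePair) -> GenePair:
    """Orient each pair so scaffold_a <= scaffold_b (rank_a first on ties)."""
    if (pair.scaffold_b, pair.rank_b) < (pair.scaffold_a, pair.rank_a):
        return GenePair(pair.gene_b, pair.gene_a, pair.scaffold_b, pair.scaffold_a,
                        pair.rank_b, pair.rank_a, pair.similarity)
    return pair


def _chain_key(anchors: Sequence[GenePair], chain: Sequence[int]) -> tuple:
    return tuple((anchors[i].rank_a, anchors[i].rank_b) for i in chain)


def _better(anchors, c1: Optional[list[int]], c2: Optional[list[int]]) -> Optional[list[int]]:
    """Prefer longer chains; break ties by lexicographically smaller ranks."""
    if c1 is None:
        return c2
    if c2 is None:
        return c1
    if len(c1) != len(c2):
        return c1 if len(c1) > len(c2) else c2
    return c1 if _chain_key(anchors, c1) <= _chain_key(anchors, c2) else c2


def _step_ok(p: GenePair, q: GenePair, direction: int, max_gaps: int) -> bool:
    """Can a chain step from anchor p to anchor q (q after p on scaffold a)?"""
    if q.rank_a <= p.rank_a:
        return False
    if direction > 0 and q.rank_b <= p.rank_b:
        return False
    if direction < 0 and q.rank_b >= p.rank_b:
        return False
    gap = max(q.rank_a - p.rank_a - 1, abs(q.rank_b - p.rank_b) - 1)
    return gap < max_gaps


def _best_chain(anchors: list[GenePair], max_gaps: int) -> Optional[list[int]]:
    """Best monotone chain (indices into anchors) under the gap rule."""
    if not anchors:
        return None
    best: Optional[list[int]] = None
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    for direction in (1, -1):
        dp: dict[int, list[int]] = {}
        for i in order:
            cand = [i]
            for j in order:
                if j == i or j not in dp:
                    continue
                if _step_ok(anchors[j], anchors[i], direction, max_gaps):
                    cand = _better(anchors, cand, dp[j] + [i])
            dp[i] = cand
            best = _better(anchors, best, cand)
    return best


def chain_blocks(pairs: Sequence[GenePair], orders: dict[str, list[str]],
                 min_genes: int = MIN_GENES, max_gaps: int = MAX_GAPS) -> list[CollinearBlock]:
    """Chain anchor pairs into collinear blocks.

    Chains are peeled greedily (best first) per scaffold pair; each anchor
    belongs to at most one block, chains shorter than ``min_genes`` are
    discarded. Duplicate (gene_a, gene_b) anchors are deduplicated.
    """
    seen = set()
    groups: dict[tuple[str, str], list[GenePair]] = defaultdict(list)
    n_dup = 0
    for p in pairs:
        cp = _canonical(p)
        key = (cp.gene_a, cp.gene_b)
        if key in seen or (cp.gene_b, cp.gene_a) in seen:
            n_dup += 1
            continue
        seen.add(key)
        groups[(cp.scaffold_a, cp.scaffold_b)].append(cp)
    if n_dup:
        log.info("chain_blocks: deduplicated %d anchor pairs", n_dup)

    blocks: list[CollinearBlock] = []
    block_id = 0
    for (sa, sb) in sorted(groups):
        anchors = groups[(sa, sb)]
        while True:
            chain = _best_chain(anchors, max_gaps)
            if chain is None or len(chain) < min_genes:
                break
            chain_pairs = [anchors[i] for i in chain]
            rb = [p.rank_b for p in chain_pairs]
            orientation = "inverted" if all(y < x for x, y in zip(rb, rb[1:])) else "same"
            block = CollinearBlock(
                block_id=block_id, scaffold_a=sa, scaffold_b=sb,
                pairs=chain_pairs, orientation=orientation,
            )
            collinearity_index(block, orders)
            blocks.append(block)
            block_id += 1
            used = set(chain)
            anchors = [a for i, a in enumerate(anchors) if i not in used]
    return blocks


def collinearity_index(block: CollinearBlock, orders: dict[str, list[str]]) -> float:
    """CI = collinear genes / all annotated genes within the block's two
    boundary intervals (each anchor pair contributes two collinear genes)."""
    lo_a, hi_a = block.span_a()
    lo_b, hi_b = block.span_b()
    span = (hi_a - lo_a + 1) + (hi_b - lo_b + 1)
    if span <= 0:
        raise ValidationError("zero-span block")
    block.n_span_genes = span
    block.CI = block.n_collinear_genes / span
    return block.CI


def partition_blocks(blocks: Iterable[CollinearBlock],
                     ks_threshold: float = KS_THRESHOLD) -> list[CollinearBlock]:
    """Categorise blocks: homolog (mean_KS < threshold), ohnolog (>=),
    unassigned (mean_KS undefined)."""
    out = []
    for b in blocks:
        if b.mean_KS is None:
            b.category = "unassigned"
        elif b.mean_KS < ks_threshold:
            b.category = "homolog"
        else:
            b.category = "ohnolog"
        out.append(b)
    return out


def _block_view(b: CollinearBlock) -> tuple[tuple[str, str], tuple, tuple, str]:
    """(scaffold-pair key, focal span, partner span, orientation) with the
    lexicographically smaller scaffold as focal, so the count is invariant
    under relabelling scaffold_a/scaffold_b."""
    if b.scaffold_b < b.scaffold_a:
        return (b.scaffold_b, b.scaffold_a), b.span_b(), b.span_a(), b.orientation
    return (b.scaffold_a, b.scaffold_b), b.span_a(), b.span_b(), b.orientation


def _consistent(u, v) -> bool:
    """Can adjacent same-partner block views u, v (u first on the focal
    scaffold) be aligned without rearrangement?

    Requires equal orientations, with partner order matching focal order for
    same-orientation blocks and reversed for inverted blocks (a wholesale
    flip of one scaffold is not a rearrangement).
    """
    (_, _, u_partner, u_orient) = u
    (_, _, v_partner, v_orient) = v
    if u_orient != v_orient:
        return False
    u_mid = sum(u_partner) / 2.0
    v_mid = sum(v_partner) / 2.0
    if u_orient == "same":
        return u_mid <= v_mid
    return u_mid >= v_mid


def count_breakpoints(blocks: Sequence[CollinearBlock]) -> tuple[int, dict[str, int], float]:
    """Count collinearity breakpoints among the given (homolog) blocks.

    Blocks linking the same scaffold pair are taken in positional order
    along the focal (lexicographically smaller) scaffold; each adjacency
    that cannot be aligned without rearrangement contributes one
    breakpoint. Returns (total, per-focal-scaffold counts, total / number
    of blocks).
    """
    groups: dict[tuple[str, str], list] = defaultdict(list)
    for b in blocks:
        view = _block_view(b)
        groups[view[0]].append(view)
    total = 0
    per_scaffold: dict[str, int] = defaultdict(int)
    for (sa, _sb), grp in groups.items():
        grp = sorted(grp, key=lambda v: v[1])
        for u, v in zip(grp, grp[1:]):
            if not _consistent(u, v):
                total += 1
                per_scaffold[sa] += 1
    n_blocks = len(list(blocks))
    frac = total / n_blocks if n_blocks else 0.0
    return total, dict(per_scaffold), frac


def classify_same_scaffold_blocks(blocks: Iterable[CollinearBlock]) -> dict[int, str]:
    """Classify blocks whose two regions lie on one scaffold.

    Inverted orientation (head-to-head copies, g1 g2 g3 ... g3' g2' g1') is
    a palindrome; same orientation is a tandem array. Overlapping copy
    intervals are rejected as self-match artefacts.
    """
    out: dict[int, str] = {}
    for b in blocks:
        if b.scaffold_a != b.scaffold_b:
            continue
        lo_a, hi_a = b.span_a()
        lo_b, hi_b = b.span_b()
        if not (hi_a < lo_b or hi_b < lo_a):
            raise ValidationError(
                f"block {b.block_id}: overlapping same-scaffold intervals"
            )
        out[b.block_id] = "palindrome" if b.orientation == "inverted" else "tandem"
    return out


def genes_in_blocks(blocks: Iterable[CollinearBlock], total_genes: int) -> dict[str, dict]:
    """Distinct genes appearing in >= 1 block per category, and the fraction
    of all genes they represent."""
    if total_genes <= 0:
        raise ValidationError("total_genes must be positive")
    genes_by_cat: dict[str, set] = defaultdict(set)
    for b in blocks:
        for p in b.pairs:
            genes_by_cat[b.category].add(p.gene_a)
            genes_by_cat[b.category].add(p.gene_b)
    return {
        cat: {"count": len(gs), "pct": 100.0 * len(gs) / total_genes}
        for cat, gs in genes_by_cat.items()
    }


def block_size_summary(blocks: Iterable[CollinearBlock]) -> dict[str, dict]:
    """Per-category block count and median number of anchor pairs."""
    sizes: dict[str, list[int]] = defaultdict(list)
    for b in blocks:
        sizes[b.category].append(b.n_pairs)
    return {
        cat: {"count": len(v), "median_pairs": float(np.median(v)) if v else None}
        for cat, v in sizes.items()
    }
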