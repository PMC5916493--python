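"""Intragenomic divergence estimation.

Implements Nei-Gojobori (1986) pathway counting with Jukes-Cantor
correction for codon-level Ka/Ks, per-block divergence means, top-non-self
hit identity distributions, SNP-based collapsed-homolog divergence, folded
minor-allele-frequency spectra and read-coverage collapse diagnostics.
"""
from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax

from .models import (
    CodonAlignment,
    CollinearBlock,
    DepthProfile,
    HomologyHit,
    MafSpectrum,
    PairDivergence,
    ValidationError,
    VariantRecord,
)

_BASES = "ACGT"
_CODON_TABLE = {}
_STOPS = {"TAA", "TAG", "TGA"}
# standard genetic code
_AA_BY_BLOCK = [
    ("TTT", "F"), ("TTC", "F"), ("TTA", "L"), ("TTG", "L"),
    ("CTT", "L"), ("CTC", "L"), ("CTA", "L"), ("CTG", "L"),
    ("ATT", "I"), ("ATC", "I"), ("ATA", "I"), ("ATG", "M"),
    ("GTT", "V"), ("GTC", "V"), ("GTA", "V"), ("GTG", "V"),
    ("TCT", "S"), ("TCC", "S"), ("TCA", "S"), ("TCG", "S"),
    ("CCT", "P"), ("CCC", "P"), ("CCA", "P"), ("CCG", "P"),
    ("ACT", "T"), ("ACC", "T"), ("ACA", "T"), ("ACG", "T"),
    ("GCT", "A"), ("GCC", "A"), ("GCA", "A"), ("GCG", "A"),
    ("TAT", "Y"), ("TAC", "Y"), ("TAA", "*"), ("TAG", "*"),
    ("CAT", "H"), ("CAC", "H"), ("CAA", "Q"), ("CAG", "Q"),
    ("AAT", "N"), ("AAC", "N"), ("AAA", "K"), ("AAG", "K"),
    ("GAT", "D"), ("GAC", "D"), ("GAA", "E"), ("GAG", "E"),
    ("TGT", "C"), ("TGC", "C"), ("TGA", "*"), ("TGG", "W"),
    ("CGT", "R"), ("CGC", "R"), ("CGA", "R"), ("CGG", "R"),
    ("AGT", "S"), ("AGC", "S"), ("AGA", "R"), ("AGG", "R"),
    ("GGT", "G"), ("GGC", "G"), ("GGA", "G"), ("GGG", "G"),
]
_CODON_TABLE = dict(_AA_BY_BLOCK)


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Fraction-weighted count of synonymous sites in one sense codon.

    Each position contributes (number of synonymous single-base changes)/3;
    changes creating a stop codon count as nonsynonymous.
    """
    if codon in _STOPS:
        raise ValidationError(f"stop codon {codon} has no site counts")
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at k positions are averaged over all k! minimal
    substitution paths with equal weight; paths passing through a stop
    codon are excluded (if every path is blocked, all paths are used and
    steps to/from stops count as nonsynonymous).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                blocked = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((blocked, sd, nd))
    allowed = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not allowed:
        allowed = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in allowed) / len(allowed)
    nd = sum(p[1] for p in allowed) / len(allowed)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when p >= 3/4 (saturated)."""
    if math.isnan(p) or p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ka_ks(aln: CodonAlignment, gene_a: str = "a", gene_b: str = "b") -> PairDivergence:
    """Nei-Gojobori Ka/Ks for one codon alignment.

    Site counts are averaged over the two sequences; codon columns with a
    gap, an ambiguity character or a stop codon are skipped. pS/pN are
    Jukes-Cantor corrected; a saturated proportion (>= 3/4) leaves the rate
    undefined (None).
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(aln.seq_a), 3):
        ca = aln.seq_a[i:i + 3].upper()
        cb = aln.seq_b[i:i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if any(b not in _BASES for b in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        s = 0.5 * (synonymous_sites(ca) + synonymous_sites(cb))
        S += s
        N += 3.0 - s
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValidationError("no ungapped, unambiguous codon columns")
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    return PairDivergence(
        gene_a=gene_a, gene_b=gene_b, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, KS=jukes_cantor(pS), KA=jukes_cantor(pN),
    )


def block_mean_divergence(block: CollinearBlock,
                          pair_divergences: dict) -> tuple[Optional[float], Optional[float]]:
    """Arithmetic block means of KS/KA over pairs with defined rates.

    ``pair_divergences`` maps frozenset({gene_a, gene_b}) -> PairDivergence.
    Sets mean_KS/mean_KA on the block and returns them (None when every
    pair is undefined).
    """
    ks_vals, ka_vals = [], []
    for p in block.pairs:
        d = pair_divergences.get(frozenset((p.gene_a, p.gene_b)))
        if d is None:
            continue
        if d.KS is not None:
            ks_vals.append(d.KS)
        if d.KA is not None:
            ka_vals.append(d.KA)
    block.mean_KS = float(np.mean(ks_vals)) if ks_vals else None
    block.mean_KA = float(np.mean(ka_vals)) if ka_vals else None
    return block.mean_KS, block.mean_KA


def top_nonself_identity(hits: Iterable[HomologyHit], bin_width: float = 0.25):
    """Per-gene divergence of the top non-self intragenomic hit.

    Returns (divergences: dict gene -> percent divergence, median, mode bin
    midpoint, n_omitted). Divergence = 100 - pct_identity of the
    highest-bitscore non-self hit; the mode is taken on ``bin_width``-wide
    percent bins (0.25 by default).
    """
    best: dict[str, HomologyHit] = {}
    queries = set()
    for h in hits:
        queries.add(h.query_id)
        if h.subject_id == h.query_id or h.taxon_class == "self":
            continue
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.query_id] = h
    n_omitted = len(queries - set(best))
    divs = {q: 100.0 - h.pct_identity for q, h in best.items()}
    if not divs:
        return divs, None, None, n_omitted
    vals = np.array(list(divs.values()))
    median = float(np.median(vals))
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts))
    mode = float(edges[k] + bin_width / 2.0)
    return divs, median, mode, n_omitted


def snp_divergence(n_snps: int, cds_span: float) -> float:
    """Upper-limit percent divergence between collapsed homologs."""
    if cds_span <= 0:
        raise ValidationError("cds_span must be positive")
    return 100.0 * n_snps / cds_span


def filter_snps(records: Sequence[VariantRecord], min_mq: float = 30.0,
                min_qual: float = 20.0, mean_cov: float = None,
                depth_frac: float = 0.25) -> list[VariantRecord]:
    """Quality filter for SNP calls: mapq, site quality and minimum depth
    relative to the library's mean coverage."""
    if mean_cov is None or mean_cov <= 0:
        raise ValidationError("mean_cov must be positive")
    min_depth = depth_frac * mean_cov
    return [
        r for r in records
        if r.mapq >= min_mq and r.qual >= min_qual and r.depth >= min_depth
    ]


def fold_maf(records: Sequence[VariantRecord], bin_width: float = 0.02) -> MafSpectrum:
    """Folded minor-allele-frequency spectrum on (0, 0.5]."""
    edges = np.round(np.arange(0.0, 0.5 + bin_width / 2, bin_width), 10)
    if edges[-1] < 0.5:
        edges = np.append(edges, 0.5)
    vals = np.array([r.maf for r in records]) if records else np.empty(0)
    counts, _ = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts)) if len(vals) else 0
    return MafSpectrum(
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
        mode_bin=(float(edges[k]), float(edges[k + 1])),
    )


def detect_coverage_peaks(profile: DepthProfile, smooth_sigma: float = 2.0,
                          min_frac: float = 0.01) -> list[float]:
    """Heuristic peak detection: local maxima of the smoothed depth histogram."""
    counts = np.asarray(profile.counts, dtype=float)
    if counts.sum() == 0:
        raise ValidationError("empty depth profile")
    centers = 0.5 * (np.asarray(profile.bin_edges[:-1]) + np.asarray(profile.bin_edges[1:]))
    smooth = gaussian_filter1d(counts, smooth_sigma)
    idx = argrelmax(smooth, order=2)[0]
    floor = min_frac * smooth.max()
    return [float(centers[i]) for i in idx if smooth[i] >= floor]


def coverage_collapse_profile(profile: DepthProfile, snp_depths: Sequence[float],
                              peaks: Optional[Sequence[float]] = None,
                              halfwidth_frac: float = 0.25) -> dict:
    """Assign all sites and SNP sites to coverage peaks (1x vs 2x etc.).

    A site is assigned to the nearest peak when within
    ``halfwidth_frac * peak`` of it, else left unassigned. Returns per-peak
    fractions for both populations.
    """
    counts = np.asarray(profile.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty depth profile")
    if peaks is None:
        peaks = detect_coverage_peaks(profile)
    if not list(peaks):
        raise ValidationError("at least one coverage peak required")
    peaks = sorted(float(p) for p in peaks)
    centers = 0.5 * (np.asarray(profile.bin_edges[:-1]) + np.asarray(profile.bin_edges[1:]))

    def _assign(values: np.ndarray) -> np.ndarray:
        """Index of the assigned peak per value; -1 = unassigned."""
        out = np.full(len(values), -1, dtype=int)
        for i, v in enumerate(values):
            dists = [abs(v - p) for p in peaks]
            k = int(np.argmin(dists))
            if dists[k] <= halfwidth_frac * peaks[k]:
                out[i] = k
        return out

    site_assign = _assign(centers)
    site_fracs = [float(counts[site_assign == k].sum() / total) for k in range(len(peaks))]
    snp_depths = np.asarray(list(snp_depths), dtype=float)
    if len(snp_depths):
        snp_assign = _assign(snp_depths)
        snp_fracs = [float((snp_assign == k).sum() / len(snp_depths)) for k in range(len(peaks))]
        snp_un = float((snp_assign == -1).sum() / len(snp_depths))
    else:
        snp_fracs = [0.0] * len(peaks)
        snp_un = 0.0
    return {
        "peaks": peaks,
        "site_fractions": site_fracs,
        "site_unassigned": float(1.0 - sum(site_fracs)),
        "snp_fractions": snp_fracs,
        "snp_unassigned": snp_un,
    }
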