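"""Protein/codon alignment, NG86 Ka/Ks, SNP divergence, MAF, coverage."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetracomp import divergence as div
from tetracomp.align import align_cds_pair, codon_align, global_protein_align
from tetracomp.models import (
    CodonAlignment,
    DepthProfile,
    HomologyHit,
    ValidationError,
    VariantRecord,
)

from conftest import make_block

# ---------------------------------------------------------------------------
# independent oracles

_B62 = None


def _blosum():
    global _B62
    if _B62 is None:
        from Bio.Align import substitution_matrices
        _B62 = substitution_matrices.load("BLOSUM62")
    return _B62


def brute_force_best_score(a: str, b: str, gap_open=10.0, gap_ext=1.0) -> float:
    """Enumerate every global alignment of two short strings and score it
    (gap of length L costs open + (L-1)*ext)."""
    mat = _blosum()
    best = -math.inf
    stack = [(0, 0, 0.0, "none")]
    while stack:
        i, j, score, prev = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, score + mat[a[i]][b[j]], "diag"))
        if i < len(a):
            cost = gap_ext if prev == "up" else gap_open
            stack.append((i + 1, j, score - cost, "up"))
        if j < len(b):
            cost = gap_ext if prev == "left" else gap_open
            stack.append((i, j + 1, score - cost, "left"))
    return best


_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def oracle_syn_sites(codon):
    aa = div._CODON_TABLE[codon]
    s = 0.0
    for pos, b in itertools.product(range(3), _BASES):
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if alt not in _STOPS and div._CODON_TABLE[alt] == aa:
            s += 1 / 3
    return s


def oracle_paths(c1, c2):
    """Recursive enumeration of substitution paths (vs the permutation-based
    implementation)."""
    if c1 == c2:
        return [(False, 0.0, 0.0)]
    out = []
    for pos in range(3):
        if c1[pos] == c2[pos]:
            continue
        nxt = c1[:pos] + c2[pos] + c1[pos + 1:]
        blocked = nxt in _STOPS and nxt != c2
        syn = div._CODON_TABLE[c1] == div._CODON_TABLE[nxt]
        for b2, sd, nd in oracle_paths(nxt, c2):
            out.append((blocked or b2, sd + (1.0 if syn else 0.0),
                        nd + (0.0 if syn else 1.0)))
    return out


def oracle_ng86(codon_pairs):
    S = N = Sd = Nd = 0.0
    for c1, c2 in codon_pairs:
        s = 0.5 * (oracle_syn_sites(c1) + oracle_syn_sites(c2))
        S += s
        N += 3 - s
        paths = oracle_paths(c1, c2)
        allowed = [(sd, nd) for blocked, sd, nd in paths if not blocked]
        if not allowed:
            allowed = [(sd, nd) for _, sd, nd in paths]
        Sd += sum(p[0] for p in allowed) / len(allowed)
        Nd += sum(p[1] for p in allowed) / len(allowed)
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")

    def jc(p):
        return None if (math.isnan(p) or p >= 0.75) else -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(pS), jc(pN)


SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
         if a + b + c not in _STOPS]


# ---------------------------------------------------------------------------

class TestProteinAlign:
    def test_identical_strings(self):
        a, b, _ = global_protein_align("MKVLA", "MKVLA")
        assert a == b == "MKVLA"

    def test_single_gap_placement(self):
        a, b, _ = global_protein_align("ACDEF", "ACEF")
        assert a == "ACDEF" and b == "AC-EF"

    def test_score_matches_brute_force(self):
        rng = np.random.default_rng(2)
        aas = "ARNDCQEGHILKMFPSTVWY"
        for _ in range(15):
            la, lb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = "".join(rng.choice(list(aas), size=la))
            b = "".join(rng.choice(list(aas), size=lb))
            _, _, score = global_protein_align(a, b)
            assert score == pytest.approx(brute_force_best_score(a, b))

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValidationError):
            global_protein_align("MK1", "MK")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            global_protein_align("", "MK")


class TestCodonAlign:
    def test_ungapped_pair(self):
        aln = codon_align("MK", "MK", "ATGAAA", "ATGAAG")
        assert aln.seq_a == "ATGAAA" and aln.seq_b == "ATGAAG"
        assert aln.codon_count == 2

    def test_gap_becomes_codon_gap(self):
        aln = codon_align("MAK", "M-K", "ATGGCTAAA", "ATGAAA")
        assert aln.seq_b == "ATG---AAA"
        assert aln.codon_count == 2

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError):
            codon_align("MK", "MK", "ATGTAAAAA"[:6] + "TAA", "ATGAAA")

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValidationError, match="codon 2"):
            codon_align("MK", "MK", "ATGGGG", "ATGAAA")

    def test_trailing_stop_tolerated(self):
        aln = codon_align("MK", "MK", "ATGAAATAA", "ATGAAA")
        assert aln.codon_count == 2


class TestKaKs:
    def test_identical_pair_is_zero(self):
        d = div.ka_ks(CodonAlignment("ATGGCTAAA", "ATGGCTAAA"))
        assert d.KS == 0.0 and d.KA == 0.0

    def test_single_synonymous_codon(self):
        # TTT vs TTC (Phe/Phe): one synonymous difference on 1/3 of a
        # synonymous site; pS saturates so KS is undefined, KA = 0
        d = div.ka_ks(CodonAlignment("TTT", "TTC"))
        S, N, Sd, Nd, ks, ka = oracle_ng86([("TTT", "TTC")])
        assert d.Sd == 1.0 and d.Nd == 0.0
        assert d.S == pytest.approx(S) and d.N == pytest.approx(N)
        assert d.KS is ks is None and d.KA == pytest.approx(ka) == 0.0

    def test_matches_oracle_on_sampled_codon_pairs(self):
        rng = np.random.default_rng(4)
        sample = [(SENSE[i], SENSE[j])
                  for i in rng.integers(0, 61, size=150)
                  for j in rng.integers(0, 61, size=1)]
        for c1, c2 in sample:
            d = div.ka_ks(CodonAlignment(c1, c2))
            S, N, Sd, Nd, ks, ka = oracle_ng86([(c1, c2)])
            assert d.S == pytest.approx(S, abs=1e-12)
            assert d.Sd == pytest.approx(Sd, abs=1e-12)
            assert d.Nd == pytest.approx(Nd, abs=1e-12)

    @given(st.lists(st.sampled_from(SENSE), min_size=1, max_size=30),
           st.lists(st.sampled_from(SENSE), min_size=1, max_size=30))
    def test_site_counts_partition_total(self, cod_a, cod_b):
        n = min(len(cod_a), len(cod_b))
        aln = CodonAlignment("".join(cod_a[:n]), "".join(cod_b[:n]))
        d = div.ka_ks(aln)
        assert d.S + d.N == pytest.approx(3 * n, abs=1e-9)

    def test_fourfold_site_mutation_recovers_rate(self):
        # substitutions confined to 4-fold degenerate third positions at
        # 0.1 events/site: KA must be exactly 0, KS close to 0.1
        fourfold = ["GCT", "GGT", "CCT", "ACT", "GTT", "TCT", "CGT", "CTT"]
        rng = np.random.default_rng(6)
        ks_vals = []
        for _ in range(50):
            codons = [fourfold[i] for i in rng.integers(0, len(fourfold), size=100)]
            seq_a = "".join(codons)
            seq_b = list(seq_a)
            n_events = rng.binomial(100, 0.1)  # 0.1 events per 4-fold site
            for _e in range(n_events):
                k = int(rng.integers(0, 100))
                pos = 3 * k + 2
                cur = seq_b[pos]
                seq_b[pos] = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4]
            d = div.ka_ks(CodonAlignment(seq_a, "".join(seq_b)))
            assert d.KA == 0.0
            if d.KS is not None:
                ks_vals.append(d.KS)
        mean_ks = float(np.mean(ks_vals))
        assert mean_ks == pytest.approx(0.1, abs=0.02)

    def test_zero_ungapped_codons_rejected(self):
        with pytest.raises(ValidationError):
            div.ka_ks(CodonAlignment("---", "---"))


class TestBlockMeans:
    def _pd(self, a, b, ks, ka=0.0):
        return div.PairDivergence(a, b, 1, 1, 0, 0, 0, 0, ks, ka)

    def test_mean_of_defined(self):
        b = make_block(0, "sA", "sB", 0, 0, n=5)
        pairs = {frozenset((p.gene_a, p.gene_b)): self._pd(p.gene_a, p.gene_b, ks)
                 for p, ks in zip(b.pairs, [0.04, 0.06, None, None, None])}
        pairs = {k: v for k, v in pairs.items() if v.KS is not None}
        ks, ka = div.block_mean_divergence(b, pairs)
        assert ks == pytest.approx(0.05)

    def test_undefined_excluded(self):
        b = make_block(0, "sA", "sB", 0, 0, n=2)
        pairs = {frozenset((p.gene_a, p.gene_b)): self._pd(p.gene_a, p.gene_b, ks)
                 for p, ks in zip(b.pairs, [0.2, None])}
        ks, _ = div.block_mean_divergence(b, pairs)
        assert ks == pytest.approx(0.2)

    def test_all_undefined(self):
        b = make_block(0, "sA", "sB", 0, 0, n=2)
        ks, ka = div.block_mean_divergence(b, {})
        assert ks is None and ka is None


class TestTopNonself:
    def _hits(self, ident, n=6):
        out = []
        for i in range(n):
            out.append(HomologyHit(f"g{i}", f"g{i}", 100.0, 100, 0.0, 500.0))
            out.append(HomologyHit(f"g{i}", f"h{i}", ident, 100, 1e-50, 200.0))
        return out

    def test_median_divergence(self):
        divs, median, mode, n_omitted = div.top_nonself_identity(self._hits(98.58))
        assert median == pytest.approx(1.42)
        assert n_omitted == 0

    def test_perfect_identity_zero_divergence(self):
        hits = [HomologyHit("g", "h", 100.0, 100, 1e-50, 200.0)]
        divs, median, mode, _ = div.top_nonself_identity(hits)
        assert divs["g"] == 0.0 and median == 0.0

    def test_gene_without_nonself_hit_omitted(self):
        hits = [HomologyHit("g", "g", 100.0, 100, 0.0, 500.0)]
        divs, median, mode, n_omitted = div.top_nonself_identity(hits)
        assert divs == {} and n_omitted == 1

    def test_planted_homolog_divergence_recovered(self):
        from tetracomp.simulate import SimParams, simulate_tetraploid, simulate_intragenomic_hits
        p = SimParams(seed=9, n_scaffold_quartets=1, genes_per_scaffold=30,
                      d_hom=0.045, d_ohn=0.4, n_breaks=0, n_palindromes=0,
                      n_tandems=0)
        b = simulate_tetraploid(p)
        _, median, _, _ = div.top_nonself_identity(simulate_intragenomic_hits(b))
        assert median == pytest.approx(4.5, abs=0.8)


class TestSnpDivergence:
    def test_printed_bound(self):
        assert div.snp_divergence(13115, 40.0e6) == pytest.approx(0.0328, abs=5e-4)

    def test_zero_snps(self):
        assert div.snp_divergence(0, 1e6) == 0.0

    def test_zero_span_rejected(self):
        with pytest.raises(ValidationError):
            div.snp_divergence(10, 0)

    @given(st.integers(0, 10**6), st.integers(1, 10**9), st.integers(1, 50))
    def test_linear_and_scale_invariant(self, n, span, k):
        assert div.snp_divergence(k * n, span) == pytest.approx(k * div.snp_divergence(n, span))
        assert div.snp_divergence(k * n, k * span) == pytest.approx(div.snp_divergence(n, span))


class TestFilterSnps:
    def _rec(self, mapq=60, qual=50, dr=50, da=50):
        return VariantRecord("s", 1, "A", "C", mapq, qual, dr, da)

    def test_mapq_boundary(self):
        kept = div.filter_snps([self._rec(mapq=29), self._rec(mapq=30)], mean_cov=100)
        assert len(kept) == 1 and kept[0].mapq == 30

    def test_depth_fraction_boundary(self):
        kept = div.filter_snps([self._rec(dr=12, da=12), self._rec(dr=13, da=12)],
                               mean_cov=100)
        assert len(kept) == 1 and kept[0].depth == 25

    def test_all_passing_retained(self):
        recs = [self._rec() for _ in range(10)]
        assert len(div.filter_snps(recs, mean_cov=100)) == 10

    def test_mean_cov_required(self):
        with pytest.raises(ValidationError):
            div.filter_snps([self._rec()], mean_cov=None)


class TestFoldMaf:
    def test_balanced_depths(self):
        spec = div.fold_maf([VariantRecord("s", 1, "A", "C", 60, 50, 30, 30)])
        assert spec.mode_bin == (pytest.approx(0.48), pytest.approx(0.5))

    def test_quarter(self):
        r = VariantRecord("s", 1, "A", "C", 60, 50, 75, 25)
        assert r.maf == pytest.approx(0.25)

    @given(st.lists(st.tuples(st.integers(1, 200), st.integers(1, 200)),
                    min_size=1, max_size=50))
    def test_invariant_under_ref_alt_swap(self, depths):
        recs = [VariantRecord("s", i + 1, "A", "C", 60, 50, dr, da)
                for i, (dr, da) in enumerate(depths)]
        swapped = [VariantRecord("s", i + 1, "A", "C", 60, 50, da, dr)
                   for i, (dr, da) in enumerate(depths)]
        assert div.fold_maf(recs).counts == div.fold_maf(swapped).counts

    def test_binomial_sampling_mode_contains_half(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(10000):
            alt = int(rng.binomial(100, 0.5))
            alt = min(max(alt, 1), 99)
            recs.append(VariantRecord("s", i + 1, "A", "C", 60, 50, 100 - alt, alt))
        spec = div.fold_maf(recs)
        lo, hi = spec.mode_bin
        assert lo < 0.5 <= hi


class TestCoverageCollapse:
    def test_single_peak_all_assigned(self):
        prof = DepthProfile([85.0, 95.0], [1000])
        out = div.coverage_collapse_profile(prof, [], peaks=[90.0, 180.0])
        assert out["site_fractions"] == [pytest.approx(1.0), pytest.approx(0.0)]

    def test_mixture_recovery(self):
        rng = np.random.default_rng(5)
        depths = np.concatenate([rng.poisson(100, size=75000),
                                 rng.poisson(200, size=25000)])
        edges = np.arange(0, 320, 2.0)
        counts, _ = np.histogram(depths, bins=edges)
        prof = DepthProfile([float(e) for e in edges], [int(c) for c in counts])
        out = div.coverage_collapse_profile(prof, [], peaks=[100.0, 200.0])
        assert out["site_fractions"][0] == pytest.approx(0.75, abs=0.02)
        assert out["site_fractions"][1] == pytest.approx(0.25, abs=0.02)

    def test_snps_from_collapsed_regions(self):
        rng = np.random.default_rng(5)
        depths = np.concatenate([rng.poisson(100, size=50000),
                                 rng.poisson(200, size=50000)])
        edges = np.arange(0, 320, 2.0)
        counts, _ = np.histogram(depths, bins=edges)
        prof = DepthProfile([float(e) for e in edges], [int(c) for c in counts])
        snp_depths = rng.poisson(200, size=2000)
        out = div.coverage_collapse_profile(prof, snp_depths, peaks=[100.0, 200.0])
        assert out["snp_fractions"][1] >= 0.98

    def test_peak_detection_finds_both_modes(self):
        rng = np.random.default_rng(5)
        depths = np.concatenate([rng.poisson(100, size=60000),
                                 rng.poisson(200, size=40000)])
        edges = np.arange(0, 320, 2.0)
        counts, _ = np.histogram(depths, bins=edges)
        prof = DepthProfile([float(e) for e in edges], [int(c) for c in counts])
        peaks = div.detect_coverage_peaks(prof)
        assert any(abs(p - 100) < 10 for p in peaks)
        assert any(abs(p - 200) < 12 for p in peaks)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            div.coverage_collapse_profile(DepthProfile([0.0, 1.0], [0]), [], peaks=[1.0])


class TestParameterRecovery:
    def test_ks_estimates_substitutions_per_site(self):
        # uniform (unbiased) mutation at d = 0.25: block-mean KS must sit
        # within 10% of the planted ohnologous divergence, homolog KS near 0
        from tetracomp import collinearity as col
        from tetracomp.simulate import (SimParams, homolog_pairs_from_truth,
                                        simulate_tetraploid)
        p = SimParams(seed=13, n_scaffold_quartets=1, genes_per_scaffold=40,
                      d_hom=0.001, d_ohn=0.25, syn_bias=0.0,
                      n_breaks=0, n_palindromes=0, n_tandems=0)
        b = simulate_tetraploid(p)
        orders = col.gene_orders(b.genes)
        pairs = col.build_pairs(homolog_pairs_from_truth(b), orders)
        blocks = col.chain_blocks(pairs, orders)
        cds = {g.gene_id: g.cds_seq for g in b.genes}
        hom_ks, ohn_ks = [], []
        for blk in blocks:
            vals = []
            for pr in blk.pairs:
                d = div.ka_ks(align_cds_pair(cds[pr.gene_a], cds[pr.gene_b]))
                if d.KS is not None:
                    vals.append(d.KS)
            mean = float(np.mean(vals))
            sub_a, sub_b = blk.scaffold_a[-2], blk.scaffold_b[-2]
            (hom_ks if sub_a == sub_b else ohn_ks).append(mean)
        assert hom_ks and ohn_ks
        assert float(np.mean(ohn_ks)) == pytest.approx(0.25, rel=0.10)
        assert float(np.mean(hom_ks)) < 0.01
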