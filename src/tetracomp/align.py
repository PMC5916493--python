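"""Deterministic global protein alignment and codon back-translation.

A built-in Needleman-Wunsch/Gotoh aligner (BLOSUM62, gap open 10, gap
extend 1) keeps alignment fully reproducible: ties are broken by a fixed
priority (match state first, then a gap in the second sequence, then a gap
in the first). A gap of length L costs open + (L-1)*extend. The inner DP is
numba-compiled; precomputed protein alignments can be supplied instead
anywhere a caller prefers an external aligner's output.
"""
from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .models import CodonAlignment, ValidationError

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = "".join(a for a in _BLOSUM.alphabet if a != "*")
_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(_ALPHABET):
    _AA_INDEX[ord(_a)] = _i
_SUBMAT = np.zeros((len(_ALPHABET), len(_ALPHABET)), dtype=np.float64)
for _i, _a in enumerate(_ALPHABET):
    for _j, _b in enumerate(_ALPHABET):
        _SUBMAT[_i, _j] = _BLOSUM[_a][_b]

_DIAG, _UP, _LEFT = 0, 1, 2
_NEG = -1e18


@njit(cache=False)
def _nw_kernel(a, b, sub, gap_open, gap_ext):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (consume a, "up")
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (consume b, "left")
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_ext)
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_ext)
        pY[0, j] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            # match state: best predecessor, tie priority M > X > Y
            best = M[i - 1, j - 1]
            ptr = _DIAG
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _UP
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _LEFT
            M[i, j] = best + s
            pM[i, j] = ptr
            # gap states: prefer opening (from M) on ties
            if M[i - 1, j] - gap_open >= X[i - 1, j] - gap_ext:
                X[i, j] = M[i - 1, j] - gap_open
                pX[i, j] = 0
            else:
                X[i, j] = X[i - 1, j] - gap_ext
                pX[i, j] = 1
            if M[i, j - 1] - gap_open >= Y[i, j - 1] - gap_ext:
                Y[i, j] = M[i, j - 1] - gap_open
                pY[i, j] = 0
            else:
                Y[i, j] = Y[i, j - 1] - gap_ext
                pY[i, j] = 1
    # traceback, tie priority M > X > Y
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = _DIAG
            k += 1
            nxt = pM[i, j]
            i -= 1
            j -= 1
            state = nxt
        elif state == 1:
            ops[k] = _UP
            k += 1
            nxt = pX[i, j]
            i -= 1
            state = 0 if nxt == 0 else 1
        else:
            ops[k] = _LEFT
            k += 1
            nxt = pY[i, j]
            j -= 1
            state = 0 if nxt == 0 else 2
        if i == 0 and j > 0 and state == 0:
            state = 2
        if j == 0 and i > 0 and state == 0:
            state = 1
    return score, ops[:k][::-1].copy()


def _encode(prot: str) -> np.ndarray:
    arr = np.empty(len(prot), dtype=np.int64)
    for i, ch in enumerate(prot):
        idx = _AA_INDEX[ord(ch)] if ord(ch) < 128 else -1
        if idx < 0:
            raise ValidationError(f"non-amino-acid symbol {ch!r} in protein sequence")
        arr[i] = idx
    return arr


def global_protein_align(prot_a: str, prot_b: str, gap_open: float = 10.0,
                         gap_ext: float = 1.0) -> tuple[str, str, float]:
    """Global (NW) alignment of two proteins; returns (aln_a, aln_b, score)."""
    if not prot_a or not prot_b:
        raise ValidationError("empty protein sequence")
    a, b = _encode(prot_a.upper()), _encode(prot_b.upper())
    score, ops = _nw_kernel(a, b, _SUBMAT, float(gap_open), float(gap_ext))
    out_a, out_b = [], []
    i = j = 0
    for op in ops:
        if op == _DIAG:
            out_a.append(prot_a[i]); out_b.append(prot_b[j]); i += 1; j += 1
        elif op == _UP:
            out_a.append(prot_a[i]); out_b.append("-"); i += 1
        else:
            out_a.append("-"); out_b.append(prot_b[j]); j += 1
    return "".join(out_a), "".join(out_b), float(score)


def _check_translation(cds: str, prot: str, label: str) -> str:
    """Validate that cds translates to prot; returns cds without trailing stop."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"{label}: CDS length not divisible by 3")
    translated = str(Seq(cds).translate())
    if translated.endswith("*"):
        translated = translated[:-1]
        cds = cds[:-3]
    if "*" in translated:
        pos = translated.index("*")
        raise ValidationError(f"{label}: internal stop codon at codon {pos + 1}")
    if translated != prot.upper():
        for k, (x, y) in enumerate(zip(translated, prot.upper())):
            if x != y:
                raise ValidationError(
                    f"{label}: translation mismatch at codon {k + 1} ({x} vs {y})"
                )
        raise ValidationError(f"{label}: translation/protein length mismatch")
    return cds


def codon_align(aln_prot_a: str, aln_prot_b: str, cds_a: str, cds_b: str) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its source CDSs.

    Each aligned residue is replaced by its codon; residue gaps become
    ``---`` codon gaps. Both CDSs must translate exactly to their proteins
    (standard code; one trailing stop codon is tolerated and dropped).
    """
    prot_a = aln_prot_a.replace("-", "")
    prot_b = aln_prot_b.replace("-", "")
    cds_a = _check_translation(cds_a, prot_a, "seq_a")
    cds_b = _check_translation(cds_b, prot_b, "seq_b")
    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(aln_prot_a, aln_prot_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3]); ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3]); ib += 1
    return CodonAlignment("".join(out_a), "".join(out_b))


def align_cds_pair(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-align then back-translate a CDS pair (the paper's route)."""
    prot_a = str(Seq(cds_a.upper()).translate()).rstrip("*")
    prot_b = str(Seq(cds_b.upper()).translate()).rstrip("*")
    aln_a, aln_b, _ = global_protein_align(prot_a, prot_b)
    return codon_align(aln_a, aln_b, cds_a, cds_b)
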