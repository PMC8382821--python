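"""Local pairwise protein alignment with BLAST-like statistics.

The similarity kernel behind the sequence similarity networks.  Alignment is
optimal Smith–Waterman under affine gaps (Gotoh), scored with BLOSUM62 and the
blastp default gap penalties (open 11, extend 1; a length-k gap costs 11+k).
Raw scores are converted to bit scores and E-values with the Karlin–Altschul
formula using NCBI's gapped BLOSUM62 constants, and the EFI-style "alignment
score" is -log10 of the E-value.

The DP is vectorized row-wise in numpy; the horizontal (affine) gap state is
resolved with a running-maximum scan, so each row costs O(m) array work.
Traceback is deterministic with tie order diagonal > up > left.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord

# Karlin–Altschul constants for gapped BLOSUM62, open 11 / extend 1 (NCBI)
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_EVALUE_CUTOFF = 1e-5

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_B62.alphabet)
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
#: BLOSUM62 as a plain numpy array indexed by ``_CHAR_INDEX``
BLOSUM62 = np.array(_B62, dtype=np.float64)


def load_matrix(path_or_name: str) -> np.ndarray:
    """Load a substitution matrix: a named Biopython matrix or an NCBI-format
    text file. Returned as a numpy array over the BLOSUM62 alphabet order."""
    if os.path.exists(path_or_name):
        mat = substitution_matrices.read(path_or_name)
    else:
        mat = substitution_matrices.load(path_or_name)
    out = np.full((len(_ALPHABET), len(_ALPHABET)), -4.0)
    alpha = str(mat.alphabet)
    for a in alpha:
        for b in alpha:
            if a in _CHAR_INDEX and b in _CHAR_INDEX:
                out[_CHAR_INDEX[a], _CHAR_INDEX[b]] = mat[a, b]
    return out


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CHAR_INDEX[c] for c in seq.upper()], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"residue {exc.args[0]!r} not in matrix alphabet") from exc


@dataclass(frozen=True)
class PairwiseHit:
    """One above-cutoff local alignment between two proteins.

    ``alignment_score`` is the EFI convention: -log10 of the E-value, floored
    at zero.  ``percent_identity`` follows BLAST: identical residue pairs over
    the alignment length including gap columns.  Coverages are the aligned
    span over the full sequence length, in percent.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    alignment_score: float
    percent_identity: float
    alignment_length: int
    query_coverage: float
    subject_coverage: float


def _gotoh_matrices(a: np.ndarray, b: np.ndarray, sub: np.ndarray,
                    open_pen: float, ext_pen: float):
    """Full Smith–Waterman/Gotoh DP matrices (H, E, F), vectorized per row.

    Gap of length k costs ``open_pen + k * ext_pen``.  E is the
    gap-in-``a``/horizontal state, F the vertical.  The E recurrence
    E[i,j] = max(H'[i,j-1] - open - ext, E[i,j-1] - ext) is exact with H'
    replaced by the E-free part of H, which allows a prefix-max scan.
    """
    n, m = len(a), len(b)
    neg = -np.inf
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    first = open_pen + ext_pen  # cost of the first gap residue
    idx = np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] - ext_pen, H[i - 1, 1:] - first)
        diag = H[i - 1, :-1] + sub[a[i - 1], b]
        h_no_e = np.maximum(np.maximum(diag, F[i, 1:]), 0.0)
        padded = np.concatenate(([0.0], h_no_e))  # j = 0..m
        running = np.maximum.accumulate(padded + idx * ext_pen)
        E[i, 1:] = running[:-1] - first - (idx[1:] - 1.0) * ext_pen
        H[i, 1:] = np.maximum(h_no_e, E[i, 1:])
    return H, E, F


def smith_waterman_score(a: str, b: str, matrix: np.ndarray | None = None,
                         gap_open: float = DEFAULT_GAP_OPEN,
                         gap_extend: float = DEFAULT_GAP_EXTEND) -> int:
    """Optimal local alignment score only (no traceback); faster path."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    sub = BLOSUM62 if matrix is None else matrix
    H, _, _ = _gotoh_matrices(encode(a), encode(b), sub, gap_open, gap_extend)
    return int(H.max())


def smith_waterman(a: str, b: str, matrix: np.ndarray | None = None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND):
    """Optimal local alignment of ``a`` vs ``b`` under affine gaps.

    Returns ``(raw_score, aligned_a, aligned_b, (a_start, a_end, b_start,
    b_end))`` with 1-based inclusive span coordinates.  Traceback starts at
    the first maximal cell in row-major order and resolves ties in the order
    diagonal > up > left, so output is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    sub = BLOSUM62 if matrix is None else matrix
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("need gap_open >= gap_extend >= 0")
    ea, eb = encode(a), encode(b)
    H, E, F = _gotoh_matrices(ea, eb, sub, gap_open, gap_extend)
    score = H.max()
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    first = gap_open + gap_extend

    out_a: list[str] = []
    out_b: list[str] = []
    end_i, end_j = i, j
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[ea[i - 1], eb[j - 1]] if i and j else -np.inf
            if i and j and H[i, j] == diag:
                out_a.append(a[i - 1]); out_b.append(b[j - 1])
                i -= 1; j -= 1
            elif i and H[i, j] == F[i, j]:
                state = "F"
            elif j and H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP guarantees one branch holds
                raise AssertionError("traceback failed")
        elif state == "F":  # gap in b, consume a
            out_a.append(a[i - 1]); out_b.append("-")
            came_open = H[i - 1, j] - first
            i -= 1
            if F[i + 1, j] == came_open:
                state = "H"
            # else remain in F (extension)
        else:  # state == "E": gap in a, consume b
            out_a.append("-"); out_b.append(b[j - 1])
            came_open = H[i, j - 1] - first
            j -= 1
            if E[i, j + 1] == came_open:
                state = "H"
    start_i, start_j = i, j
    return (
        int(score),
        "".join(reversed(out_a)),
        "".join(reversed(out_b)),
        (start_i + 1, end_i, start_j + 1, end_j),
    )


def score_hit(raw_score: float, m: int, n: int,
              lam: float = LAMBDA_GAPPED, K: float = K_GAPPED):
    """Karlin–Altschul statistics for a raw local alignment score.

    bit_score = (lam*S - ln K) / ln 2;  E = m*n*2^(-bit_score);
    alignment_score = max(0, -log10 E).
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if lam <= 0 or K <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    bit_score = (lam * raw_score - math.log(K)) / math.log(2)
    evalue = m * n * 2.0 ** (-bit_score)
    alignment_score = max(0.0, -math.log10(evalue)) if evalue > 0 else math.inf
    return bit_score, evalue, alignment_score


def align_pair(qa: ProteinRecord, qb: ProteinRecord,
               matrix: np.ndarray | None = None,
               gap_open: float = DEFAULT_GAP_OPEN,
               gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseHit:
    """Align two proteins and package the full hit record."""
    raw, al_a, al_b, (qs, qe, ss, se) = smith_waterman(
        qa.sequence, qb.sequence, matrix, gap_open, gap_extend
    )
    ident = sum(1 for x, y in zip(al_a, al_b) if x == y and x != "-")
    length = len(al_a)
    bit, evalue, ascore = score_hit(raw, len(qa.sequence), len(qb.sequence))
    return PairwiseHit(
        query_id=qa.protein_id,
        subject_id=qb.protein_id,
        raw_score=raw,
        bit_score=bit,
        evalue=evalue,
        alignment_score=ascore,
        percent_identity=100.0 * ident / length if length else 0.0,
        alignment_length=length,
        query_coverage=100.0 * (qe - qs + 1) / len(qa.sequence),
        subject_coverage=100.0 * (se - ss + 1) / len(qb.sequence),
    )


def all_vs_all(records: Sequence[ProteinRecord],
               evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
               matrix: np.ndarray | None = None,
               gap_open: float = DEFAULT_GAP_OPEN,
               gap_extend: float = DEFAULT_GAP_EXTEND) -> list[PairwiseHit]:
    """One hit per unordered pair with E-value <= cutoff; self-pairs excluded.

    Query/subject assignment within each pair follows the input order, so
    results are deterministic for a fixed record list (and the partition
    induced downstream is order-independent, since scores are symmetric).
    """
    if len(records) < 2:
        return []
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids in all_vs_all input: {dupes}")
    hits = []
    for ra, rb in itertools.combinations(records, 2):
        hit = align_pair(ra, rb, matrix, gap_open, gap_extend)
        if hit.evalue <= evalue_cutoff:
            hits.append(hit)
    return hits


def hits_to_frame(hits: Sequence[PairwiseHit]) -> pd.DataFrame:
    """BLAST-tabular-like table (qseqid, sseqid, pident, length, bitscore,
    evalue, qcovs) plus the EFI alignment score."""
    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(h.percent_identity, 2),
                "length": h.alignment_length,
                "bitscore": round(h.bit_score, 1),
                "evalue": h.evalue,
                "qcovs": round(h.query_coverage, 1),
                "alignment_score": round(h.alignment_score, 2),
            }
            for h in hits
        ],
        columns=["qseqid", "sseqid", "pident", "length", "bitscore", "evalue",
                 "qcovs", "alignment_score"],
    )
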