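"""Internal alignment engine backing AAI/POCP and 16S identity.

Local protein alignment (Smith–Waterman, affine gaps, BLOSUM62 by default)
with BLAST-style bit scores and e-values, global nucleotide alignment
(Needleman–Wunsch, linear gaps), and one-way best-hit search between
proteomes. Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend`` (so 11/1 charges 12 for the first gap
residue).

Tracebacks are deterministic: the alignment endpoint is the first maximal
cell in row-major order and ties are resolved diagonal > up > left (up
consumes a query residue). This makes every downstream metric bit-exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from marinitax.seq_io import Proteome, SequenceRecord

_NEG_INF = -1.0e18

#: BLOSUM62 alphabet order used for residue encoding.
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)  # "ARNDCQEGHILKMFPSTWYVBZX*"
_X_INDEX = _ALPHABET.index("X")

_ENCODE = np.full(256, _X_INDEX, dtype=np.int64)
for _i, _ch in enumerate(_ALPHABET):
    _ENCODE[ord(_ch)] = _i

_MATRICES: dict[str, np.ndarray] = {}


def _substitution_array(name: str) -> np.ndarray:
    """Named amino-acid matrix as a dense float64 array in BLOSUM62 order."""
    if name not in _MATRICES:
        mat = substitution_matrices.load(name)
        if str(mat.alphabet) != _ALPHABET:
            raise ValueError(
                f"matrix {name!r} alphabet {mat.alphabet!r} differs from BLOSUM62 order"
            )
        _MATRICES[name] = np.asarray(mat, dtype=np.float64)
    return _MATRICES[name]


def encode_protein(sequence: str) -> np.ndarray:
    """Encode a protein string as BLOSUM62 row indices (unknowns → 'X')."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and statistics parameters for protein search.

    ``lambda_`` and ``k_const`` are the Karlin–Altschul parameters of the
    gapped BLOSUM62/11/1 system used for bit scores and e-values
    (``E = K·m·n·exp(−λ·S)``).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k_const: float = 0.041
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("lambda_ and k_const must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject protein."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_pct: float  # identities / alignment columns (gaps included)
    aln_len: int
    query_cover_pct: float  # aligned query residues / query length
    subject_cover_pct: float = field(default=0.0)
    n_identical: int = field(default=0)
    query_aligned: int = field(default=0)
    subject_aligned: int = field(default=0)


@dataclass(frozen=True)
class GlobalAlignment:
    """Global nucleotide alignment as two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _sw_score(a, b, sub, gap_open, gap_ext):
    """Optimal local score, linear memory (two rolling rows)."""
    n = b.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.float64)
    f_prev = np.full(n + 1, _NEG_INF, dtype=np.float64)
    h_cur = np.zeros(n + 1, dtype=np.float64)
    f_cur = np.full(n + 1, _NEG_INF, dtype=np.float64)
    best = 0.0
    for i in range(1, a.shape[0] + 1):
        e = _NEG_INF  # E[i, j-1]
        h_cur[0] = 0.0
        for j in range(1, n + 1):
            e = max(e - gap_ext, h_cur[j - 1] - gap_open - gap_ext)
            f_cur[j] = max(f_prev[j] - gap_ext, h_prev[j] - gap_open - gap_ext)
            diag = h_prev[j - 1] + sub[a[i - 1], b[j - 1]]
            h = max(0.0, diag, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return best


@njit(cache=True)
def _sw_full(a, b, sub, gap_open, gap_ext):
    """Full H/E/F matrices for traceback."""
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), _NEG_INF, dtype=np.float64)
    F = np.full((m + 1, n + 1), _NEG_INF, dtype=np.float64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1], H[i, j - 1] - gap_open) - gap_ext
            F[i, j] = max(F[i - 1, j], H[i - 1, j] - gap_open) - gap_ext
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
    return H, E, F


@njit(cache=True)
def _sw_traceback(a, b, sub, gap_open, gap_ext):
    """Optimal local alignment statistics via deterministic traceback.

    Returns (score, n_identical, n_columns, query_aligned, subject_aligned).
    Endpoint = first maximal H cell in row-major order; tie order
    diagonal > up (gap in subject) > left (gap in query); inside a gap the
    gap is closed as early as possible.
    """
    m, n = a.shape[0], b.shape[0]
    H, E, F = _sw_full(a, b, sub, gap_open, gap_ext)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i, j] > best:
                best = H[i, j]
                bi, bj = i, j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0

    i, j = bi, bj
    n_ident = 0
    n_cols = 0
    q_aligned = 0
    s_aligned = 0
    state = 0  # 0 = match state (H), 1 = up/F (gap in subject), 2 = left/E
    while True:
        if state == 0:
            if H[i, j] == 0.0:
                break
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]] if i > 0 and j > 0 else _NEG_INF
            if i > 0 and j > 0 and H[i, j] == diag:
                n_cols += 1
                q_aligned += 1
                s_aligned += 1
                if a[i - 1] == b[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            # consume a[i-1] against a gap
            n_cols += 1
            q_aligned += 1
            closes = H[i - 1, j] - gap_open - gap_ext
            stays = F[i - 1, j] - gap_ext
            val = F[i, j]
            i -= 1
            if val == closes:
                state = 0
            elif val == stays:
                state = 1
            else:
                state = 0
        else:
            n_cols += 1
            s_aligned += 1
            closes = H[i, j - 1] - gap_open - gap_ext
            stays = E[i, j - 1] - gap_ext
            val = E[i, j]
            j -= 1
            if val == closes:
                state = 0
            elif val == stays:
                state = 2
            else:
                state = 0
    return best, n_ident, n_cols, q_aligned, s_aligned


@njit(cache=True)
def _sw_score_all(q, subj_buf, offsets, sub, gap_open, gap_ext):
    """Scores of one query against every subject in a concatenated buffer."""
    k = offsets.shape[0] - 1
    out = np.empty(k, dtype=np.float64)
    for t in range(k):
        out[t] = _sw_score(q, subj_buf[offsets[t] : offsets[t + 1]], sub, gap_open, gap_ext)
    return out


@njit(cache=True)
def _nw_linear(a, b, match, mismatch, gap):
    """Global DP matrix and deterministic traceback moves.

    Moves are emitted end→start: 0 diagonal, 1 up (consume a), 2 left
    (consume b); tie order diagonal > up > left.
    """
    m, n = a.shape[0], b.shape[0]
    H = np.empty((m + 1, n + 1), dtype=np.float64)
    for j in range(n + 1):
        H[0, j] = gap * j
    for i in range(1, m + 1):
        H[i, 0] = gap * i
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    moves = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                moves[k] = 0
                i -= 1
                j -= 1
                k += 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            moves[k] = 1
            i -= 1
            k += 1
            continue
        moves[k] = 2
        j -= 1
        k += 1
    return H[m, n], moves[:k]


# ---------------------------------------------------------------------------
# public operations


def evalue_from_score(raw_score: float, m: int, n: int, p: AlignParams | None = None) -> float:
    """Karlin–Altschul expectation ``E = K·m·n·exp(−λ·S)``.

    ``m`` is the query length and ``n`` the residue count of the searched
    subject set.
    """
    if p is None:
        p = AlignParams()
    if m < 1 or n < 1:
        raise ValueError("search space dimensions m, n must be >= 1")
    return p.k_const * m * n * math.exp(-p.lambda_ * raw_score)


def bit_score_from_raw(raw_score: float, p: AlignParams | None = None) -> float:
    """Normalized bit score ``(λ·S − ln K) / ln 2``."""
    if p is None:
        p = AlignParams()
    return (p.lambda_ * raw_score - math.log(p.k_const)) / math.log(2.0)


def smith_waterman_protein(
    a: SequenceRecord,
    b: SequenceRecord,
    p: AlignParams | None = None,
    search_space_n: int | None = None,
) -> AlignmentHit | None:
    """Optimal local alignment of two proteins, or ``None`` if no positive score.

    ``search_space_n`` overrides the e-value subject size (defaults to
    ``len(b)``; :func:`search_best_hits` passes the whole-proteome residue
    count, matching BLAST database semantics).
    """
    if p is None:
        p = AlignParams()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    sub = _substitution_array(p.substitution_matrix)
    score, n_ident, n_cols, q_aln, s_aln = _sw_traceback(
        encode_protein(a.sequence), encode_protein(b.sequence), sub, p.gap_open, p.gap_extend
    )
    if score <= 0.0:
        return None
    n = search_space_n if search_space_n is not None else len(b)
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=int(round(score)),
        bit_score=bit_score_from_raw(score, p),
        evalue=evalue_from_score(score, len(a), n, p),
        identity_pct=100.0 * n_ident / n_cols,
        aln_len=n_cols,
        query_cover_pct=100.0 * q_aln / len(a),
        subject_cover_pct=100.0 * s_aln / len(b),
        n_identical=n_ident,
        query_aligned=q_aln,
        subject_aligned=s_aln,
    )


def needleman_wunsch_nucleotide(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> GlobalAlignment:
    """Optimal global alignment of two nucleotide sequences (linear gaps)."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    ca = np.frombuffer(a.sequence.encode("ascii"), dtype=np.uint8)
    cb = np.frombuffer(b.sequence.encode("ascii"), dtype=np.uint8)
    score, moves = _nw_linear(ca, cb, match, mismatch, gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for mv in moves[::-1]:
        if mv == 0:
            out_a.append(a.sequence[i])
            out_b.append(b.sequence[j])
            i += 1
            j += 1
        elif mv == 1:
            out_a.append(a.sequence[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b.sequence[j])
            j += 1
    return GlobalAlignment("".join(out_a), "".join(out_b), float(score))


def _concat_codes(proteome: Proteome) -> tuple[np.ndarray, np.ndarray]:
    codes = [encode_protein(r.sequence) for r in proteome.records]
    offsets = np.zeros(len(codes) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([c.shape[0] for c in codes])
    return np.concatenate(codes), offsets


def search_best_hits(
    query: Proteome,
    subject: Proteome,
    p: AlignParams | None = None,
) -> dict[str, AlignmentHit]:
    """Best subject hit for each query protein at ``E < p.max_evalue``.

    The best hit maximizes the raw (hence bit) score; score ties go to the
    lexicographically smaller subject id. Queries without a qualifying hit
    are absent from the map. E-values use the subject proteome's total
    residue count as ``n``.
    """
    if p is None:
        p = AlignParams()
    sub = _substitution_array(p.substitution_matrix)
    subj_buf, offsets = _concat_codes(subject)
    n_total = subject.n_residues
    order = sorted(range(subject.n_proteins), key=lambda t: subject.records[t].id)
    hits: dict[str, AlignmentHit] = {}
    for q_rec in query.records:
        scores = _sw_score_all(
            encode_protein(q_rec.sequence), subj_buf, offsets, sub, p.gap_open, p.gap_extend
        )
        best = scores.max()
        if best <= 0.0 or evalue_from_score(best, len(q_rec), n_total, p) >= p.max_evalue:
            continue
        winner = next(t for t in order if scores[t] == best)
        hit = smith_waterman_protein(
            q_rec, subject.records[winner], p, search_space_n=n_total
        )
        assert hit is not None and hit.raw_score == int(round(best))
        hits[q_rec.id] = hit
    return hits
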