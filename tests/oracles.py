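"""Independent brute-force oracles used only by the test suite.

The local aligner here is a naive full-matrix affine-gap DP with explicit
pointer matrices recorded during the fill — a deliberately different
mechanism from the package's recompute-and-compare traceback — written
against the same documented conventions (gap of length L costs
open + L·extend; endpoint = first maximal cell row-major; ties
diagonal > up > left; gaps close as early as possible). Metric oracles
apply the AAI/POCP filter definitions literally over all protein pairs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from marinitax.pairwise_align import (
    AlignParams,
    _substitution_array,
    encode_protein,
    evalue_from_score,
)
from marinitax.seq_io import Proteome

NEG = -1.0e18

# pointer codes: 0 stop, 1 diag, 2 up-close, 3 up-extend, 4 left-close, 5 left-extend


@njit(cache=True)
def _naive_fill(a, b, sub, go, ge):
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ph = np.zeros((m + 1, n + 1), dtype=np.int8)  # pointer in H
    pe = np.zeros((m + 1, n + 1), dtype=np.int8)  # 4 close / 5 extend
    pf = np.zeros((m + 1, n + 1), dtype=np.int8)  # 2 close / 3 extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_close = H[i, j - 1] - go - ge
            e_ext = E[i, j - 1] - ge
            if e_close >= e_ext:
                E[i, j] = e_close
                pe[i, j] = 4
            else:
                E[i, j] = e_ext
                pe[i, j] = 5
            f_close = H[i - 1, j] - go - ge
            f_ext = F[i - 1, j] - ge
            if f_close >= f_ext:
                F[i, j] = f_close
                pf[i, j] = 2
            else:
                F[i, j] = f_ext
                pf[i, j] = 3
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            best = max(0.0, diag, F[i, j], E[i, j])
            H[i, j] = best
            if best == 0.0:
                ph[i, j] = 0
            elif best == diag:
                ph[i, j] = 1
            elif best == F[i, j]:
                ph[i, j] = 2
            else:
                ph[i, j] = 4
    return H, ph, pe, pf


@njit(cache=True)
def _naive_traceback(a, b, sub, go, ge):
    """(score, n_identical, n_columns, query_aligned, subject_aligned)."""
    m, n = a.shape[0], b.shape[0]
    H, ph, pe, pf = _naive_fill(a, b, sub, go, ge)
    best = 0.0
    bi = bj = 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0
    i, j = bi, bj
    ident = cols = qa = sa = 0
    state = 0  # 0 in H, 1 in F (up), 2 in E (left)
    while True:
        if state == 0:
            p = ph[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                qa += 1
                sa += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = pf[i, j]
            cols += 1
            qa += 1
            i -= 1
            state = 0 if p == 2 else 1
        else:
            p = pe[i, j]
            cols += 1
            sa += 1
            j -= 1
            state = 0 if p == 4 else 2
    return best, ident, cols, qa, sa


def all_hits(pa: Proteome, pb: Proteome, p: AlignParams):
    """Every pairwise local alignment (score, ident, cols, q_aln, s_aln)."""
    sub = _substitution_array(p.substitution_matrix)
    codes_a = [encode_protein(r.sequence) for r in pa.records]
    codes_b = [encode_protein(r.sequence) for r in pb.records]
    out = {}
    for i, ca in enumerate(codes_a):
        for j, cb in enumerate(codes_b):
            out[(i, j)] = _naive_traceback(ca, cb, sub, p.gap_open, p.gap_extend)
    return out


def best_hit_map(pa: Proteome, pb: Proteome, p: AlignParams, hits=None):
    """query id -> subject id, literal best-hit rule (score, then lexicographic)."""
    if hits is None:
        hits = all_hits(pa, pb, p)
    n_res = pb.n_residues
    out = {}
    for i, q in enumerate(pa.records):
        scored = [(hits[(i, j)][0], s.id, j) for j, s in enumerate(pb.records)]
        best = max(s for s, _, _ in scored)
        if best <= 0.0 or evalue_from_score(best, len(q), n_res, p) >= p.max_evalue:
            continue
        out[q.id] = min((sid for s, sid, _ in scored if s == best))
    return out


def aai_oracle(pa: Proteome, pb: Proteome, p: AlignParams, min_ident=30.0, min_cover=70.0, max_e=1e-5):
    """Literal RBH-AAI: mean identity over filtered reciprocal best hits.

    ``pa`` must be the canonically first genome (smaller genome id) so the
    recorded identity direction matches the implementation's convention.
    """
    hits_ab = all_hits(pa, pb, p)
    fwd = best_hit_map(pa, pb, p, hits_ab)
    rev = best_hit_map(pb, pa, p, {(j, i): h for (i, j), h in hits_ab.items()})
    idx_a = {r.id: i for i, r in enumerate(pa.records)}
    idx_b = {r.id: j for j, r in enumerate(pb.records)}
    identities = []
    n_res_b = pb.n_residues
    for a_id, b_id in fwd.items():
        if rev.get(b_id) != a_id:
            continue
        score, ident, cols, qa, sa = hits_ab[(idx_a[a_id], idx_b[b_id])]
        la, lb = len(pa.records[idx_a[a_id]]), len(pb.records[idx_b[b_id]])
        shorter = min(la, lb)
        aligned_shorter = qa if la <= lb else sa
        identity = 100.0 * ident / cols
        if (
            identity >= min_ident
            and 100.0 * aligned_shorter / shorter >= min_cover
            and evalue_from_score(score, la, n_res_b, p) < max_e
        ):
            identities.append(identity)
    return (float(np.mean(identities)) if identities else None), len(identities)


def pocp_oracle(pa: Proteome, pb: Proteome, p: AlignParams):
    """Literal POCP: C = queries with ANY hit at E<1e-5, id>40%, >50% alignable."""
    hits_ab = all_hits(pa, pb, p)

    def conserved(qs: Proteome, ss: Proteome, get) -> int:
        n_res = ss.n_residues
        c = 0
        for i, q in enumerate(qs.records):
            for j in range(ss.n_proteins):
                score, ident, cols, qa, sa = get(i, j)
                if score <= 0:
                    continue
                if (
                    evalue_from_score(score, len(q), n_res, p) < 1e-5
                    and 100.0 * ident / cols > 40.0
                    and 100.0 * qa / len(q) > 50.0
                ):
                    c += 1
                    break
        return c

    c1 = conserved(pa, pb, lambda i, j: hits_ab[(i, j)])
    # reverse direction: swap roles; aligned-residue counts swap too
    c2 = conserved(
        pb,
        pa,
        lambda i, j: (
            hits_ab[(j, i)][0],
            hits_ab[(j, i)][1],
            hits_ab[(j, i)][2],
            hits_ab[(j, i)][4],
            hits_ab[(j, i)][3],
        ),
    )
    pocp = 100.0 * (c1 + c2) / (pa.n_proteins + pb.n_proteins)
    return pocp, c1, c2


def nw_oracle(sa: str, sb: str, match: float, mismatch: float, gap: float) -> float:
    """Global alignment score by plain-python DP (score only)."""
    m, n = len(sa), len(sb)
    prev = [gap * j for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [gap * i] + [0.0] * n
        for j in range(1, n + 1):
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[n]
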