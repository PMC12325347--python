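"""AAI and POCP: the quantitative core of genome-based genus delineation.

AAI (average amino acid identity) is the unweighted mean percent identity
over reciprocal-best-hit protein pairs between two proteomes, after
filtering hits by identity, coverage of the shorter protein, and e-value.
POCP (percentage of conserved proteins) is ``100·(C1+C2)/(T1+T2)`` where
``C1`` counts proteins of genome A with at least one hit in genome B at
E < 1e-5, identity > 40% and an alignable region > 50% of the query
length (``C2`` symmetric; ``T`` = proteome sizes).

Both metrics are symmetric under swapping the two genomes: the RBH set is
direction-free, per-pair identities are computed in a canonical genome-id
order, and POCP simply swaps (C1, T1) with (C2, T2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from marinitax.pairwise_align import (
    AlignParams,
    AlignmentHit,
    _concat_codes,
    _substitution_array,
    _sw_score,
    evalue_from_score,
    smith_waterman_protein,
)
from marinitax.seq_io import Proteome


@dataclass(frozen=True)
class AaiParams:
    """Hit filters applied to RBH pairs before averaging identities.

    Coverage is measured on the shorter protein of the pair. Filters are
    inclusive (≥), unlike the strict POCP filters.
    """

    min_identity_pct: float = 30.0
    min_cover_pct: float = 70.0
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity_pct <= 100.0):
            raise ValueError("min_identity_pct must be in [0, 100]")
        if not (0.0 < self.min_cover_pct <= 100.0):
            raise ValueError("min_cover_pct must be in (0, 100]")


#: Literal POCP conservation filters (strict inequalities).
POCP_MAX_EVALUE = 1e-5
POCP_MIN_IDENTITY_PCT = 40.0
POCP_MIN_ALIGNABLE_PCT = 50.0


@dataclass
class PairwiseGenomeMetrics:
    """AAI and POCP evidence for one genome pair."""

    genome_a: str
    genome_b: str
    aai_mean_pct: float | None = None
    aai_min_pct: float | None = None
    aai_max_pct: float | None = None
    aai_n_pairs: int = 0
    pocp_pct: float | None = None
    c1: int = 0
    c2: int = 0
    t1: int = 0
    t2: int = 0

    @property
    def aai_defined(self) -> bool:
        """False when no RBH pair passed the AAI filters."""
        return self.aai_mean_pct is not None


@njit(cache=True)
def _all_scores(buf_a, off_a, buf_b, off_b, sub, gap_open, gap_ext):
    """Raw Smith–Waterman scores for every protein pair (n_a × n_b)."""
    n_a = off_a.shape[0] - 1
    n_b = off_b.shape[0] - 1
    out = np.empty((n_a, n_b), dtype=np.float64)
    for i in range(n_a):
        q = buf_a[off_a[i] : off_a[i + 1]]
        for j in range(n_b):
            out[i, j] = _sw_score(q, buf_b[off_b[j] : off_b[j + 1]], sub, gap_open, gap_ext)
    return out


class _PairSearch:
    """All-vs-all scores between two proteomes with cached tracebacks."""

    def __init__(self, pa: Proteome, pb: Proteome, p: AlignParams):
        self.pa, self.pb, self.p = pa, pb, p
        sub = _substitution_array(p.substitution_matrix)
        buf_a, off_a = _concat_codes(pa)
        buf_b, off_b = _concat_codes(pb)
        self.scores = _all_scores(buf_a, off_a, buf_b, off_b, sub, p.gap_open, p.gap_extend)
        self.n_res_a = pa.n_residues
        self.n_res_b = pb.n_residues
        self._hits: dict[tuple[int, int], AlignmentHit] = {}

    def hit(self, i: int, j: int) -> AlignmentHit:
        """Traceback alignment of pa[i] (query) vs pb[j], cached."""
        key = (i, j)
        if key not in self._hits:
            h = smith_waterman_protein(
                self.pa.records[i], self.pb.records[j], self.p, search_space_n=self.n_res_b
            )
            assert h is not None
            self._hits[key] = h
        return self._hits[key]

    def best_map(self, reverse: bool = False) -> dict[int, int]:
        """Per-query best subject index at E < max_evalue.

        Ties on raw score resolve to the lexicographically smallest subject
        id. ``reverse=True`` searches pb against pa.
        """
        scores = self.scores.T if reverse else self.scores
        queries = self.pb if reverse else self.pa
        subjects = self.pa if reverse else self.pb
        n_res = self.n_res_a if reverse else self.n_res_b
        order = sorted(range(subjects.n_proteins), key=lambda t: subjects.records[t].id)
        out: dict[int, int] = {}
        for qi in range(queries.n_proteins):
            row = scores[qi]
            best = row.max()
            if best <= 0.0:
                continue
            if evalue_from_score(best, len(queries.records[qi]), n_res, self.p) >= self.p.max_evalue:
                continue
            out[qi] = next(t for t in order if row[t] == best)
        return out


def reciprocal_best_hits(
    pa: Proteome,
    pb: Proteome,
    p: AlignParams | None = None,
    _search: _PairSearch | None = None,
) -> list[tuple[AlignmentHit, AlignmentHit]]:
    """Reciprocal best hit pairs between two proteomes.

    A pair (x, y) is reported iff y is x's best hit in ``pb`` and x is y's
    best hit in ``pa`` (both at E < max_evalue). Each protein occurs in at
    most one pair. Returns ``(hit_ab, hit_ba)`` tuples ordered by the
    query id in ``pa``.
    """
    if p is None:
        p = AlignParams()
    s = _search if _search is not None else _PairSearch(pa, pb, p)
    fwd = s.best_map()
    rev = s.best_map(reverse=True)
    pairs: list[tuple[AlignmentHit, AlignmentHit]] = []
    for i in sorted(fwd, key=lambda i: pa.records[i].id):
        j = fwd[i]
        if rev.get(j) == i:
            hit_ab = s.hit(i, j)
            hit_ba = smith_waterman_protein(
                pb.records[j], pa.records[i], p, search_space_n=s.n_res_a
            )
            assert hit_ba is not None
            pairs.append((hit_ab, hit_ba))
    return pairs


def _canonical(pa: Proteome, pb: Proteome) -> tuple[Proteome, Proteome, bool]:
    """Order a pair by genome id so per-pair values are direction-free."""
    if pa.genome_id <= pb.genome_id:
        return pa, pb, False
    return pb, pa, True


def compute_aai(
    pa: Proteome,
    pb: Proteome,
    ap: AlignParams | None = None,
    qp: AaiParams | None = None,
    _search: _PairSearch | None = None,
) -> PairwiseGenomeMetrics:
    """AAI between two proteomes (unweighted mean over filtered RBH pairs).

    When no RBH pair passes the filters the result carries
    ``aai_mean_pct = None`` (``aai_defined`` is False), never 0.
    """
    if ap is None:
        ap = AlignParams()
    if qp is None:
        qp = AaiParams()
    first, second, _ = _canonical(pa, pb)
    s = _search if _search is not None else _PairSearch(first, second, ap)
    identities: list[float] = []
    for hit_ab, _hit_ba in reciprocal_best_hits(first, second, ap, _search=s):
        q_len = len(next(r for r in first.records if r.id == hit_ab.query_id))
        s_len = len(next(r for r in second.records if r.id == hit_ab.subject_id))
        shorter = min(q_len, s_len)
        aligned_shorter = hit_ab.query_aligned if q_len <= s_len else hit_ab.subject_aligned
        cover = 100.0 * aligned_shorter / shorter
        if (
            hit_ab.identity_pct >= qp.min_identity_pct
            and cover >= qp.min_cover_pct
            and hit_ab.evalue < qp.max_evalue
        ):
            identities.append(hit_ab.identity_pct)
    m = PairwiseGenomeMetrics(
        genome_a=pa.genome_id, genome_b=pb.genome_id, t1=pa.n_proteins, t2=pb.n_proteins
    )
    if identities:
        m.aai_mean_pct = float(np.mean(identities))
        m.aai_min_pct = float(min(identities))
        m.aai_max_pct = float(max(identities))
        m.aai_n_pairs = len(identities)
    return m


def _conserved_count(s: _PairSearch, reverse: bool) -> int:
    """Queries with ≥1 hit passing the literal POCP filters.

    Candidate subjects are examined in decreasing score order; the scan
    stops at the first qualifying alignment, so only as many tracebacks are
    done as needed while remaining equivalent to checking every hit.
    """
    scores = s.scores.T if reverse else s.scores
    queries = s.pb if reverse else s.pa
    n_res = s.n_res_a if reverse else s.n_res_b
    count = 0
    for qi in range(queries.n_proteins):
        q_len = len(queries.records[qi])
        row = scores[qi]
        for j in np.argsort(-row, kind="stable"):
            sc = row[j]
            if sc <= 0.0 or evalue_from_score(sc, q_len, n_res, s.p) >= POCP_MAX_EVALUE:
                break
            if reverse:
                h = s.hit(int(j), qi)
                identity, alignable = h.identity_pct, h.subject_aligned
            else:
                h = s.hit(qi, int(j))
                identity, alignable = h.identity_pct, h.query_aligned
            if (
                identity > POCP_MIN_IDENTITY_PCT
                and 100.0 * alignable / q_len > POCP_MIN_ALIGNABLE_PCT
            ):
                count += 1
                break
    return count


def compute_pocp(
    pa: Proteome,
    pb: Proteome,
    ap: AlignParams | None = None,
    _search: _PairSearch | None = None,
) -> PairwiseGenomeMetrics:
    """POCP between two proteomes: ``100·(C1+C2)/(T1+T2)``."""
    if ap is None:
        ap = AlignParams()
    first, second, swapped = _canonical(pa, pb)
    s = _search if _search is not None else _PairSearch(first, second, ap)
    c_first = _conserved_count(s, reverse=False)
    c_second = _conserved_count(s, reverse=True)
    c1, c2 = (c_second, c_first) if swapped else (c_first, c_second)
    m = PairwiseGenomeMetrics(
        genome_a=pa.genome_id,
        genome_b=pb.genome_id,
        c1=c1,
        c2=c2,
        t1=pa.n_proteins,
        t2=pb.n_proteins,
    )
    m.pocp_pct = 100.0 * (c1 + c2) / (m.t1 + m.t2)
    return m


def compute_pair_metrics(
    pa: Proteome,
    pb: Proteome,
    ap: AlignParams | None = None,
    qp: AaiParams | None = None,
) -> PairwiseGenomeMetrics:
    """AAI and POCP for one pair sharing a single all-vs-all score pass."""
    if ap is None:
        ap = AlignParams()
    first, second, _ = _canonical(pa, pb)
    s = _PairSearch(first, second, ap)
    aai = compute_aai(pa, pb, ap, qp, _search=s)
    pocp = compute_pocp(pa, pb, ap, _search=s)
    aai.pocp_pct, aai.c1, aai.c2 = pocp.pocp_pct, pocp.c1, pocp.c2
    return aai


def all_pairs_metrics(
    proteomes: list[Proteome],
    ap: AlignParams | None = None,
    qp: AaiParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Symmetric AAI and POCP matrices plus a long-form pair table.

    Returns ``(aai_matrix, pocp_matrix, long_table)``. Diagonals are 100 by
    definition; an undefined AAI appears as NaN in the matrix.
    """
    if len(proteomes) < 2:
        raise ValueError("all_pairs_metrics requires at least 2 proteomes")
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids in proteome list")
    aai_m = pd.DataFrame(100.0, index=ids, columns=ids)
    pocp_m = pd.DataFrame(100.0, index=ids, columns=ids)
    rows = []
    for i in range(len(proteomes)):
        for j in range(i + 1, len(proteomes)):
            m = compute_pair_metrics(proteomes[i], proteomes[j], ap, qp)
            aai = m.aai_mean_pct if m.aai_defined else np.nan
            aai_m.iloc[i, j] = aai_m.iloc[j, i] = aai
            pocp_m.iloc[i, j] = pocp_m.iloc[j, i] = m.pocp_pct
            rows.append(
                {
                    "genome_a": m.genome_a,
                    "genome_b": m.genome_b,
                    "aai_mean_pct": aai,
                    "aai_n_pairs": m.aai_n_pairs,
                    "pocp_pct": m.pocp_pct,
                    "c1": m.c1,
                    "c2": m.c2,
                    "t1": m.t1,
                    "t2": m.t2,
                }
            )
    return aai_m, pocp_m, pd.DataFrame(rows)
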