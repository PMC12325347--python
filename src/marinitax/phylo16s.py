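"""16S rRNA distances, neighbor-joining trees and bootstrap supports.

Pairwise identity mirrors EzTaxon-style similarity (gap columns excluded
from the denominator). Distance models: p-distance, Jukes–Cantor (JC69,
``d = −(3/4)·ln(1 − 4p/3)``) and Kimura two-parameter (K2P,
``d = −(1/2)·ln((1−2P−Q)·sqrt(1−2Q))`` with transition proportion P and
transversion proportion Q). Trees are built by Saitou–Nei neighbor
joining with deterministic tie-breaking; bootstrap supports count how
often each internal bipartition of the full-data tree recurs among trees
built from column-resampled alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from marinitax.pairwise_align import needleman_wunsch_nucleotide
from marinitax.seq_io import SequenceRecord

_MODELS = ("p_distance", "JC69", "K2P")

# nucleotide codes: A=0, C=1, G=2, T/U=3, anything else (gap, ambiguity) = 4
_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _NT_CODE[ord(_ch)] = _i
_NT_CODE[ord("U")] = 3


class SaturationError(ValueError):
    """A distance is undefined (log of a non-positive argument).

    Raised by :func:`neighbor_joining` when the matrix carries saturated
    pairs; switch to p-distance or remove the offending taxa.
    """


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair saturation flags."""

    ids: list[str]
    data: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        sym = self.data.copy()
        sym[self.saturated] = 0.0  # saturated pairs are flagged pairwise
        if not np.allclose(sym, sym.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.data) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class PhyloParams:
    """Tree-building parameters (MEGA-style defaults)."""

    model: str = "K2P"
    n_bootstrap: int = 1000
    seed: int = 0
    min_show_support: int = 50

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")


# ---------------------------------------------------------------------------
# identity and distances


def pairwise_identity_16s(
    a: SequenceRecord,
    b: SequenceRecord,
    aligned: bool | None = None,
    include_gaps: bool = False,
) -> float:
    """Percent identity of two 16S sequences.

    Unaligned inputs are globally aligned first (Needleman–Wunsch). By
    default identity = 100·matches / columns where both sequences carry a
    base — internal and terminal gap columns are excluded, as EzTaxon-style
    platforms do. ``include_gaps=True`` switches to the BLAST-style
    denominator (all alignment columns).
    """
    if aligned is None:
        aligned = "-" in a.sequence or "-" in b.sequence
    if aligned:
        if len(a.sequence) != len(b.sequence):
            raise ValueError("aligned sequences must have equal length")
        sa, sb = a.sequence, b.sequence
    else:
        aln = needleman_wunsch_nucleotide(a, b)
        sa, sb = aln.aligned_a, aln.aligned_b
    both = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not both:
        raise ValueError(f"no gap-free overlap between {a.id!r} and {b.id!r}")
    matches = sum(1 for x, y in both if x == y)
    denom = len(sa) if include_gaps else len(both)
    return 100.0 * matches / denom


def _encode_alignment(alignment: list[SequenceRecord]) -> np.ndarray:
    lengths = {len(r.sequence) for r in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    return np.vstack(
        [_NT_CODE[np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)] for r in alignment]
    )


def _distances_from_codes(codes: np.ndarray, model: str) -> tuple[np.ndarray, np.ndarray]:
    n = codes.shape[0]
    d = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    is_purine = (codes == 0) | (codes == 2)
    valid = codes < 4
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            m = int(mask.sum())
            if m == 0:
                raise ValueError("a sequence pair has no comparable columns")
            diff = mask & (codes[i] != codes[j])
            p = diff.sum() / m
            if model == "p_distance":
                dij = p
            elif model == "JC69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0.0:
                    saturated[i, j] = saturated[j, i] = True
                    dij = math.inf
                else:
                    dij = -0.75 * math.log(arg)
            else:  # K2P
                ts = (diff & (is_purine[i] == is_purine[j])).sum()
                P = ts / m
                Q = p - P
                arg1 = 1.0 - 2.0 * P - Q
                arg2 = 1.0 - 2.0 * Q
                if arg1 <= 0.0 or arg2 <= 0.0:
                    saturated[i, j] = saturated[j, i] = True
                    dij = math.inf
                else:
                    dij = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
            d[i, j] = d[j, i] = dij
    return d, saturated


def distance_matrix(alignment: list[SequenceRecord], model: str = "K2P") -> DistanceMatrix:
    """Pairwise distances from a gapped multiple alignment.

    ``p`` is the mismatch proportion over pairwise-complete columns (both
    sequences unambiguous bases). Pairs whose model transform is undefined
    are flagged saturated and carry ``inf``.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    if len(alignment) < 3:
        raise ValueError("distance_matrix requires at least 3 taxa")
    codes = _encode_alignment(alignment)
    d, saturated = _distances_from_codes(codes, model)
    return DistanceMatrix(ids=[r.id for r in alignment], data=d, saturated=saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-criterion ties resolve to the smallest (i, j) index pair; negative
    branch lengths are clamped to zero with the deficit moved to the sister
    edge. The returned tree is rooted at the final three-way join (the
    standard unrooted-NJ representation).
    """
    if dm.saturated is not None and dm.saturated.any():
        raise SaturationError(
            "distance matrix carries saturated pairs; use a different model"
        )
    if not np.all(np.isfinite(dm.data)):
        raise ValueError("distance matrix entries must be finite")
    if dm.n_taxa < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.extend([nodes[i], nodes[j]])

        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        new_D = np.zeros((len(keep) + 1, len(keep) + 1))
        new_D[:-1, :-1] = D[np.ix_(keep, keep)]
        new_D[-1, :-1] = new_D[:-1, -1] = du[keep]
        D = new_D
        nodes = [nodes[k] for k in keep] + [parent]

    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (dxy + dxz - dyz),
        0.5 * (dxy + dyz - dxz),
        0.5 * (dxz + dyz - dxy),
    ]
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        node.length = max(0.0, length)
        root.append(node)
    return root


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0.0:
        vj += vi
        vi = 0.0
    if vj < 0.0:
        vi = max(0.0, vi + vj)
        vj = 0.0
    return vi, vj


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (implicitly unrooted) tree.

    Each is normalized as the side not containing the lexicographically
    smallest leaf name, so topologies compare across rootings.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_supports(
    alignment: list[SequenceRecord], pp: PhyloParams | None = None
) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_bootstrap`` times (seeded);
    each internal edge of the full-data tree gets the percentage of
    replicate trees containing the same bipartition, rounded to the nearest
    integer and stored as ``node.support``. Supports below
    ``min_show_support`` are retained but flagged via
    ``node.support_displayed = False`` (the Fig-style >50% display rule).
    Replicates whose resampled distances saturate are skipped and excluded
    from the denominator. With ``n_bootstrap = 0`` the tree carries no
    supports.
    """
    if pp is None:
        pp = PhyloParams()
    codes = _encode_alignment(alignment)
    ids = [r.id for r in alignment]
    d, sat = _distances_from_codes(codes, pp.model)
    tree = neighbor_joining(DistanceMatrix(ids=ids, data=d, saturated=sat))
    if pp.n_bootstrap == 0:
        return tree

    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(tree)}
    rng = np.random.default_rng(pp.seed)
    n_ok = 0
    L = codes.shape[1]
    for _ in range(pp.n_bootstrap):
        cols = rng.integers(0, L, size=L)
        try:
            db, satb = _distances_from_codes(codes[:, cols], pp.model)
            rep = neighbor_joining(DistanceMatrix(ids=ids, data=db, saturated=satb))
        except (SaturationError, ValueError):
            continue
        n_ok += 1
        for b in bipartitions(rep):
            if b in counts:
                counts[b] += 1
    if n_ok == 0:
        raise SaturationError("every bootstrap replicate saturated")

    leaves = frozenset(ids)
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if side in counts:
            node.support = int(round(100.0 * counts[side] / n_ok))
            node.support_displayed = node.support >= pp.min_show_support
    return tree
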