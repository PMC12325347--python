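"""Seeded generators of pipeline inputs with known ground truth.

Three emulations, one per pipeline stage:

* proteome pairs with a controlled ortholog fraction and per-ortholog
  identity (substitution-only mutation, so realized identity is exact by
  construction);
* ordered gene tables with planted marker clusters at controlled
  spacings (separations exceed the chaining gap, so the planted member
  sets are the exact expected detector output);
* nucleotide alignments evolved site-independently on a known tree under
  JC69 or K2P.

All randomness flows through one ``numpy`` generator per call; the same
seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from marinitax.phylo16s import DistanceMatrix
from marinitax.seq_io import GeneFeature, Proteome, SequenceRecord

#: The 20 proteinogenic residues used for background and ortholog sequences.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


# ---------------------------------------------------------------------------
# proteome pairs


@dataclass(frozen=True)
class ProteomePairSpec:
    """Two proteomes sharing ``n_orth`` orthologs at a target identity."""

    n_a: int
    n_b: int
    n_orth: int
    target_identity_pct: float
    length_range: tuple[int, int] = (100, 400)
    seed: int = 0
    genome_a: str = "GA"
    genome_b: str = "GB"

    def __post_init__(self) -> None:
        if self.n_orth > min(self.n_a, self.n_b):
            raise ValueError("n_orth cannot exceed either proteome size")
        if not (0.0 < self.target_identity_pct <= 100.0):
            raise ValueError("target_identity_pct must be in (0, 100]")
        if self.length_range[0] < 10 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")


@dataclass(frozen=True)
class OrthologTruth:
    a_id: str
    b_id: str
    identity_pct: float  # realized, exact by construction


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute ``n_subs`` distinct positions with a different residue."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        alternatives = AA20.replace(chars[pos], "")
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def simulate_proteome_pair(
    spec: ProteomePairSpec,
) -> tuple[Proteome, Proteome, list[OrthologTruth]]:
    """Generate a proteome pair plus the ortholog truth table.

    Each ortholog's realized identity is ``100·(L−k)/L`` with ``k``
    substitutions rounded from the target, hence within ±1 point of the
    target for default lengths. Non-orthologous proteins are i.i.d. over
    the 20 residues.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    rec_a: list[SequenceRecord] = []
    rec_b: list[SequenceRecord] = []
    truth: list[OrthologTruth] = []
    for i in range(spec.n_orth):
        L = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, L)
        k = int(round(L * (1.0 - spec.target_identity_pct / 100.0)))
        a_id = f"{spec.genome_a}_p{i:04d}"
        b_id = f"{spec.genome_b}_p{i:04d}"
        rec_a.append(SequenceRecord(id=a_id, sequence=seq))
        rec_b.append(SequenceRecord(id=b_id, sequence=_mutate(rng, seq, k)))
        truth.append(OrthologTruth(a_id, b_id, 100.0 * (L - k) / L))
    for i in range(spec.n_orth, spec.n_a):
        L = int(rng.integers(lo, hi + 1))
        rec_a.append(SequenceRecord(id=f"{spec.genome_a}_p{i:04d}", sequence=_random_protein(rng, L)))
    for i in range(spec.n_orth, spec.n_b):
        L = int(rng.integers(lo, hi + 1))
        rec_b.append(SequenceRecord(id=f"{spec.genome_b}_p{i:04d}", sequence=_random_protein(rng, L)))
    return (
        Proteome(genome_id=spec.genome_a, records=rec_a),
        Proteome(genome_id=spec.genome_b, records=rec_b),
        truth,
    )


# ---------------------------------------------------------------------------
# gene tables with planted clusters


@dataclass(frozen=True)
class PlantedCluster:
    """One cluster to plant: expected class and (label, offset) members."""

    cluster_class: str  # expected detector class: PUL, PUL_LIKE or CGC
    members: tuple[tuple[str, int], ...]  # (label, ordinal offset from start)

    @property
    def width(self) -> int:
        return max(off for _, off in self.members) + 1


def pul_layout() -> PlantedCluster:
    """Canonical PUL: susC/susD tandem plus a downstream GH."""
    return PlantedCluster("PUL", (("TBDT", 0), ("SUSD", 1), ("GH", 3)))


def pul_like_layout() -> PlantedCluster:
    """susD without its TBDT partner, plus a CAZyme."""
    return PlantedCluster("PUL_LIKE", (("SUSD", 0), ("GH", 2)))


def cgc_layout() -> PlantedCluster:
    """Transporter-free CAZyme/sulfatase cluster."""
    return PlantedCluster("CGC", (("GH", 0), ("SULFATASE", 2), ("CE", 4)))


@dataclass(frozen=True)
class GeneTableSpec:
    n_genes: int
    planted: tuple[PlantedCluster, ...] = ()
    background_marker_rate: float = 0.0
    max_gap: int = 10  # separations are kept strictly above this
    seed: int = 0
    genome_id: str = "G1"
    contig_id: str = "c1"


@dataclass(frozen=True)
class TruthCluster:
    cluster_class: str
    member_ordinals: tuple[int, ...]


def simulate_gene_table(
    spec: GeneTableSpec,
) -> tuple[list[GeneFeature], list[TruthCluster]]:
    """Generate an ordered gene table with planted clusters.

    Planted clusters sit on one contig, separated from each other and from
    any background singleton markers by more than ``max_gap`` genes, so a
    chaining detector with that gap bound must recover exactly the planted
    member sets. Background markers (lone CAZymes at rate
    ``background_marker_rate``) are singletons and thus discarded by any
    detector requiring ≥2 markers.
    """
    rng = np.random.default_rng(spec.seed)
    labels = ["OTHER"] * spec.n_genes
    truth: list[TruthCluster] = []
    marker_positions: list[int] = []

    cursor = int(rng.integers(0, 3))
    for pc in spec.planted:
        start = cursor
        end = start + pc.width - 1
        if end >= spec.n_genes:
            raise ValueError(
                f"n_genes={spec.n_genes} too small to place planted clusters "
                f"with >{spec.max_gap}-gene separations"
            )
        ordinals = []
        for lab, off in pc.members:
            labels[start + off] = lab
            ordinals.append(start + off)
            marker_positions.append(start + off)
        truth.append(TruthCluster(pc.cluster_class, tuple(sorted(ordinals))))
        cursor = end + spec.max_gap + 1 + int(rng.integers(0, 4))

    if spec.background_marker_rate > 0.0:
        candidates = [
            pos
            for pos in range(spec.n_genes)
            if all(abs(pos - mp) > spec.max_gap for mp in marker_positions)
        ]
        for pos in candidates:
            if rng.random() < spec.background_marker_rate and all(
                abs(pos - mp) > spec.max_gap for mp in marker_positions
            ):
                labels[pos] = AA_BACKGROUND_LABELS[rng.integers(0, len(AA_BACKGROUND_LABELS))]
                marker_positions.append(pos)

    strands = rng.integers(0, 2, size=spec.n_genes)
    genes = [
        GeneFeature(
            genome_id=spec.genome_id,
            contig_id=spec.contig_id,
            ordinal=o,
            start=o * 1000 + 1,
            end=o * 1000 + 900,
            strand="+" if strands[o] else "-",
            label=labels[o],
        )
        for o in range(spec.n_genes)
    ]
    return genes, truth


#: Labels used for isolated background markers.
AA_BACKGROUND_LABELS = ("GH", "CE", "SULFATASE", "CBM")


# ---------------------------------------------------------------------------
# alignments evolved on a tree


def _jc69_matrix(t: float) -> np.ndarray:
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _k2p_matrix(t: float, kappa: float) -> np.ndarray:
    # states A=0, C=1, G=2, T=3; transitions A<->G and C<->T
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    for a, b in ((0, 2), (2, 0), (1, 3), (3, 1)):
        P[a, b] = p_ts
    return P


def evolve_alignment(
    tree: TreeNode | str,
    length: int,
    model: str = "JC69",
    kappa: float = 2.0,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Evolve a gap-free alignment down a tree.

    Branch lengths are expected substitutions per site; the root state is
    uniform over {A, C, G, T} and each branch applies the model's
    transition-probability matrix independently per site.
    """
    if isinstance(tree, str):
        import io

        tree = TreeNode.read(io.StringIO(tree))
    if model not in ("JC69", "K2P"):
        raise ValueError("model must be 'JC69' or 'K2P'")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    out: list[SequenceRecord] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            P = _jc69_matrix(t) if model == "JC69" else _k2p_matrix(t, kappa)
            child_seq = np.empty_like(seq)
            for s in range(4):
                idx = np.flatnonzero(seq == s)
                if idx.size:
                    child_seq[idx] = rng.choice(4, size=idx.size, p=P[s])
            if child.is_tip():
                out.append(
                    SequenceRecord(
                        id=str(child.name),
                        sequence="".join(_NT[x] for x in child_seq),
                    )
                )
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return out


# ---------------------------------------------------------------------------
# random trees and additive matrices (oracles for NJ)


def random_tree(
    n_taxa: int,
    seed: int = 0,
    branch_range: tuple[float, float] = (0.02, 0.2),
) -> TreeNode:
    """Random unrooted binary topology with uniform branch lengths.

    Taxa are named t0..t{n-1}; the tree is represented rooted at a final
    trifurcation, matching neighbor joining's output shape.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    lo, hi = branch_range

    def draw() -> float:
        return float(rng.uniform(lo, hi))

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        nodes[i].length = draw()
        nodes[j].length = draw()
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    for node in nodes:
        node.length = draw()
        root.append(node)
    return root


def additive_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree — an exactly additive matrix."""
    skb = tree.tip_tip_distances()
    ids = list(skb.ids)
    return DistanceMatrix(ids=ids, data=np.asarray(skb.data, dtype=float))
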