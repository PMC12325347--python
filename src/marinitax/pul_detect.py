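"""Detection of PULs, PUL-like loci and CAZyme gene clusters (CGCs).

Marker genes are degradative CAZymes (GH, PL, CE, CBM, AA — glycosyl
transferases are explicitly excluded), sulfatases, TonB-dependent
transporters (susC-like TBDTs) and susD-like genes. Markers on one contig
are chained by single linkage whenever their gene ordinals differ by at
most ``max_gap_genes`` (default 10). The seven-gene scan window mentioned
alongside this rule is an implementation detail of scanning and cannot
change cluster membership; the within-ten-genes linkage is the operative
criterion.

Cluster classes follow the susC/susD-tandem convention:

* **PUL** — contains a TBDT and a susD gene at adjacent ordinals (the
  susC/susD tandem) plus at least one degradative CAZyme;
* **PUL_LIKE** — contains a TBDT or susD gene but no such tandem;
* **CGC** — CAZyme/sulfatase cluster without transporter genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from marinitax.seq_io import GeneFeature

#: Degradative CAZyme classes (GT deliberately absent).
DEGRADATIVE_CAZYME_LABELS = frozenset({"GH", "PL", "CE", "CBM", "AA"})
#: All CAZyme classes, for genome-wide annotation totals.
ALL_CAZYME_LABELS = DEGRADATIVE_CAZYME_LABELS | {"GT"}
#: Labels that seed and join clusters.
MARKER_LABELS = DEGRADATIVE_CAZYME_LABELS | {"SULFATASE", "TBDT", "SUSD"}

_COUNT_LABELS = ("GH", "PL", "CE", "CBM", "AA", "SULFATASE", "TBDT", "SUSD")


@dataclass(frozen=True)
class PulParams:
    """Chaining and classification parameters.

    ``max_gap_genes`` is the maximum ordinal distance between two chained
    markers (10 ⇒ up to 9 intervening genes); ``window_genes`` only sizes
    the scan and never affects membership.
    """

    max_gap_genes: int = 10
    window_genes: int = 7
    min_markers: int = 2
    require_cazyme: bool = True

    def __post_init__(self) -> None:
        if self.max_gap_genes < 1 or self.window_genes < 1:
            raise ValueError("max_gap_genes and window_genes must be >= 1")
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")


@dataclass
class GeneCluster:
    """A detected marker-gene cluster on one contig."""

    genome_id: str
    contig_id: str
    member_ordinals: list[int]
    cluster_class: str = "CGC"
    label_counts: dict[str, int] = field(default_factory=dict)
    span: tuple[int, int] = (0, 0)

    @property
    def n_markers(self) -> int:
        return len(self.member_ordinals)


@dataclass(frozen=True)
class GenomeDegradationSummary:
    """Genome-wide polysaccharide-degradation gene content."""

    genome_id: str
    n_cazymes: int  # every CAZyme-labeled gene, GT included
    n_sulfatases: int
    n_puls: int
    n_pul_like: int
    n_cgcs: int


def flag_markers(genes: Sequence[GeneFeature]) -> list[bool]:
    """Marker mask: degradative CAZyme, sulfatase, TBDT or susD.

    GT and OTHER genes are never markers.
    """
    return [g.label in MARKER_LABELS for g in genes]


def chain_clusters(genes: Sequence[GeneFeature], p: PulParams | None = None) -> list[GeneCluster]:
    """Single-linkage chaining of marker genes per contig.

    Two markers join one cluster iff their ordinal distance is
    ``<= max_gap_genes``; clusters never span contigs. Clusters with fewer
    than ``min_markers`` markers — or, when ``require_cazyme``, without any
    degradative CAZyme — are discarded. Returned clusters are unclassified
    (:func:`classify_cluster` assigns the class).
    """
    if p is None:
        p = PulParams()
    by_contig: dict[tuple[str, str], list[GeneFeature]] = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)

    clusters: list[GeneCluster] = []
    for (gid, cid) in sorted(by_contig):
        contig_genes = sorted(by_contig[(gid, cid)], key=lambda g: g.ordinal)
        markers = [g for g, m in zip(contig_genes, flag_markers(contig_genes)) if m]
        run: list[GeneFeature] = []
        for g in markers:
            if run and g.ordinal - run[-1].ordinal > p.max_gap_genes:
                clusters.extend(_emit(gid, cid, run, p))
                run = []
            run.append(g)
        clusters.extend(_emit(gid, cid, run, p))
    return clusters


def _emit(gid: str, cid: str, run: list[GeneFeature], p: PulParams) -> Iterable[GeneCluster]:
    if len(run) < p.min_markers:
        return []
    counts = {lab: sum(1 for g in run if g.label == lab) for lab in _COUNT_LABELS}
    if p.require_cazyme and not any(counts[lab] for lab in DEGRADATIVE_CAZYME_LABELS):
        return []
    return [
        GeneCluster(
            genome_id=gid,
            contig_id=cid,
            member_ordinals=[g.ordinal for g in run],
            label_counts=counts,
            span=(min(g.start for g in run), max(g.end for g in run)),
        )
    ]


def classify_cluster(c: GeneCluster, genes: Sequence[GeneFeature]) -> str:
    """Three-way cluster class: PUL, PUL_LIKE or CGC.

    PUL requires the susC/susD tandem — a TBDT and a susD gene at adjacent
    ordinals — plus a degradative CAZyme; a transporter gene without the
    tandem gives PUL_LIKE; anything else is a CGC.
    """
    by_ordinal = {
        g.ordinal: g.label
        for g in genes
        if g.genome_id == c.genome_id and g.contig_id == c.contig_id
    }
    members = sorted(c.member_ordinals)
    labels = [by_ordinal[o] for o in members]
    has_transporter = any(lab in ("TBDT", "SUSD") for lab in labels)
    has_cazyme = any(lab in DEGRADATIVE_CAZYME_LABELS for lab in labels)
    tandem = any(
        abs(a - b) == 1 and {by_ordinal[a], by_ordinal[b]} == {"TBDT", "SUSD"}
        for a in members
        for b in members
        if a < b
    )
    if tandem and has_cazyme:
        return "PUL"
    if has_transporter:
        return "PUL_LIKE"
    return "CGC"


def detect_clusters(
    genes: Sequence[GeneFeature], p: PulParams | None = None
) -> list[GeneCluster]:
    """Chain markers and classify every retained cluster."""
    clusters = chain_clusters(genes, p)
    for c in clusters:
        c.cluster_class = classify_cluster(c, genes)
    return clusters


def summarize_genome(
    genes: Sequence[GeneFeature], clusters: Sequence[GeneCluster]
) -> GenomeDegradationSummary:
    """Per-genome CAZyme/sulfatase totals and cluster counts by class.

    ``n_cazymes`` counts every CAZyme-labeled gene genome-wide (GT
    included), not only cluster members.
    """
    gids = {g.genome_id for g in genes} | {c.genome_id for c in clusters}
    if len(gids) > 1:
        raise ValueError(f"summarize_genome expects a single genome, got {sorted(gids)}")
    gid = gids.pop() if gids else ""
    by_class = {"PUL": 0, "PUL_LIKE": 0, "CGC": 0}
    for c in clusters:
        by_class[c.cluster_class] += 1
    return GenomeDegradationSummary(
        genome_id=gid,
        n_cazymes=sum(1 for g in genes if g.label in ALL_CAZYME_LABELS),
        n_sulfatases=sum(1 for g in genes if g.label == "SULFATASE"),
        n_puls=by_class["PUL"],
        n_pul_like=by_class["PUL_LIKE"],
        n_cgcs=by_class["CGC"],
    )


# ---------------------------------------------------------------------------
# tabular export


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        row = {
            "genome_id": c.genome_id,
            "contig_id": c.contig_id,
            "cluster_class": c.cluster_class,
            "member_ordinals": ",".join(map(str, c.member_ordinals)),
            "span_start": c.span[0],
            "span_end": c.span[1],
        }
        row.update({f"n_{lab.lower()}": c.label_counts.get(lab, 0) for lab in _COUNT_LABELS})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cluster_table(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def write_summary_table(summaries: Sequence[GenomeDegradationSummary], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(path, sep="\t", index=False)
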