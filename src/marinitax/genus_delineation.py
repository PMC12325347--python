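"""Threshold-based genus delineation from AAI/POCP matrices.

Organisms sharing ≥65% AAI are considered congeneric, with ≥50% POCP as
the corroborating criterion (the gray zone extends to 60%). Genus-level
decisions are made on the mean of inter-genus pairwise values; genera
whose decision is *congeneric* on both metrics are linked, and connected
components of the resulting genus graph become merge proposals — the
logic by which *Ancylomarina* and *Labilibaculum* fold into
*Marinifilum*. Pairs where only one metric passes are "ambiguous": they
never create merge edges but are listed as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenusThresholds:
    """Genus-boundary thresholds (percent)."""

    aai_genus_pct: float = 65.0
    pocp_genus_pct: float = 50.0
    pocp_upper_pct: float = 60.0  # upper edge of the POCP gray zone

    def __post_init__(self) -> None:
        if not (0.0 < self.aai_genus_pct < 100.0):
            raise ValueError("aai_genus_pct must be in (0, 100)")
        if self.pocp_genus_pct > self.pocp_upper_pct:
            raise ValueError("pocp_genus_pct must not exceed pocp_upper_pct")


@dataclass(frozen=True)
class GroupDistributionSummary:
    """Distribution of one metric within or between two genera."""

    genus_x: str
    genus_y: str  # == genus_x for intra-genus summaries
    metric: str  # "AAI" or "POCP"
    mean: float
    min: float
    max: float
    n_pairs: int

    @property
    def intra(self) -> bool:
        return self.genus_x == self.genus_y


@dataclass
class MergeEvidence:
    """Inter-genus means backing one proposed merge component."""

    genera: frozenset[str]
    pair_means: dict[tuple[str, str], tuple[float, float]]  # (AAI, POCP) per genus pair
    pair_decision: dict[tuple[str, str], str]


@dataclass
class ReclassificationReport:
    summaries: list[GroupDistributionSummary]
    merge_components: list[frozenset[str]]
    evidence: list[MergeEvidence]
    target_names: dict[frozenset[str], str] = field(default_factory=dict)


def _check_labels(matrix: pd.DataFrame, genus_labels: dict[str, str]) -> None:
    unlabeled = [g for g in matrix.index if g not in genus_labels]
    if unlabeled:
        raise ValueError(f"genome(s) without a genus label: {unlabeled}")


def _pair_values(
    matrix: pd.DataFrame, members_x: list[str], members_y: list[str], intra: bool
) -> np.ndarray:
    if intra:
        vals = [
            matrix.loc[a, b]
            for i, a in enumerate(members_x)
            for b in members_x[i + 1 :]
        ]
    else:
        vals = [matrix.loc[a, b] for a in members_x for b in members_y]
    return np.asarray(vals, dtype=float)


def summarize_groups(
    matrix_aai: pd.DataFrame,
    matrix_pocp: pd.DataFrame,
    genus_labels: dict[str, str],
) -> list[GroupDistributionSummary]:
    """Mean/min/max of each metric per genus and per genus pair.

    Intra-genus summaries exclude the diagonal; genus pairs without any
    genome pair (two singleton-free cases) are omitted.
    """
    out: list[GroupDistributionSummary] = []
    for metric, matrix in (("AAI", matrix_aai), ("POCP", matrix_pocp)):
        _check_labels(matrix, genus_labels)
        genera = sorted({genus_labels[g] for g in matrix.index})
        members = {
            gen: [g for g in matrix.index if genus_labels[g] == gen] for gen in genera
        }
        for i, gx in enumerate(genera):
            for gy in genera[i:]:
                vals = _pair_values(matrix, members[gx], members[gy], intra=gx == gy)
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    continue
                out.append(
                    GroupDistributionSummary(
                        genus_x=gx,
                        genus_y=gy,
                        metric=metric,
                        mean=float(vals.mean()),
                        min=float(vals.min()),
                        max=float(vals.max()),
                        n_pairs=int(vals.size),
                    )
                )
    return out


def classify_pair(
    aai_mean: float, pocp: float, t: GenusThresholds | None = None
) -> str:
    """Genus-level decision for a pair of taxa or genus means.

    ``congeneric`` iff both metrics reach their thresholds (inclusive),
    ``distinct`` iff both fall below, else ``ambiguous`` (the metrics
    disagree).
    """
    if t is None:
        t = GenusThresholds()
    for v in (aai_mean, pocp):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"metric value {v} outside [0, 100]")
    aai_ok = aai_mean >= t.aai_genus_pct
    pocp_ok = pocp >= t.pocp_genus_pct
    if aai_ok and pocp_ok:
        return "congeneric"
    if not aai_ok and not pocp_ok:
        return "distinct"
    return "ambiguous"


def propose_merges(
    matrix_aai: pd.DataFrame,
    matrix_pocp: pd.DataFrame,
    genus_labels: dict[str, str],
    t: GenusThresholds | None = None,
    name_priority: list[str] | None = None,
) -> ReclassificationReport:
    """Merge proposals from inter-genus mean AAI/POCP.

    Genera are linked when :func:`classify_pair` on their inter-genus means
    returns ``congeneric``; connected components of size ≥ 2 become merge
    proposals (single linkage — congeneric-ness is treated as transitive).
    The proposed name of each component is its highest-priority member
    (first listed in ``name_priority``, else lexicographically smallest).
    """
    if t is None:
        t = GenusThresholds()
    summaries = summarize_groups(matrix_aai, matrix_pocp, genus_labels)
    inter = {
        (s.genus_x, s.genus_y): {}
        for s in summaries
        if not s.intra
    }
    for s in summaries:
        if not s.intra:
            inter[(s.genus_x, s.genus_y)][s.metric] = s.mean

    genera = sorted({genus_labels[g] for g in matrix_aai.index})
    graph = nx.Graph()
    graph.add_nodes_from(genera)
    pair_means: dict[tuple[str, str], tuple[float, float]] = {}
    pair_decision: dict[tuple[str, str], str] = {}
    for (gx, gy), metrics in inter.items():
        if "AAI" not in metrics or "POCP" not in metrics:
            continue
        decision = classify_pair(metrics["AAI"], metrics["POCP"], t)
        pair_means[(gx, gy)] = (metrics["AAI"], metrics["POCP"])
        pair_decision[(gx, gy)] = decision
        if decision == "congeneric":
            graph.add_edge(gx, gy)

    components = [
        frozenset(c) for c in nx.connected_components(graph) if len(c) >= 2
    ]
    components.sort(key=lambda c: min(c))
    evidence = [
        MergeEvidence(
            genera=comp,
            pair_means={
                k: v for k, v in pair_means.items() if k[0] in comp and k[1] in comp
            },
            pair_decision={
                k: v for k, v in pair_decision.items() if k[0] in comp and k[1] in comp
            },
        )
        for comp in components
    ]
    priority = name_priority or []
    target_names = {}
    for comp in components:
        named = [g for g in priority if g in comp]
        target_names[comp] = named[0] if named else min(comp)
    return ReclassificationReport(
        summaries=summaries,
        merge_components=components,
        evidence=evidence,
        target_names=target_names,
    )


# ---------------------------------------------------------------------------
# report export


def summaries_to_frame(summaries: list[GroupDistributionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def write_report(
    report: ReclassificationReport, tsv_path: str | Path, text_path: str | Path
) -> None:
    """Emit the TSV summary table and a human-readable merge report."""
    summaries_to_frame(report.summaries).to_csv(tsv_path, sep="\t", index=False)
    lines = ["Genus delineation report", "=" * 24, ""]
    if not report.merge_components:
        lines.append("No merges proposed: all inter-genus means fall below threshold.")
    for comp in report.merge_components:
        name = report.target_names[comp]
        lines.append(f"Proposed merge: {', '.join(sorted(comp))} -> {name}")
        ev = next(e for e in report.evidence if e.genera == comp)
        for (gx, gy), (aai, pocp) in sorted(ev.pair_means.items()):
            lines.append(
                f"  {gx} vs {gy}: mean AAI {aai:.2f}%, mean POCP {pocp:.2f}% "
                f"({ev.pair_decision[(gx, gy)]})"
            )
        lines.append("")
    Path(text_path).write_text("\n".join(lines) + "\n")


def plot_distributions(
    summaries: list[GroupDistributionSummary],
    t: GenusThresholds,
    path: str | Path,
) -> None:
    """Scatter of group means (range bars) with threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=False)
    for ax, metric, thr in (
        (axes[0], "AAI", t.aai_genus_pct),
        (axes[1], "POCP", t.pocp_genus_pct),
    ):
        subset = [s for s in summaries if s.metric == metric]
        labels = [f"{s.genus_x}|{s.genus_y}" if not s.intra else s.genus_x for s in subset]
        x = np.arange(len(subset))
        means = [s.mean for s in subset]
        err_low = [s.mean - s.min for s in subset]
        err_high = [s.max - s.mean for s in subset]
        ax.errorbar(x, means, yerr=[err_low, err_high], fmt="o", capsize=3)
        ax.axhline(thr, color="red", linestyle="--", linewidth=1)
        if metric == "POCP":
            ax.axhline(t.pocp_upper_pct, color="orange", linestyle=":", linewidth=1)
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_ylabel(f"{metric} (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
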