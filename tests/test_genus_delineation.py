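import itertools

import numpy as np
import pandas as pd
import pytest

from marinitax.genus_delineation import (
    GenusThresholds,
    classify_pair,
    propose_merges,
    summarize_groups,
    write_report,
)


def block_matrix(genera_sizes, intra, inter, seed=0, jitter=0.0):
    """Symmetric matrix with block structure; returns (df, labels)."""
    rng = np.random.default_rng(seed)
    ids, labels = [], {}
    for genus, size in genera_sizes.items():
        for k in range(size):
            gid = f"{genus}_{k}"
            ids.append(gid)
            labels[gid] = genus
    n = len(ids)
    m = np.full((n, n), 0.0)
    for i, j in itertools.combinations(range(n), 2):
        same = labels[ids[i]] == labels[ids[j]]
        base = intra if same else inter
        v = base + (rng.normal(0, jitter) if jitter else 0.0)
        m[i, j] = m[j, i] = v
    np.fill_diagonal(m, 100.0)
    return pd.DataFrame(m, index=ids, columns=ids), labels


class TestSummarizeGroups:
    def test_two_singleton_genera_give_only_inter_summaries(self):
        aai, labels = block_matrix({"X": 1, "Y": 1}, intra=80, inter=60)
        pocp, _ = block_matrix({"X": 1, "Y": 1}, intra=75, inter=40)
        summaries = summarize_groups(aai, pocp, labels)
        assert len(summaries) == 2
        assert all(not s.intra for s in summaries)

    def test_single_genus_intra_over_all_pairs(self):
        aai, labels = block_matrix({"X": 3}, intra=85, inter=0)
        summaries = summarize_groups(aai, aai, labels)
        intra = [s for s in summaries if s.metric == "AAI"]
        assert len(intra) == 1
        assert intra[0].n_pairs == 3
        assert intra[0].mean == pytest.approx(85.0)

    def test_means_match_flat_enumeration(self):
        aai, labels = block_matrix({"X": 3, "Y": 3}, intra=80, inter=55, jitter=2.0, seed=5)
        summaries = summarize_groups(aai, aai, labels)
        inter = next(s for s in summaries if s.metric == "AAI" and not s.intra)
        xs = [g for g in aai.index if labels[g] == "X"]
        ys = [g for g in aai.index if labels[g] == "Y"]
        values = [aai.loc[a, b] for a in xs for b in ys]
        assert inter.n_pairs == 9
        assert inter.mean == pytest.approx(np.mean(values))
        assert inter.min == pytest.approx(np.min(values))
        assert inter.max == pytest.approx(np.max(values))

    def test_unlabeled_genome_named_in_error(self):
        aai, labels = block_matrix({"X": 2}, intra=80, inter=0)
        del labels["X_1"]
        with pytest.raises(ValueError, match="X_1"):
            summarize_groups(aai, aai, labels)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "aai,pocp,expected",
        [
            (72.0, 62.2, "congeneric"),   # Ancylomarina–Marinifilum means
            (75.4, 64.8, "congeneric"),   # Labilibaculum–Marinifilum means
            (60.2, 38.1, "distinct"),     # overall between-genus averages
            (65.0, 50.0, "congeneric"),   # inclusive boundary
            (64.9, 50.0, "ambiguous"),
            (70.0, 30.0, "ambiguous"),
        ],
    )
    def test_threshold_logic(self, aai, pocp, expected):
        assert classify_pair(aai, pocp) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(101.0, 50.0)


class TestProposeMerges:
    def test_all_congeneric_genera_form_one_component(self):
        aai, labels = block_matrix({"A": 2, "B": 2, "C": 2}, intra=85, inter=72)
        pocp, _ = block_matrix({"A": 2, "B": 2, "C": 2}, intra=80, inter=62)
        report = propose_merges(aai, pocp, labels)
        assert report.merge_components == [frozenset({"A", "B", "C"})]

    def test_chain_does_not_bridge_distinct_pairs(self):
        # A-B congeneric; B-C and A-C distinct
        ids = ["A_0", "B_0", "C_0"]
        labels = {g: g[0] for g in ids}

        def mat(ab, ac, bc):
            m = pd.DataFrame(100.0, index=ids, columns=ids)
            m.loc["A_0", "B_0"] = m.loc["B_0", "A_0"] = ab
            m.loc["A_0", "C_0"] = m.loc["C_0", "A_0"] = ac
            m.loc["B_0", "C_0"] = m.loc["C_0", "B_0"] = bc
            return m

        report = propose_merges(mat(72, 55, 55), mat(62, 30, 30), labels)
        assert report.merge_components == [frozenset({"A", "B"})]

    def test_single_genus_yields_no_merges(self):
        aai, labels = block_matrix({"X": 3}, intra=85, inter=0)
        report = propose_merges(aai, aai, labels)
        assert report.merge_components == []

    def test_all_below_threshold_yields_no_merges(self):
        aai, labels = block_matrix({"A": 2, "B": 2}, intra=85, inter=55)
        pocp, _ = block_matrix({"A": 2, "B": 2}, intra=80, inter=35)
        assert propose_merges(aai, pocp, labels).merge_components == []

    def test_ambiguous_pair_listed_but_never_merged(self):
        aai, labels = block_matrix({"A": 2, "B": 2}, intra=85, inter=72)
        pocp, _ = block_matrix({"A": 2, "B": 2}, intra=80, inter=35)  # POCP fails
        report = propose_merges(aai, pocp, labels)
        assert report.merge_components == []
        # the disagreement is still recorded pairwise in the summaries
        inter = [s for s in report.summaries if not s.intra]
        assert len(inter) == 2

    def test_name_priority_controls_target_name(self):
        aai, labels = block_matrix({"A": 2, "B": 2}, intra=85, inter=72)
        pocp, _ = block_matrix({"A": 2, "B": 2}, intra=80, inter=62)
        report = propose_merges(aai, pocp, labels, name_priority=["B"])
        assert report.target_names[frozenset({"A", "B"})] == "B"
        report2 = propose_merges(aai, pocp, labels)
        assert report2.target_names[frozenset({"A", "B"})] == "A"

    def test_invariant_to_genome_order(self):
        aai, labels = block_matrix({"A": 2, "B": 2, "C": 2}, intra=85, inter=72, jitter=1.5, seed=8)
        pocp, _ = block_matrix({"A": 2, "B": 2, "C": 2}, intra=80, inter=62, jitter=1.5, seed=9)
        perm = list(reversed(aai.index))
        r1 = propose_merges(aai, pocp, labels)
        r2 = propose_merges(aai.loc[perm, perm], pocp.loc[perm, perm], labels)
        assert r1.merge_components == r2.merge_components

    def test_known_block_structure_recovered(self):
        rng = np.random.default_rng(0)
        for rep in range(25):
            sizes = {"A": 3, "B": 2, "C": 3}
            ids, labels = [], {}
            for genus, size in sizes.items():
                for k in range(size):
                    gid = f"{genus}{k}"
                    ids.append(gid)
                    labels[gid] = genus
            # blocks: A+B are one true genus (intra-block ~N(80,2)), C apart (~N(55,2))
            n = len(ids)
            aai = np.zeros((n, n))
            pocp = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                same_block = (labels[ids[i]] in "AB") == (labels[ids[j]] in "AB")
                a = rng.normal(80 if same_block else 55, 2)
                q = rng.normal(70 if same_block else 38, 2)
                aai[i, j] = aai[j, i] = a
                pocp[i, j] = pocp[j, i] = q
            np.fill_diagonal(aai, 100.0)
            np.fill_diagonal(pocp, 100.0)
            report = propose_merges(
                pd.DataFrame(aai, index=ids, columns=ids),
                pd.DataFrame(pocp, index=ids, columns=ids),
                labels,
            )
            assert report.merge_components == [frozenset({"A", "B"})], f"rep {rep}"

    def test_report_files_written(self, tmp_path):
        aai, labels = block_matrix({"A": 2, "B": 2}, intra=85, inter=72)
        pocp, _ = block_matrix({"A": 2, "B": 2}, intra=80, inter=62)
        report = propose_merges(aai, pocp, labels)
        write_report(report, tmp_path / "s.tsv", tmp_path / "r.txt")
        text = (tmp_path / "r.txt").read_text()
        assert "Proposed merge: A, B -> A" in text
        assert (tmp_path / "s.tsv").read_text().startswith("genus_x\t")


def test_threshold_invariants():
    with pytest.raises(ValueError):
        GenusThresholds(pocp_genus_pct=70, pocp_upper_pct=60)
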