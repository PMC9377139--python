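"""Prophage splitting, presence/induction calling, group tests, subsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phindex import induction as ind
from phindex import synthetic as syn
from phindex.errors import FormatError, IntervalError, UndefinedStatisticError


def _genome(contig_lengths, regions=()):
    contigs = tuple(
        syn.Contig(f"g_c{i}", ln) for i, ln in enumerate(contig_lengths)
    )
    return syn.GenomeRecord("g", "prokaryote", contigs, tuple(regions))


class TestSplitProphage:
    def test_whole_contig_becomes_viral_part(self):
        g = _genome([100_000, 40_000], [("g_c1", 0, 40_000)])
        s = ind.split_prophage(g)
        assert s.virus_contigs == ("g_c1",)
        assert s.host_contigs == ("g_c0",)
        assert s.virus_length == 40_000
        assert s.host_length == 100_000

    def test_half_open_interval_arithmetic(self):
        g = _genome([10_000], [("g_c0", 100, 600)])
        s = ind.split_prophage(g)
        assert s.virus_length == 500
        assert s.host_length == 9_500

    def test_empty_interval_list_is_an_error(self):
        with pytest.raises(IntervalError):
            ind.split_prophage(_genome([10_000]))

    @pytest.mark.parametrize(
        "regions",
        [
            [("g_c0", 0, 20_000)],            # past contig end
            [("g_c0", 500, 500)],             # empty interval
            [("g_c0", 0, 400), ("g_c0", 300, 600)],  # overlap
            [("nope", 0, 100)],               # unknown contig
        ],
    )
    def test_bad_intervals_rejected(self, regions):
        with pytest.raises(IntervalError):
            ind.split_prophage(_genome([10_000]), regions)

    @given(
        st.lists(st.integers(1_000, 100_000), min_size=1, max_size=5),
        st.integers(0, 4),
        st.data(),
    )
    def test_length_conservation(self, contig_lengths, region_contig, data):
        region_contig = region_contig % len(contig_lengths)
        ln = contig_lengths[region_contig]
        start = data.draw(st.integers(0, ln - 1))
        end = data.draw(st.integers(start + 1, ln))
        g = _genome(contig_lengths, [(f"g_c{region_contig}", start, end)])
        s = ind.split_prophage(g)
        assert s.host_length + s.virus_length == sum(contig_lengths)
        assert s.virus_length == end - start


class TestCoverageAndCalls:
    def test_mean_is_unweighted(self):
        assert ind.genome_coverage([2, 4]) == 3.0
        assert ind.genome_coverage([0.7]) == 0.7
        # a length-weighted mean of (10x over 1kb, 1x over 99kb) would be
        # near 1; the per-contig mean must be 5.5
        assert ind.genome_coverage([10.0, 1.0]) == 5.5

    def test_empty_coverage_list_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ind.genome_coverage([])

    @pytest.mark.parametrize(
        "host, virus, expected",
        [
            (0.5, 0.005, "host_only"),
            (0.005, 0.5, "virus_only"),
            (0.0, 0.0, "neither"),
            (0.01, 0.01, "both"),  # threshold itself counts as present
            (0.5, 0.5, "both"),
        ],
    )
    def test_presence_classes(self, host, virus, expected):
        assert ind.classify_presence(host, virus) == expected

    def test_negative_coverage_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ind.classify_presence(-0.1, 0.5)

    def test_printed_archaeal_example_is_induced(self):
        induced, ratio = ind.call_induction(host_coverage=0.05, virus_coverage=37.0)
        assert induced
        assert ratio == pytest.approx(740.0)

    def test_cutoff_is_strict(self):
        induced, ratio = ind.call_induction(1.0, 10.0)
        assert ratio == 10.0 and not induced

    def test_lysogenic_ratio_one_not_induced(self):
        induced, ratio = ind.call_induction(2.0, 2.0)
        assert ratio == 1.0 and not induced


class TestInductionTable:
    def _records(self):
        cov = pd.DataFrame(
            {
                "sample": ["s1"] * 4,
                "contig": ["a_host", "a_pro", "b_host", "b_pro"],
                "coverage": [1.0, 50.0, 1.0, 1.2],
            }
        )
        splits = [
            ind.SplitGenome("a", ("a_host",), ("a_pro",), (("a_pro", 0, 1),), 10, 1),
            ind.SplitGenome("b", ("b_host",), ("b_pro",), (("b_pro", 0, 1),), 10, 1),
        ]
        return ind.induction_table(cov, splits)

    def test_detects_only_the_elevated_prophage(self):
        rec = self._records().set_index("mag")
        assert bool(rec.loc["a", "induced"]) and not bool(rec.loc["b", "induced"])
        assert rec.loc["a", "ratio"] == pytest.approx(50.0)

    def test_virus_only_is_flagged_not_called(self):
        cov = pd.DataFrame(
            {"sample": ["s1"] * 2, "contig": ["a_host", "a_pro"], "coverage": [0.001, 5.0]}
        )
        splits = [
            ind.SplitGenome("a", ("a_host",), ("a_pro",), (("a_pro", 0, 1),), 10, 1)
        ]
        rec = ind.induction_table(cov, splits)
        assert rec.presence.iloc[0] == "virus_only"
        assert not rec.induced.iloc[0]


class TestCooccurrence:
    def test_printed_counts_give_printed_percentages(self):
        # 7,872 evaluations: 2,722 host-only, 22 virus-only, 1,221 neither
        presence = (
            ["host_only"] * 2_722
            + ["virus_only"] * 22
            + ["neither"] * 1_221
            + ["both"] * (7_872 - 2_722 - 22 - 1_221)
        )
        records = pd.DataFrame({"presence": presence})
        summary = ind.cooccurrence_summary(records).set_index("presence")
        assert summary.loc["host_only", "percent"] == 34.6
        assert summary.loc["virus_only", "percent"] == 0.3
        assert summary.loc["neither", "percent"] == 15.5

    def test_all_both_gives_hundred_percent(self):
        records = pd.DataFrame({"presence": ["both"] * 10})
        summary = ind.cooccurrence_summary(records).set_index("presence")
        assert summary.loc["both", "percent"] == 100.0
        assert summary.drop("both")["percent"].sum() == 0.0

    @given(st.lists(st.sampled_from(ind.PRESENCE_CLASSES), min_size=1, max_size=300))
    def test_percentages_sum_to_hundred(self, presence):
        summary = ind.cooccurrence_summary(pd.DataFrame({"presence": presence}))
        assert summary["count"].sum() == len(presence)
        # each of the four classes is rounded to 1 d.p., so the sum can
        # deviate from 100 by at most 4 x 0.05
        assert summary["percent"].sum() == pytest.approx(100.0, abs=0.2 + 1e-9)


def _mannwhitney_exact_oracle(a, b):
    """Two-sided p by exhaustive enumeration of group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    obs = u_stat(a, b)
    mu = len(a) * len(b) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= abs(obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestGroupTest:
    def _frame(self, a_vals, b_vals):
        cols = [f"A{i}" for i in range(len(a_vals))] + [
            f"B{i}" for i in range(len(b_vals))
        ]
        groups = {c: c[0] for c in cols}
        cov = pd.DataFrame([list(a_vals) + list(b_vals)], index=["p1"], columns=cols)
        return cov, groups

    def test_identical_groups_not_flagged(self):
        cov, groups = self._frame([1, 2, 3], [1, 2, 3])
        res = ind.group_abundance_test(cov, groups, "A", "B")
        assert res.p.iloc[0] == 1.0
        assert res.direction.iloc[0] == ""

    def test_exact_p_matches_enumeration_at_3v3(self):
        cov, groups = self._frame([1, 2, 3], [10, 11, 12])
        res = ind.group_abundance_test(cov, groups, "A", "B")
        assert res.p.iloc[0] == pytest.approx(0.1)
        assert res.p.iloc[0] == pytest.approx(
            _mannwhitney_exact_oracle([1, 2, 3], [10, 11, 12])
        )
        assert res.direction.iloc[0] == ""  # 0.1 is not below alpha

    def test_enumeration_oracle_agreement_on_random_small_groups(self):
        rng = np.random.default_rng(0)
        done = 0
        while done < 10:
            a = rng.normal(size=4).round(2)
            b = (rng.normal(size=4) + rng.choice([0, 2])).round(2)
            if len(set(a) | set(b)) < 8:
                continue  # scipy's exact method requires untied data
            done += 1
            cov, groups = self._frame(a, b)
            res = ind.group_abundance_test(cov, groups, "A", "B")
            assert res.p.iloc[0] == pytest.approx(
                _mannwhitney_exact_oracle(list(a), list(b)), abs=1e-9
            )

    def test_planted_direction_summary(self):
        # 64 proviruses: 54 clearly higher in A, 4 higher in B, 6 identical
        rows, index = [], []
        for i in range(64):
            if i < 54:
                rows.append([10, 11, 12, 13, 1, 2, 3, 4])
            elif i < 58:
                rows.append([1, 2, 3, 4, 10, 11, 12, 13])
            else:
                rows.append([5, 5, 5, 5, 5, 5, 5, 5])
            index.append(f"p{i:02d}")
        cols = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        cov = pd.DataFrame(rows, index=index, columns=cols)
        groups = {c: c[0] for c in cols}
        res = ind.group_abundance_test(cov, groups, "A", "B")
        summary = ind.group_test_summary(res, "A", "B")
        assert summary["higher_in_A"] == 54
        assert summary["higher_in_A_percent"] == 84
        assert summary["higher_in_B"] == 4
        assert summary["not_significant"] == 6

    def test_empty_group_rejected(self):
        cov = pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["A0", "A1"])
        with pytest.raises(UndefinedStatisticError):
            ind.group_abundance_test(cov, {"A0": "A", "A1": "A"}, "A", "B")


class TestRatioProfiles:
    def test_identical_profiles_merge_at_zero(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"]
        )
        res = ind.cluster_ratio_profiles(profiles)
        assert res.linkage[0, 2] == 0.0

    def test_induced_group_separates(self):
        rng = np.random.default_rng(2)
        induced = np.log2(50 + rng.uniform(0, 5, size=(5, 4)))
        silent = np.log2(1 + rng.uniform(0, 0.1, size=(5, 4)))
        profiles = pd.DataFrame(
            np.vstack([induced, silent]), index=[f"m{i}" for i in range(10)]
        )
        res = ind.cluster_ratio_profiles(profiles, k=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]


def _write_fastq(path, n, prefix="r"):
    recs = [
        (f"{prefix}{i}", "ACGT" * 5, "I" * 20) for i in range(n)
    ]
    ind.write_fastq(recs, path)
    return recs


class TestSubsampleReads:
    def test_small_file_returned_whole(self, tmp_path):
        f = tmp_path / "in.fastq"
        recs = _write_fastq(f, 50)
        out = ind.subsample_reads(f, n=1_000, seed=0)
        assert sorted(out) == sorted(recs)

    def test_same_seed_same_subset(self, tmp_path):
        f = tmp_path / "in.fastq"
        _write_fastq(f, 500)
        s1 = ind.subsample_reads(f, n=50, seed=7)
        s2 = ind.subsample_reads(f, n=50, seed=7)
        assert s1 == s2
        assert len(s1) == 50

    def test_paired_files_sampled_in_lockstep(self, tmp_path):
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(f1, 300, prefix="x")
        _write_fastq(f2, 300, prefix="x")
        r1, r2 = ind.subsample_reads(f1, n=40, seed=3, mate=f2)
        assert [t for t, _, _ in r1] == [t for t, _, _ in r2]

    def test_unequal_pair_lengths_rejected(self, tmp_path):
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        _write_fastq(f1, 10)
        _write_fastq(f2, 11)
        with pytest.raises(FormatError):
            ind.subsample_reads(f1, n=5, seed=0, mate=f2)

    def test_malformed_record_reports_index(self, tmp_path):
        f = tmp_path / "bad.fastq"
        f.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\nIII\n")
        with pytest.raises(FormatError, match="index 1"):
            list(ind.subsample_reads(f, n=10, seed=0))

    def test_sampling_is_uniform(self, tmp_path):
        # keep-probability 0.1 per read; over 200 seeds each read's empirical
        # frequency stays within 4 sigma of 0.1 and the average is exact
        f = tmp_path / "in.fastq"
        _write_fastq(f, 1_000)
        hits = np.zeros(1_000)
        n_seeds = 200
        for s in range(n_seeds):
            for title, _, _ in ind.subsample_reads(f, n=100, seed=s):
                hits[int(title[1:])] += 1
        freq = hits / n_seeds
        assert freq.mean() == pytest.approx(0.1, abs=1e-12)
        sigma = np.sqrt(0.1 * 0.9 / n_seeds)
        assert np.abs(freq - 0.1).max() < 4 * sigma
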