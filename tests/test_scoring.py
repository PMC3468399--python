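import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protpair as pp
from protpair.errors import (
    DegenerateSpreadError,
    InsufficientSamplesError,
    NoScorablePairsError,
)

from conftest import make_random_cohort


def brute_force_scan(table, annot, ratio_scale="log", sd_mode="sample"):
    """Literal double-loop reference: one pair at a time, plain numpy."""
    peptides = table.peptide_ids
    rows = []
    for i in range(len(peptides)):
        for j in range(i + 1, len(peptides)):
            try:
                rs = pp.compute_ratios(table, annot, peptides[i], peptides[j])
                d = pp.discriminability_index(rs, sd_mode, ratio_scale)
            except (InsufficientSamplesError, DegenerateSpreadError):
                continue
            rows.append((peptides[i], peptides[j], d,
                         len(rs.ratios_C), len(rs.ratios_P)))
    return rows


def brute_force_aggregate(scores, pmap):
    """Dict-based reference for protein-pair medians."""
    groups = {}
    for row in scores.itertuples():
        p1 = pmap.protein_of(row.peptide_i)
        p2 = pmap.protein_of(row.peptide_j)
        if p1 == p2:
            continue
        key = tuple(sorted((p1, p2)))
        d = row.d if p1 == key[0] else -row.d
        groups.setdefault(key, []).append(d)
    return {k: float(np.median(v)) for k, v in groups.items()}


class TestPairCount:
    @pytest.mark.parametrize(
        "n,expected",
        [(1760, 1_547_920), (112, 6_216), (2, 1), (1, 0), (0, 0)],
    )
    def test_values(self, n, expected):
        assert pp.pair_count(n) == expected

    def test_matches_enumeration_length(self):
        for n in range(0, 201, 17):
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            assert pp.pair_count(n) == len(pairs)


ratio_vectors = st.lists(
    st.floats(min_value=1e-6, max_value=1e6, allow_nan=False), min_size=2, max_size=12
)


class TestDiscriminabilityProperties:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(n=st.integers(min_value=1, max_value=500))
    def test_pair_count_recurrence(self, n):
        assert pp.pair_count(n) == pp.pair_count(n - 1) + (n - 1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(rc=ratio_vectors, rp=ratio_vectors)
    def test_class_swap_negates_index(self, rc, rp):
        fwd = pp.RatioSet("i", "j", np.array(rc), np.array(rp))
        rev = pp.RatioSet("i", "j", np.array(rp), np.array(rc))
        try:
            d = pp.discriminability_index(fwd)
        except DegenerateSpreadError:
            with pytest.raises(DegenerateSpreadError):
                pp.discriminability_index(rev)
            return
        assert pp.discriminability_index(rev) == -d

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(rc=ratio_vectors, rp=ratio_vectors,
           scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_log_mode_invariant_to_common_ratio_scaling(self, rc, rp, scale):
        base = pp.RatioSet("i", "j", np.array(rc), np.array(rp))
        scaled = pp.RatioSet("i", "j", scale * np.array(rc), scale * np.array(rp))
        try:
            d = pp.discriminability_index(base, ratio_scale="log")
        except DegenerateSpreadError:
            return
        d_scaled = pp.discriminability_index(scaled, ratio_scale="log")
        assert d_scaled == pytest.approx(d, rel=1e-6, abs=1e-9)


class TestComputeRatios:
    def test_direct_division(self, toy_annotation):
        table = pp.IntensityTable(
            pd.DataFrame(
                [[10.0, 20, 8, 6, 1, 2, 3, 4], [5.0, 4, 2, 3, 1, 1, 1, 1]],
                index=["pi", "pj"],
                columns=toy_annotation.sample_ids,
            )
        )
        rs = pp.compute_ratios(table, toy_annotation, "pi", "pj")
        assert rs.ratios_C.tolist() == [2.0, 5.0, 4.0, 2.0]
        assert rs.ratios_P.tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_nonpositive_sample_omitted_matches_deletion(self, toy_annotation):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.normal(5, 1, size=(2, 8)))
        vals[1, 0] = 0.0  # denominator zero in sample a1
        table = pp.IntensityTable(
            pd.DataFrame(vals, index=["pi", "pj"], columns=toy_annotation.sample_ids)
        )
        rs = pp.compute_ratios(table, toy_annotation, "pi", "pj")
        deleted = pp.IntensityTable(
            pd.DataFrame(
                vals[:, 1:], index=["pi", "pj"], columns=toy_annotation.sample_ids[1:]
            )
        )
        annot_del = pp.SampleAnnotation(
            toy_annotation.frame[toy_annotation.frame.sample_id != "a1"]
        )
        rs_del = pp.compute_ratios(deleted, annot_del, "pi", "pj")
        assert rs.ratios_C.tolist() == rs_del.ratios_C.tolist()
        assert rs.ratios_P.tolist() == rs_del.ratios_P.tolist()

    def test_same_peptide_rejected(self, toy_annotation):
        table = pp.IntensityTable(
            pd.DataFrame(
                np.ones((1, 8)), index=["pi"], columns=toy_annotation.sample_ids
            )
        )
        with pytest.raises(ValueError):
            pp.compute_ratios(table, toy_annotation, "pi", "pi")

    def test_too_few_usable_samples_is_signalled(self, toy_annotation):
        vals = np.ones((2, 8))
        vals[0, :3] = np.nan  # only one usable control sample
        table = pp.IntensityTable(
            pd.DataFrame(vals, index=["pi", "pj"], columns=toy_annotation.sample_ids)
        )
        with pytest.raises(InsufficientSamplesError):
            pp.compute_ratios(table, toy_annotation, "pi", "pj")


class TestDiscriminabilityIndex:
    def test_hand_worked_raw_example(self):
        rs = pp.RatioSet("i", "j", np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        # medians 2 and 5, sample SDs 1 and 1
        assert pp.discriminability_index(rs, ratio_scale="raw") == -3.0

    def test_identical_distributions_score_zero(self):
        rs = pp.RatioSet("i", "j", np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert pp.discriminability_index(rs, ratio_scale="raw") == 0.0
        assert pp.discriminability_index(rs, ratio_scale="log") == 0.0

    def test_constant_ratios_are_degenerate(self):
        rs = pp.RatioSet("i", "j", np.array([2.0, 2, 2]), np.array([1.0, 2, 3]))
        with pytest.raises(DegenerateSpreadError, match="degenerate-spread"):
            pp.discriminability_index(rs)

    def test_even_length_median_is_mean_of_central_pair(self):
        rs = pp.RatioSet("i", "j", np.array([1.0, 2, 3, 10]), np.array([1.0, 3, 5, 7]))
        d = pp.discriminability_index(rs, ratio_scale="raw")
        num = (2 + 3) / 2 - (3 + 5) / 2
        den = np.std([1.0, 2, 3, 10], ddof=1) * np.std([1.0, 3, 5, 7], ddof=1)
        assert d == pytest.approx(num / den)

    def test_population_sd_mode_changes_denominator(self):
        rs = pp.RatioSet("i", "j", np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        d_sample = pp.discriminability_index(rs, "sample", "raw")
        d_pop = pp.discriminability_index(rs, "population", "raw")
        assert d_pop == pytest.approx(d_sample * (np.std([1, 2, 3], ddof=1) ** 2)
                                      / (np.std([1, 2, 3]) ** 2))


class TestScanPeptidePairs:
    def test_enumerates_all_pairs(self):
        rng = np.random.default_rng(0)
        table, annot = make_random_cohort(rng, n_peptides=4, missing_rate=0,
                                          zero_rate=0)
        scores = pp.scan_peptide_pairs(table, annot)
        assert len(scores) == pp.pair_count(4) == 6

    @pytest.mark.parametrize("ratio_scale", ["log", "raw"])
    def test_matches_brute_force_exactly(self, ratio_scale):
        rng = np.random.default_rng(202)
        for _ in range(25):
            table, annot = make_random_cohort(rng)
            try:
                scan = pp.scan_peptide_pairs(table, annot, ratio_scale=ratio_scale)
            except NoScorablePairsError:
                scan = pd.DataFrame(columns=pp.scoring.PEPTIDE_SCORE_COLUMNS)
            expected = brute_force_scan(table, annot, ratio_scale)
            got = list(
                scan[["peptide_i", "peptide_j", "d", "n_C", "n_P"]].itertuples(
                    index=False, name=None
                )
            )
            assert got == expected

    def test_all_missing_peptide_only_affects_its_own_pairs(self):
        rng = np.random.default_rng(7)
        table, annot = make_random_cohort(rng, n_peptides=6, missing_rate=0,
                                          zero_rate=0)
        broken = table.data.copy()
        broken.loc["pep0", annot.samples_of_class("C")] = np.nan
        scan_broken = pp.scan_peptide_pairs(pp.IntensityTable(broken), annot)
        assert not (scan_broken[["peptide_i", "peptide_j"]] == "pep0").any().any()
        others = table.subset_peptides([p for p in table.peptide_ids if p != "pep0"])
        scan_removed = pp.scan_peptide_pairs(others, annot)
        pd.testing.assert_frame_equal(
            scan_broken.reset_index(drop=True), scan_removed.reset_index(drop=True)
        )

    def test_single_peptide_raises(self, toy_annotation):
        table = pp.IntensityTable(
            pd.DataFrame(np.ones((1, 8)), index=["pi"],
                         columns=toy_annotation.sample_ids)
        )
        with pytest.raises(NoScorablePairsError):
            pp.scan_peptide_pairs(table, toy_annotation)

    def test_feature_scan_identical_to_peptide_scan(self):
        rng = np.random.default_rng(9)
        table, annot = make_random_cohort(rng, n_peptides=5)
        pd.testing.assert_frame_equal(
            pp.scan_feature_pairs(table, annot),
            pp.scan_peptide_pairs(table, annot),
        )

    def test_two_features_give_one_pair(self):
        rng = np.random.default_rng(10)
        table, annot = make_random_cohort(rng, n_peptides=2, missing_rate=0,
                                          zero_rate=0)
        assert len(pp.scan_feature_pairs(table, annot)) == 1


class TestInvariances:
    @pytest.mark.parametrize("ratio_scale", ["log", "raw"])
    def test_per_sample_rescaling_leaves_scores_unchanged(self, ratio_scale):
        rng = np.random.default_rng(31)
        table, annot = make_random_cohort(rng, n_peptides=12)
        factors = np.exp(rng.normal(0, 2, size=len(table.sample_ids)))
        scaled = pp.IntensityTable(table.data * factors)
        base = pp.scan_peptide_pairs(table, annot, ratio_scale=ratio_scale)
        scal = pp.scan_peptide_pairs(scaled, annot, ratio_scale=ratio_scale)
        assert base[["peptide_i", "peptide_j"]].equals(
            scal[["peptide_i", "peptide_j"]]
        )
        assert np.allclose(base["d"], scal["d"], rtol=1e-9)

    def test_class_swap_negates_every_score(self):
        rng = np.random.default_rng(32)
        table, annot = make_random_cohort(rng, n_peptides=10)
        swapped = pp.SampleAnnotation(
            annot.frame.assign(
                class_label=annot.frame["class_label"].map({"C": "P", "P": "C"})
            )
        )
        base = pp.scan_peptide_pairs(table, annot)
        swap = pp.scan_peptide_pairs(table, swapped)
        assert base[["peptide_i", "peptide_j"]].equals(
            swap[["peptide_i", "peptide_j"]]
        )
        assert np.array_equal(base["d"].to_numpy(), -swap["d"].to_numpy())
        assert np.array_equal(base[["n_C", "n_P"]].to_numpy(),
                              swap[["n_P", "n_C"]].to_numpy())


class TestAggregateProteinPairs:
    def test_hand_median(self):
        scores = pd.DataFrame(
            {"peptide_i": ["a", "b"], "peptide_j": ["c", "c"],
             "d": [1.0, 3.0], "n_C": [4, 4], "n_P": [4, 4]}
        )
        pmap = pp.PeptideProteinMap(pd.Series({"a": "P1", "b": "P1", "c": "P2"}))
        out = pp.aggregate_protein_pairs(scores, pmap)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["protein_1"], row["protein_2"]) == ("P1", "P2")
        assert row["D"] == 2.0
        assert row["n_peptide_pairs"] == 2
        assert row["direction_consistency"] == 1.0

    def test_single_pair_median_is_itself(self):
        scores = pd.DataFrame(
            {"peptide_i": ["a"], "peptide_j": ["c"], "d": [-0.7],
             "n_C": [4], "n_P": [4]}
        )
        pmap = pp.PeptideProteinMap(pd.Series({"a": "P1", "c": "P2"}))
        assert pp.aggregate_protein_pairs(scores, pmap).iloc[0]["D"] == -0.7

    def test_mixed_signs_shrink_and_report_consistency(self):
        scores = pd.DataFrame(
            {"peptide_i": ["a", "a", "b"], "peptide_j": ["c", "d", "c"],
             "d": [1.0, -1.0, 1.0], "n_C": [4] * 3, "n_P": [4] * 3}
        )
        pmap = pp.PeptideProteinMap(
            pd.Series({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
        )
        row = pp.aggregate_protein_pairs(scores, pmap).iloc[0]
        assert row["D"] == 1.0
        assert row["direction_consistency"] == pytest.approx(2 / 3)

    def test_intra_protein_pairs_excluded(self):
        scores = pd.DataFrame(
            {"peptide_i": ["a", "a"], "peptide_j": ["b", "c"],
             "d": [5.0, 1.0], "n_C": [4] * 2, "n_P": [4] * 2}
        )
        pmap = pp.PeptideProteinMap(pd.Series({"a": "P1", "b": "P1", "c": "P2"}))
        out = pp.aggregate_protein_pairs(scores, pmap)
        assert len(out) == 1 and out.iloc[0]["D"] == 1.0

    def test_unmapped_peptide_is_hard_error(self):
        scores = pd.DataFrame(
            {"peptide_i": ["a"], "peptide_j": ["zzz"], "d": [1.0],
             "n_C": [4], "n_P": [4]}
        )
        pmap = pp.PeptideProteinMap(pd.Series({"a": "P1"}))
        with pytest.raises(pp.ValidationError, match="zzz"):
            pp.aggregate_protein_pairs(scores, pmap)

    def test_orientation_harmonised_against_reference(self):
        rng = np.random.default_rng(77)
        table, annot = make_random_cohort(rng, n_peptides=12)
        proteins = [f"PR{i % 4}" for i in range(12)]
        pmap = pp.PeptideProteinMap(pd.Series(proteins, index=table.peptide_ids))
        scores = pp.scan_peptide_pairs(table, annot)
        out = pp.aggregate_protein_pairs(scores, pmap)
        expected = brute_force_aggregate(scores, pmap)
        got = {
            (r.protein_1, r.protein_2): r.D for r in out.itertuples()
        }
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == expected[k]


class TestRankProteinPairs:
    def test_order_by_abs_D(self):
        pairs = pd.DataFrame(
            {"protein_1": ["A", "C", "E"], "protein_2": ["B", "D", "F"],
             "D": [1.58, -2.01, 1.60],
             "abs_D": [1.58, 2.01, 1.60],
             "n_peptide_pairs": [3, 3, 3],
             "direction_consistency": [1.0, 1.0, 1.0]}
        )
        ranked = pp.rank_protein_pairs(pairs)
        assert ranked["abs_D"].tolist() == [2.01, 1.60, 1.58]

    def test_tie_broken_by_support_then_ids(self):
        pairs = pd.DataFrame(
            {"protein_1": ["A", "C"], "protein_2": ["B", "D"],
             "D": [1.5, 1.5], "abs_D": [1.5, 1.5],
             "n_peptide_pairs": [2, 5],
             "direction_consistency": [1.0, 1.0]}
        )
        ranked = pp.rank_protein_pairs(pairs)
        assert ranked.iloc[0]["protein_1"] == "C"

    def test_single_pair_and_empty(self):
        one = pd.DataFrame(
            {"protein_1": ["A"], "protein_2": ["B"], "D": [0.5], "abs_D": [0.5],
             "n_peptide_pairs": [1], "direction_consistency": [1.0]}
        )
        assert len(pp.rank_protein_pairs(one)) == 1
        with pytest.raises(NoScorablePairsError):
            pp.rank_protein_pairs(one.iloc[:0])

    def test_up_in_P_orientation(self):
        # D < 0 means the protein_1:protein_2 ratio is higher in progressors
        pairs = pd.DataFrame(
            {"protein_1": ["A", "C"], "protein_2": ["B", "D"],
             "D": [-1.0, 1.0], "abs_D": [1.0, 1.0],
             "n_peptide_pairs": [2, 1], "direction_consistency": [1.0, 1.0]}
        )
        ranked = pp.rank_protein_pairs(pairs)
        assert ranked.set_index("protein_1")["up_in_P"].to_dict() == {
            "A": "A", "C": "D"
        }
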