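"""Call filtering, family classification, exclusions, binned summaries."""

import numpy as np
import pandas as pd
import pytest

import recombage as r
from recombage.io import FAM_COLUMNS

from conftest import make_calls, make_meioses


def _call(prob=0.9, left=100, right=None, chrom="chr1", parent="P1", child="K1",
          cohort="A"):
    right = left + 1 if right is None else right
    return (cohort, parent, child, chrom, left * 1000, right * 1000, prob,
            left, right)


class TestThreshold:
    def test_strictly_greater_than(self):
        calls = make_calls([_call(prob=p) for p in (0.4, 0.5, 0.6)])
        kept = r.threshold_calls(calls, 0.5)
        assert kept["posterior_prob"].tolist() == [0.6]

    def test_empty_and_identity(self):
        empty = make_calls([])
        assert r.threshold_calls(empty, 0.5).empty
        calls = make_calls([_call(prob=0.7), _call(prob=0.9)])
        pd.testing.assert_frame_equal(r.threshold_calls(calls, 0.0), calls)


class TestDoubleCrossoverFilter:
    X = {"A": 5}

    def test_tight_pair_both_removed(self):
        calls = make_calls([_call(left=100), _call(left=104)])
        kept, removed = r.filter_double_crossovers(calls, self.X)
        assert kept.empty
        assert len(removed) == 2 and (removed["reason"] == "tight_pair").all()

    def test_well_separated_all_survive(self):
        calls = make_calls([_call(left=100), _call(left=200), _call(left=300)])
        kept, removed = r.filter_double_crossovers(calls, self.X)
        assert len(kept) == 3 and removed.empty

    def test_single_call_survives(self):
        calls = make_calls([_call(left=100)])
        kept, _ = r.filter_double_crossovers(calls, self.X)
        assert len(kept) == 1

    def test_boundary_separation_kept(self):
        # separation exactly X is NOT "within X SNPs"
        calls = make_calls([_call(left=100, right=101), _call(left=106)])
        kept, _ = r.filter_double_crossovers(calls, self.X)
        assert len(kept) == 2

    def test_cascade_reevaluates_after_removal(self):
        # (100,101), (104,105), (108,109): first pair removed, third remains
        # alone (separation to nothing), so exactly one call survives.
        calls = make_calls([_call(left=100), _call(left=104), _call(left=108)])
        kept, removed = r.filter_double_crossovers(calls, self.X)
        assert len(kept) == 1 and kept.iloc[0]["left_snp_index"] == 108
        assert len(removed) == 2

    def test_filters_do_not_mix_meioses(self):
        calls = make_calls([
            _call(left=100, child="K1"), _call(left=104, child="K2")])
        kept, _ = r.filter_double_crossovers(calls, self.X)
        assert len(kept) == 2

    def test_idempotent(self, nb_meioses):
        table, truth, _ = nb_meioses
        sub = table.head(300)
        x_map = {c: 150 for c in sub.cohort.unique()}
        calls, _ = r.simulate_call_table(sub, truth, artifact_rate=0.3, seed=5,
                                         x_snps_by_cohort=x_map)
        once, _ = r.filter_double_crossovers(calls, x_map)
        twice, removed2 = r.filter_double_crossovers(once, x_map)
        pd.testing.assert_frame_equal(once, twice)
        assert removed2.empty
        thr_once = r.threshold_calls(calls, 0.5)
        pd.testing.assert_frame_equal(thr_once, r.threshold_calls(thr_once, 0.5))

    def test_missing_cohort_x_raises(self):
        calls = make_calls([_call()])
        with pytest.raises(KeyError, match="cohort"):
            r.filter_double_crossovers(calls, {"B": 5})


class TestNftoolsWindowFilter:
    def _with_markers(self, pairs):
        calls = make_calls([_call(left=l * 50) for l, _ in enumerate(pairs, 1)])
        calls["left_marker_index"] = [a for a, _ in pairs]
        calls["right_marker_index"] = [b for _, b in pairs]
        return calls

    def test_three_markers_apart_removed(self):
        calls = self._with_markers([(10, 11), (14, 15)])  # separation 3
        assert r.nftools_window_filter(calls, 5).empty

    def test_six_markers_apart_kept(self):
        calls = self._with_markers([(10, 11), (17, 18)])  # separation 6
        assert len(r.nftools_window_filter(calls, 5)) == 2

    def test_empty_input(self):
        calls = self._with_markers([])
        assert r.nftools_window_filter(calls, 5).empty

    def test_missing_marker_columns(self):
        with pytest.raises(KeyError, match="marker"):
            r.nftools_window_filter(make_calls([_call()]), 5)


def _fam(rows):
    return pd.DataFrame(rows, columns=FAM_COLUMNS)


class TestClassifyFamily:
    def _family(self, n_children, both_parents, grandparents):
        rows = [("F1", "mum", "gma", "gpa", 2, -9) if grandparents
                else ("F1", "mum", "0", "0", 2, -9)]
        if grandparents:
            rows += [("F1", "gma", "0", "0", 2, -9), ("F1", "gpa", "0", "0", 1, -9)]
        if both_parents:
            rows.append(("F1", "dad", "0", "0", 1, -9))
        for k in range(n_children):
            rows.append((f"F1", f"kid{k}", "dad", "mum", 0, -9))
        return _fam(rows)

    @pytest.mark.parametrize("n_children,both,grand,expected,fully", [
        (3, False, False, 1, False),
        (3, True, False, 2, True),
        (2, False, False, 3, False),
        (2, True, False, 4, False),
        (2, False, True, 5, False),
        (2, True, True, 6, True),
        (4, True, True, 2, True),   # >=3 children wins over grandparents
    ])
    def test_configurations(self, n_children, both, grand, expected, fully):
        cfg = r.classify_family(self._family(n_children, both, grand), "mum")
        assert cfg.code == expected
        assert cfg.fully_informative is fully

    def test_single_child_rejected(self):
        with pytest.raises(ValueError, match="<2"):
            r.classify_family(self._family(1, True, False), "mum")

    def test_target_parent_must_be_genotyped(self):
        fam = self._family(2, True, False)
        with pytest.raises(ValueError, match="not genotyped"):
            r.classify_family(fam[fam.individual_id != "mum"], "mum")


class TestDeduplicateMonozygotic:
    def _meioses(self, children):
        return make_meioses([
            ("A", "F1", "P1", c, "F", 30.0, 2, 40) for c in children])

    def test_one_pair_removed(self):
        out = r.deduplicate_monozygotic(
            self._meioses(["a", "b", "c", "d"]), [("a", "b")])
        assert len(out) == 3 and "b" not in set(out.child_id)

    def test_keeps_lexicographically_smaller(self):
        out = r.deduplicate_monozygotic(self._meioses(["z", "y"]), [("z", "y")])
        assert out.child_id.tolist() == ["y"]

    def test_empty_pairs_identity(self):
        m = self._meioses(["a", "b"])
        pd.testing.assert_frame_equal(r.deduplicate_monozygotic(m, []), m)

    def test_two_disjoint_pairs(self):
        out = r.deduplicate_monozygotic(
            self._meioses(list("abcdef")), [("a", "b"), ("c", "d")])
        assert len(out) == 4

    def test_absent_member_warns_and_skips(self):
        m = self._meioses(["a", "b"])
        with pytest.warns(UserWarning, match="skipped"):
            out = r.deduplicate_monozygotic(m, [("a", "x")])
        assert len(out) == 2


class TestExclusionRules:
    def _table(self, sizes, per_cfg=None):
        rows = []
        for cohort, n in sizes.items():
            for i in range(n):
                cfg = per_cfg[cohort][i] if per_cfg else 2
                rows.append((cohort, f"{cohort}F{i}", f"{cohort}P{i}",
                             f"{cohort}K{i}", "F", 30.0, cfg, 40))
        return make_meioses(rows)

    def test_cohort_level_rule(self):
        t = self._table({"a": 7, "b": 11, "c": 25})
        out = r.apply_exclusion_rules(t, 20, per_configuration=False)
        assert set(out.cohort) == {"c"} and len(out) == 25

    def test_all_cells_pass_identity(self):
        t = self._table({"a": 30, "b": 25})
        out = r.apply_exclusion_rules(t, 20)
        pd.testing.assert_frame_equal(out, t)

    def test_per_configuration_rule(self):
        cfgs = {"a": [2] * 30 + [4] * 19}
        t = self._table({"a": 49}, per_cfg=cfgs)
        out = r.apply_exclusion_rules(t, 20, per_configuration=True)
        assert len(out) == 30 and set(out.configuration) == {2}

    def test_never_removes_cells_at_threshold(self):
        t = self._table({"a": 20})
        assert len(r.apply_exclusion_rules(t, 20)) == 20


class TestBinnedAgeSummary:
    def test_all_equal_counts_zero_differences(self):
        m = make_meioses([
            ("A", "F1", "P1", f"K{i}", "F", age, 2, 40)
            for i, age in enumerate([21, 22, 27, 33])])
        out = r.binned_age_summary(m)
        assert np.allclose(out["mean_diff"], 0)
        assert np.allclose(out["ci_high"] - out["ci_low"],
                           out["ci_high"] - out["ci_low"])

    def test_closed_form_normal_ci(self):
        # reference bin mean 41 from counts {40,40,42,42}; sd = 1.1547
        m = make_meioses([
            ("A", "F1", "P1", f"K{i}", "F", 22.0, 2, c)
            for i, c in enumerate([40, 40, 42, 42])])
        out = r.binned_age_summary(m)
        sd = np.std([40, 40, 42, 42], ddof=1)
        assert abs(sd - 1.1547) < 1e-4
        row = out.iloc[0]
        assert row["n"] == 4 and row["mean_diff"] == 0
        assert np.isclose(row["ci_high"], 1.96 * sd / 2)

    def test_reference_bin_required(self):
        m = make_meioses([("A", "F1", "P1", "K1", "F", 33.0, 2, 40)])
        with pytest.raises(ValueError, match="reference"):
            r.binned_age_summary(m)

    def test_counts_offset_from_reference(self):
        m = make_meioses(
            [("A", "F1", "P1", f"K{i}", "F", 22.0, 2, 40) for i in range(3)]
            + [("A", "F2", "P2", f"J{i}", "F", 32.0, 2, 43) for i in range(3)])
        out = r.binned_age_summary(m)
        assert np.isclose(out[out.bin_low == 30].iloc[0]["mean_diff"], 3.0)


class TestAggregateCounts:
    def test_zero_for_meioses_without_calls(self, nb_meioses):
        table, truth, _ = nb_meioses
        sub = table.head(50)
        calls, _ = r.simulate_call_table(sub, truth, seed=0)
        counts = r.aggregate_counts(calls[calls.parent_id != sub.parent_id.iloc[0]],
                                    sub)
        assert (counts[counts.parent_id == sub.parent_id.iloc[0]]
                ["n_crossovers"] == 0).all()
        assert len(counts) == len(sub)


from hypothesis import given, settings, strategies as st


@st.composite
def _call_tables(draw):
    n = draw(st.integers(1, 12))
    lefts = sorted(draw(st.lists(st.integers(1, 500), min_size=n, max_size=n,
                                 unique=True)))
    probs = draw(st.lists(st.floats(0.01, 0.999), min_size=n, max_size=n))
    return make_calls([
        ("A", "P1", "K1", "chr1", l * 100, (l + 1) * 100, round(p, 3), l, l + 1)
        for l, p in zip(lefts, probs)])


class TestFilterProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(calls=_call_tables(), x=st.integers(1, 60),
           thr=st.floats(0.0, 0.99))
    def test_threshold_and_double_crossover_filter_properties(self, calls, x,
                                                              thr):
        kept = r.threshold_calls(calls, thr)
        assert (kept["posterior_prob"] > thr).all()
        out, removed = r.filter_double_crossovers(kept, {"A": x})
        # subset of input, counts conserved
        assert len(out) + len(removed) == len(kept)
        # no surviving consecutive pair within x
        lefts = out["left_snp_index"].to_numpy()
        rights = out["right_snp_index"].to_numpy()
        if len(out) > 1:
            assert (lefts[1:] - rights[:-1] >= x).all()
        # idempotence
        again, removed2 = r.filter_double_crossovers(out, {"A": x})
        assert removed2.empty
        pd.testing.assert_frame_equal(out, again)
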