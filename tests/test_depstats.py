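"""Mann-Whitney / CLES statistics, scanning, filtering and de-duplication."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgdscan import TargetLabel
from cgdscan.depstats import (
    DependencyRecord,
    PANCAN,
    adjust_pvalues,
    cles,
    delta_median,
    filter_cgds,
    mann_whitney_one_sided,
    resolve_multiscore,
    scan,
)
from cgdscan.genotype import build_alteration_matrix
from cgdscan.synth import generate_genotype, generate_screen

from conftest import oracle_exact_p, oracle_u_cles

finite_floats = st.floats(
    min_value=-50, max_value=50, allow_nan=False, allow_infinity=False
)
group = st.lists(finite_floats, min_size=1, max_size=6)


class TestCles:
    @pytest.mark.parametrize(
        "altered,wildtype,expected",
        [
            ([-3, -2], [-1, 0, 1], 1.0),
            ([-2, 0], [-1, 1], 0.75),
            ([0], [0], 0.5),
        ],
    )
    def test_worked_examples(self, altered, wildtype, expected):
        assert cles(altered, wildtype) == expected

    @given(a=group, w=group)
    @settings(max_examples=300, derandomize=True)
    def test_matches_pair_counting_oracle(self, a, w):
        _, expect = oracle_u_cles(a, w)
        assert cles(a, w) == pytest.approx(expect, abs=1e-12)

    @given(a=group, w=group)
    @settings(max_examples=200, derandomize=True)
    def test_complement_identity(self, a, w):
        assert cles(a, w) + cles(w, a) == pytest.approx(1.0, abs=1e-12)

    @given(
        a=st.lists(finite_floats.map(lambda x: round(x, 3)), min_size=1, max_size=6),
        w=st.lists(finite_floats.map(lambda x: round(x, 3)), min_size=1, max_size=6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_monotone_transform(self, a, w):
        # cubing is strictly increasing and exact on this coarse value grid
        f = lambda xs: [x ** 3 for x in xs]
        assert cles(a, w) == pytest.approx(cles(f(a), f(w)), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cles([], [1.0])


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mann_whitney_one_sided([-3, -2, -1], [1, 2, 3])
        assert u == 9 and p == pytest.approx(0.05, abs=1e-12)  # 1/C(6,3)

    def test_wrong_direction_p_one(self):
        _, p = mann_whitney_one_sided([1, 2, 3], [-3, -2, -1])
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_all_identical_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            u, p = mann_whitney_one_sided([5.0], [5.0])
        assert p == 1.0 and u == 0.5

    @given(
        data=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=4, max_size=10, unique=True,
        ),
        n1=st.integers(min_value=1, max_value=9),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_exact_p_matches_enumeration_oracle(self, data, n1):
        n1 = min(n1, len(data) - 1)
        a, w = data[:n1], data[n1:]
        u, p = mann_whitney_one_sided(a, w)
        u_expect, _ = oracle_u_cles(a, w)
        assert u == u_expect
        assert p == pytest.approx(oracle_exact_p(a, w), abs=1e-12)

    def test_normal_approximation_close_to_exact_small_n(self):
        """Tie-free n1+n2 <= 12: corrected normal p within 0.02 of exact."""
        from scipy import stats

        rng = np.random.default_rng(42)
        for _ in range(50):
            n1, n2 = rng.integers(3, 7), rng.integers(3, 7)
            a = rng.standard_normal(n1)
            w = rng.standard_normal(n2)
            _, p_exact = mann_whitney_one_sided(a, w)
            p_norm = stats.mannwhitneyu(a, w, alternative="less",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_norm) < 0.02

    def test_ties_fall_back_to_corrected_normal(self):
        a = [1.0, 1.0, 2.0, 3.0]
        w = [1.0, 2.0, 4.0, 5.0]
        u, p = mann_whitney_one_sided(a, w)
        assert 0 < p <= 1
        assert u == oracle_u_cles(a, w)[0]


class TestDeltaMedian:
    @pytest.mark.parametrize(
        "a,w,expected",
        [([-4, -2], [0, 2], -4.0), ([1, 2, 3], [1, 2, 3], 0.0), ([1], [0], 1.0)],
    )
    def test_examples(self, a, w, expected):
        assert delta_median(a, w) == expected


def make_record(p, cles_val, suffix=None, target_entrez=9101, dataset="DS1",
                context=PANCAN, driver=None, target_symbol=None):
    from cgdscan.genotype import DriverGeneSpec

    driver = driver or DriverGeneSpec(TargetLabel("DRV1", 9001), "oncogene", "both")
    n1, n2 = 10, 20
    return DependencyRecord(
        driver=driver,
        target=TargetLabel(target_symbol or "TGT", target_entrez, suffix),
        dataset_id=dataset,
        context=context,
        n_altered=n1,
        n_wildtype=n2,
        U=cles_val * n1 * n2,
        p_one_sided=p,
        cles=cles_val,
        delta_median=-1.0,
    )


class TestFilterCgds:
    def test_published_boundaries(self):
        kept = make_record(0.049, 0.65)
        p_at_limit = make_record(0.05, 0.90)
        cles_below = make_record(0.001, 0.64)
        out = filter_cgds([kept, p_at_limit, cles_below])
        assert out == [kept]

    def test_subset_order_and_idempotence(self):
        recs = [make_record(0.01, 0.9), make_record(0.2, 0.9), make_record(0.03, 0.7)]
        out = filter_cgds(recs)
        assert out == [recs[0], recs[2]]
        assert filter_cgds(out) == out
        assert len(recs) == 3  # input unmodified


class TestResolveMultiscore:
    def test_lower_p_wins(self):
        r1 = make_record(0.01, 0.8, suffix="1")
        r2 = make_record(0.03, 0.9, suffix="2")
        assert resolve_multiscore([r1, r2]) == [r1]

    def test_tie_broken_by_higher_cles(self):
        r1 = make_record(0.02, 0.7, suffix="1")
        r2 = make_record(0.02, 0.8, suffix="2")
        assert resolve_multiscore([r1, r2]) == [r2]

    def test_equal_p_and_cles_smallest_suffix(self):
        r1 = make_record(0.02, 0.8, suffix="2")
        r2 = make_record(0.02, 0.8, suffix="1")
        assert resolve_multiscore([r1, r2]) == [r2]

    def test_unsuffixed_and_distinct_groups_unchanged(self):
        single = make_record(0.01, 0.8)
        other_ds = make_record(0.03, 0.7, suffix="1", dataset="DS2")
        other_gene = make_record(0.02, 0.9, target_entrez=9102)
        out = resolve_multiscore([single, other_ds, other_gene])
        assert out == [single, other_ds, other_gene]


class TestAdjustPvalues:
    def test_none_is_identity(self):
        recs = [make_record(0.01, 0.8)]
        assert adjust_pvalues(recs, "none") == recs

    def test_bh_step_up_hand_example(self):
        recs = [make_record(p, 0.8, target_entrez=9100 + i)
                for i, p in enumerate([0.01, 0.02, 0.03])]
        out = adjust_pvalues(recs, "benjamini_hochberg")
        assert [r.q_value for r in out] == pytest.approx([0.03, 0.03, 0.03])
        assert [r.p_one_sided for r in out] == [0.01, 0.02, 0.03]

    def test_single_record_q_equals_p(self):
        out = adjust_pvalues([make_record(0.04, 0.8)], "benjamini_hochberg")
        assert out[0].q_value == pytest.approx(0.04)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([], "bonferroni")


class TestScan:
    def fixture(self, planted_truth, n_targets=6):
        screen = generate_screen(planted_truth, n_targets=n_targets, seed=11)
        muts, cnvs = generate_genotype(planted_truth)
        alterations = build_alteration_matrix(
            muts, cnvs, planted_truth.drivers, planted_truth.cell_lines
        )
        return screen, alterations

    def test_planted_complete_separation_single_record(self, ts_driver, planted_truth):
        truth = dataclasses.replace(
            planted_truth,
            planted=[dataclasses.replace(planted_truth.planted[0], effect_size=-50.0)],
        )
        screen, alterations = self.fixture(truth, n_targets=1)
        recs = scan(screen, alterations, contexts=[PANCAN])
        assert len(recs) == 1
        assert recs[0].cles == 1.0 and recs[0].context == PANCAN
        assert recs[0].n_altered == 10 and recs[0].n_wildtype == 20

    def test_below_min_altered_context_skipped(self, planted_truth):
        screen, alterations = self.fixture(planted_truth)
        recs = scan(screen, alterations, min_altered=11)
        assert recs == []

    def test_all_missing_altered_scores_skips_pair(self, planted_truth):
        screen, alterations = self.fixture(planted_truth, n_targets=2)
        altered = set(planted_truth.altered_lines(planted_truth.drivers[0]))
        for i, cl in enumerate(screen.cell_line_names):
            if cl in altered:
                screen.scores[i, 0] = np.nan
        recs = scan(screen, alterations, contexts=[PANCAN])
        assert {r.target.entrez_id for r in recs} == {screen.targets[1].entrez_id}

    def test_deterministic_output_and_order(self, planted_truth):
        screen, alterations = self.fixture(planted_truth)
        r1 = scan(screen, alterations)
        r2 = scan(screen, alterations)
        assert r1 == r2
        keys = [(r.context != PANCAN, r.context, r.driver.entrez_id,
                 r.target.entrez_id, r.target.suffix or "") for r in r1]
        assert keys == sorted(keys)

    def test_cles_equals_u_over_n1n2(self, planted_truth):
        screen, alterations = self.fixture(planted_truth)
        for r in scan(screen, alterations):
            assert r.cles == pytest.approx(
                r.U / (r.n_altered * r.n_wildtype), abs=1e-12
            )

    def test_no_shared_cell_lines_raises(self, planted_truth):
        screen, alterations = self.fixture(planted_truth)
        other = dataclasses.replace(
            alterations, cell_lines=[f"X{i}_SKIN" for i in range(30)]
        )
        with pytest.raises(ValueError, match="share no cell lines"):
            scan(screen, other)
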