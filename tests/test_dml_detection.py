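import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from flsmethylome import dml_detection as dd
from flsmethylome.io_formats import BetaMatrix

from oracles import storey_oracle, welch_oracle


def make_matrix(beta_rows, det_rows=None, samples=None):
    samples = samples or [f"s{i}" for i in range(len(beta_rows[0]))]
    loci = [f"cg{i}" for i in range(len(beta_rows))]
    beta = pd.DataFrame(beta_rows, index=loci, columns=samples, dtype=float)
    det = (
        pd.DataFrame(det_rows, index=loci, columns=samples, dtype=float)
        if det_rows is not None
        else None
    )
    return BetaMatrix(beta, det)


class TestQCFilter:
    def test_noop_when_all_pass(self):
        m = make_matrix([[0.1, 0.2]], [[0.0005, 0.0002]])
        out, removed = dd.qc_filter_loci(m)
        assert removed == 0
        pd.testing.assert_frame_equal(out.beta, m.beta)

    def test_single_failing_value_drops_whole_locus(self):
        m = make_matrix(
            [[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]],
            [[0.0, 0.0], [0.002, 0.0], [0.0, 0.0]],
        )
        out, removed = dd.qc_filter_loci(m)
        assert removed == 1
        assert list(out.beta.index) == ["cg0", "cg2"]

    def test_all_loci_failing_gives_empty_matrix(self):
        m = make_matrix([[0.1], [0.2]], [[0.5], [0.9]])
        out, removed = dd.qc_filter_loci(m)
        assert removed == 2 and out.shape[0] == 0


class TestGroupValues:
    def test_missing_and_high_detection_excluded(self):
        m = make_matrix(
            [[0.1, np.nan, 0.3, 0.4, 0.5]],
            [[0.001, 0.001, 0.02, 0.0, 0.0]],
        )
        vals = dd.group_values(m, "cg0", m.sample_ids)
        assert sorted(vals) == [0.1, 0.4, 0.5]

    def test_all_usable(self):
        m = make_matrix([[0.1, 0.2, 0.3]], [[0.0001] * 3])
        assert len(dd.group_values(m, "cg0", m.sample_ids)) == 3

    def test_empty_sample_list(self):
        m = make_matrix([[0.1]])
        assert dd.group_values(m, "cg0", []).size == 0

    def test_unknown_sample_raises(self):
        m = make_matrix([[0.1]])
        with pytest.raises(KeyError):
            dd.group_values(m, "cg0", ["ghost"])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = dd.welch_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0 and p == 1

    def test_hand_computed_example(self):
        # means 0.8 vs 0.2, both variances 0.01, n=3:
        # t = 0.6/sqrt(0.02/3) = 7.348, Welch-Satterthwaite df = 4
        t, df, p = dd.welch_test([0.8, 0.7, 0.9], [0.2, 0.1, 0.3])
        assert t == pytest.approx(7.3485, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0018, abs=2e-4)

    def test_antisymmetry(self):
        x, y = [0.8, 0.75, 0.9, 0.6], [0.2, 0.1, 0.35]
        tx, _, px = dd.welch_test(x, y)
        ty, _, py = dd.welch_test(y, x)
        assert tx == -ty and px == py

    def test_zero_variance_conventions(self):
        t, _, p = dd.welch_test([0.5, 0.5], [0.5, 0.5])
        assert (t, p) == (0.0, 1.0)
        t, _, p = dd.welch_test([0.9, 0.9], [0.1, 0.1])
        assert t == np.inf and p == 0.0

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            nx, ny = rng.integers(2, 20, size=2)
            x, y = rng.random(nx), rng.random(ny)
            t, df, p = dd.welch_test(x, y)
            to, dfo, po = welch_oracle(x, y)
            assert t == pytest.approx(to, abs=1e-10)
            assert df == pytest.approx(dfo, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)


class TestStoreyQvalues:
    def test_step_up_with_pi0_fixed(self):
        # q(i) = min_{j>=i} p(j) m / j with m=4: all equal 0.04
        q = dd.storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        assert np.allclose(dd.storey_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert dd.storey_qvalues([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dd.storey_qvalues([0.5, 1.5])

    def test_pi0_near_one_under_uniform_null(self):
        rng = np.random.default_rng(0)
        p = rng.random(10_000)
        assert 0.85 <= dd.estimate_pi0(p) <= 1.0

    def test_matches_loop_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = int(rng.integers(5, 400))
            p = rng.random(m) ** rng.uniform(0.5, 2.0)
            assert np.allclose(
                dd.storey_qvalues(p), storey_oracle(p), atol=1e-12
            )

    @given(
        hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50)
    )
    @settings(deadline=None, max_examples=50)
    def test_q_order_follows_p_order(self, pvals):
        q = dd.storey_qvalues(pvals, pi0=1.0)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1.0).all() and (q >= 0.0).all()


class TestCallDml:
    def test_too_few_values_skipped(self):
        beta = [[0.8, np.nan, np.nan, 0.2, 0.2, 0.25]] * 2
        m = make_matrix(beta)
        tab = dd.call_dml(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (tab["skipped_reason"] == "too_few_values").all()
        assert tab["p_value"].isna().all() and tab["q_value"].isna().all()

    def test_overlapping_groups_rejected(self):
        m = make_matrix([[0.5] * 4])
        with pytest.raises(ValueError, match="disjoint"):
            dd.call_dml(m, ["s0", "s1"], ["s1", "s2"])

    def test_dml_requires_both_q_and_delta(self):
        # large delta but tiny n / high variance: significant q impossible
        rng = np.random.default_rng(1)
        beta = np.clip(
            np.concatenate(
                [rng.normal(0.7, 0.3, size=(5, 3)), rng.normal(0.3, 0.3, size=(5, 3))],
                axis=1,
            ),
            0,
            1,
        )
        m = make_matrix(beta.tolist())
        tab = dd.call_dml(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        big_delta = tab[tab["delta"].abs() > 0.1]
        assert not big_delta[big_delta["q_value"] >= 0.05]["is_dml"].any()

    def test_invariant_to_locus_and_sample_order(self, small_cohort):
        m = small_cohort.matrices[5]
        ra = [s for s in m.sample_ids if s.startswith("RA")][:5]
        oa = [s for s in m.sample_ids if s.startswith("OA")][:5]
        tab1 = dd.call_dml(m, ra, oa)
        shuffled_loci = list(m.beta.index[::-1])
        m2 = m.subset_loci(shuffled_loci)
        tab2 = dd.call_dml(m2, ra[::-1], oa[::-1])
        pd.testing.assert_frame_equal(tab1.sort_index(), tab2.sort_index())

    def test_lower_min_per_group_never_tests_fewer_loci(self, small_cohort):
        m = small_cohort.matrices[5]
        ra = [s for s in m.sample_ids if s.startswith("RA")]
        oa = [s for s in m.sample_ids if s.startswith("OA")]
        tested = {
            k: (dd.call_dml(m, ra, oa, min_per_group=k)["skipped_reason"] == "none").sum()
            for k in (2, 3, 4)
        }
        assert tested[2] >= tested[3] >= tested[4]

    def test_direction_matches_planted_sign(self, default_cohort):
        c = default_cohort
        m, _ = dd.qc_filter_loci(c.matrices[5])
        ra = [s for s in m.sample_ids if s.startswith("RA")]
        oa = [s for s in m.sample_ids if s.startswith("OA")]
        tab = dd.call_dml(m, ra, oa)
        truth = c.truth.loci.set_index("locus_id")
        hits = tab[tab["is_dml"]].index.intersection(
            truth.index[truth["is_planted_dml"]]
        )
        assert len(hits) > 100
        signs = np.sign(truth.loc[hits, "planted_delta"])
        called = tab.loc[hits, "direction"].map({"hyper": 1, "hypo": -1})
        assert (signs.to_numpy() == called.to_numpy()).all()
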