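import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.cluster import hierarchy

from flsmethylome import signature_stability as st
from flsmethylome.io_formats import BetaMatrix

NA = np.nan


def matrix_of(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(rows[0]))]
    loci = [f"cg{i}" for i in range(len(rows))]
    return BetaMatrix(pd.DataFrame(rows, index=loci, columns=samples, dtype=float))


class TestSubset:
    def test_partial_overlap_reported(self, small_cohort):
        m = small_cohort.matrices[3]
        sig = list(m.beta.index[:2]) + ["cg_not_there"]
        sub, absent = st.subset_to_signature(m, sig)
        assert sub.shape[0] == 2 and absent == ["cg_not_there"]

    def test_order_follows_signature(self, small_cohort):
        m = small_cohort.matrices[3]
        sig = list(m.beta.index[5:0:-1])
        sub, _ = st.subset_to_signature(m, sig)
        assert list(sub.beta.index) == sig

    def test_zero_overlap_is_error(self, small_cohort):
        with pytest.raises(ValueError):
            st.subset_to_signature(small_cohort.matrices[3], ["nope"])


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [0.1, 0.4, 0.2, 0.9]
        assert st.spearman_pairwise(x, x) == pytest.approx(1.0)
        assert st.spearman_pairwise(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_with_missing(self):
        # complete pairs (1,2),(2,1),(3,4),(4,3): sum d^2 = 4
        # rho = 1 - 6*4 / (4*15) = 0.6
        rho = st.spearman_pairwise([1, 2, 3, 4, NA], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.6)

    def test_too_few_pairs_gives_nan(self):
        assert np.isnan(st.spearman_pairwise([1, NA, 3], [2, 5, NA]))

    @given(
        hst.lists(
            hst.floats(min_value=1e-3, max_value=1.0), min_size=5, max_size=30, unique=True
        )
    )
    @settings(deadline=None, max_examples=40)
    def test_invariant_under_monotone_transform(self, xs):
        from hypothesis import assume

        t = np.exp(5 * np.asarray(xs))
        assume(len(set(t)) == len(t))  # transform must not create float ties
        rng = np.random.default_rng(0)
        ys = rng.permutation(len(xs)).astype(float)
        base = st.spearman_pairwise(xs, ys)
        assert st.spearman_pairwise(t, ys) == pytest.approx(base, abs=1e-12)


class TestDeltaHistogram:
    def test_identical_matrices_put_all_mass_at_zero(self):
        a = np.array([0.1, 0.5, 0.9])
        edges, dens = st.delta_histogram(a, a)
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        assert dens[zero_bin] == pytest.approx(100.0)
        assert np.count_nonzero(dens) == 1

    def test_constant_shift_lands_in_expected_bin(self):
        a = np.zeros(10)
        edges, dens = st.delta_histogram(a, a + 0.055)
        idx = np.flatnonzero(dens)[0]
        assert edges[idx] == pytest.approx(0.05)
        assert dens[idx] * 0.01 == pytest.approx(1.0)

    def test_area_normalization_exact(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(5000), rng.random(5000)
        a[rng.random(5000) < 0.05] = NA
        _, dens = st.delta_histogram(a, b)
        assert np.sum(dens * 0.01) == pytest.approx(1.0, abs=1e-12)
        assert (dens >= 0).all()

    def test_no_complete_pairs_is_error(self):
        with pytest.raises(ValueError):
            st.delta_histogram([NA, 1.0], [0.5, NA])


class TestPassageStability:
    def test_duplicate_sample_as_replicate_gives_rho_one(self):
        vals = np.random.default_rng(0).random((20, 1))
        m5 = matrix_of(np.hstack([vals, vals]).tolist(), ["a_P5", "a_P5r"])
        m3 = matrix_of(vals.tolist(), ["a_P3"])
        sheet = pd.DataFrame(
            {
                "sample_id": ["a_P3", "a_P5", "a_P5r"],
                "phenotype": ["RA"] * 3,
                "cell_line_id": ["a"] * 3,
                "passage": [3, 5, 5],
                "replicate_label": ["", "", "rep"],
            }
        )
        rep = st.passage_stability({3: m3, 5: m5}, sheet)
        reps = rep.per_line_rho[rep.per_line_rho["is_replicate_pair"]]
        assert len(reps) == 1 and reps["rho"].iloc[0] == pytest.approx(1.0)

    def test_single_line_two_passages_average_is_itself(self):
        rng = np.random.default_rng(1)
        vals = rng.random((30, 1))
        m3 = matrix_of(vals.tolist(), ["l1_P3"])
        m5 = matrix_of((vals + rng.normal(0, 0.01, vals.shape)).clip(0, 1).tolist(), ["l1_P5"])
        sheet = pd.DataFrame(
            {
                "sample_id": ["l1_P3", "l1_P5"],
                "phenotype": ["RA", "RA"],
                "cell_line_id": ["l1", "l1"],
                "passage": [3, 5],
                "replicate_label": ["", ""],
            }
        )
        rep = st.passage_stability({3: m3, 5: m5}, sheet)
        assert len(rep.per_line_rho) == 1
        assert rep.average_rho["mean_rho"].iloc[0] == pytest.approx(
            rep.per_line_rho["rho"].iloc[0]
        )

    def test_no_shared_lines_is_error(self):
        m3 = matrix_of([[0.5]], ["x_P3"])
        m5 = matrix_of([[0.5]], ["y_P5"])
        sheet = pd.DataFrame(
            {
                "sample_id": ["x_P3", "y_P5"],
                "phenotype": ["RA", "OA"],
                "cell_line_id": ["x", "y"],
                "passage": [3, 5],
                "replicate_label": ["", ""],
            }
        )
        with pytest.raises(ValueError):
            st.passage_stability({3: m3, 5: m5}, sheet)

    def test_replicate_pairs_present_in_cohort(self, small_cohort):
        rep = st.passage_stability(
            small_cohort.matrices, small_cohort.sheet, small_cohort.signature
        )
        reps = rep.per_line_rho[rep.per_line_rho["is_replicate_pair"]]
        assert len(reps) == small_cohort.config.p5_replicate_lines
        assert (reps["rho"] > 0.8).all()


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(2)
        base = rng.random(50)
        rows = np.column_stack([base, base, rng.random(50)])
        slink, _, _ = st.cluster_heatmap(matrix_of(rows.tolist()))
        assert slink[0, 2] == pytest.approx(0.0, abs=1e-4)
        assert {int(slink[0, 0]), int(slink[0, 1])} == {0, 1}

    def test_hand_computed_complete_linkage(self):
        # one locus, three samples at 0, 0.01, 0.05 -> x100 gives 0, 1, 5
        # distances d12=1, d13=5, d23=4: merge {1,2} at 1, then all at 5
        m = matrix_of([[0.0, 0.01, 0.05]])
        slink, _, _ = st.cluster_heatmap(m)
        assert slink[0, 2] == pytest.approx(1.0, abs=1e-6)
        assert slink[1, 2] == pytest.approx(5.0, abs=1e-6)

    def test_missing_values_kept_in_ordered_matrix(self):
        rows = np.random.default_rng(3).random((10, 3))
        rows[0, 0] = NA
        _, _, ordered = st.cluster_heatmap(matrix_of(rows.tolist()))
        assert ordered.isna().sum().sum() == 1

    def test_sample_order_invariance_up_to_heights(self, small_cohort):
        sig, _ = st.subset_to_signature(
            small_cohort.matrices[5], small_cohort.signature
        )
        l1, _, _ = st.cluster_heatmap(sig)
        rev = sig.subset_samples(list(sig.beta.columns)[::-1])
        l2, _, _ = st.cluster_heatmap(rev)
        assert np.allclose(np.sort(l1[:, 2]), np.sort(l2[:, 2]))

    def test_disjoint_observation_pattern_is_error(self):
        rows = [[0.1, NA], [NA, 0.2]]
        with pytest.raises(ValueError, match="share no observed"):
            st.cluster_heatmap(matrix_of(rows))

    def test_three_group_cohort_recovers_phenotypes(self, small_cohort):
        sig, _ = st.subset_to_signature(
            small_cohort.matrices[5], small_cohort.signature
        )
        slink, _, _ = st.cluster_heatmap(sig)
        labels = [s[:2] for s in sig.beta.columns]
        cut = hierarchy.fcluster(slink, 3, criterion="maxclust")
        # each cluster contains exactly one phenotype
        by_cluster = {}
        for lab, cl in zip(labels, cut):
            by_cluster.setdefault(cl, set()).add(lab)
        assert len(by_cluster) == 3
        assert all(len(v) == 1 for v in by_cluster.values())


class TestNewick:
    def test_leaves_and_parse(self):
        rng = np.random.default_rng(5)
        m = matrix_of(rng.random((30, 4)).tolist())
        slink, _, _ = st.cluster_heatmap(m)
        nwk = st.linkage_to_newick(slink, list(m.beta.columns))
        assert nwk.endswith(";")
        for s in m.beta.columns:
            assert s in nwk
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == set(m.beta.columns)
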