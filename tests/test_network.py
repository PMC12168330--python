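"""Network construction: adjacency, TOM, tree cut, eigenproteins, kME."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from plasmanet.correlation import bicor_matrix
from plasmanet.network import (
    NetworkParams,
    signed_adjacency,
    tom_similarity,
    cut_modules,
    module_eigenprotein,
    merge_close_modules,
    kme_table,
    enforce_kme_consistency,
    build_network,
)
from tests.conftest import two_block_matrix


def brute_force_tom(A, denom):
    """O(n^3) literal transcription of the topological overlap definition."""
    n = A.shape[0]
    k = A.sum(axis=0) - 1.0
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            D = (k[i] + k[j]) / 2 if denom == "mean" else min(k[i], k[j])
            T[i, j] = (l_ij + A[i, j]) / (D + 1.0 - A[i, j])
    return T


class TestAdjacency:
    def test_endpoints_and_closed_form(self):
        C = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 1.0], [-1.0, 1.0, 1.0]])
        A = signed_adjacency(C, 7.5)
        assert A[0, 2] == pytest.approx(0.0)
        assert A[1, 2] == pytest.approx(1.0)
        assert A[0, 1] == pytest.approx(2.0 ** -7.5)

    def test_monotone_in_correlation(self):
        rng = np.random.default_rng(0)
        c = np.sort(rng.uniform(-1, 1, 50))
        C = np.eye(51)
        C[0, 1:] = c
        C[1:, 0] = c
        A = signed_adjacency(C, 7.5)
        assert (np.diff(A[0, 1:]) > 0).all()

    def test_asymmetric_input_rejected(self):
        C = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            signed_adjacency(C, 7.5)


class TestTom:
    @pytest.mark.parametrize("denom", ["mean", "min"])
    def test_matches_brute_force_on_small_random_matrices(self, denom):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = rng.integers(3, 9)
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            assert np.allclose(tom_similarity(A, denom), brute_force_tom(A, denom),
                               atol=1e-12)

    def test_identical_neighborhoods_with_unit_edge_have_full_overlap(self):
        # two fully-overlapping nodes joined by a unit edge (binary graph)
        A = np.array([
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
            [1.0, 1.0, 0.0, 1.0],
        ])
        T = tom_similarity(A)
        assert T[0, 1] == pytest.approx(1.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 1, (20, 20))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(A)
        assert np.allclose(T, T.T)
        assert T.min() >= 0 and T.max() <= 1

    def test_out_of_range_entries_rejected(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            tom_similarity(A)


def _tom_dissim(df):
    C = np.nan_to_num(bicor_matrix(df.to_numpy()), nan=0.0)
    return 1.0 - tom_similarity(signed_adjacency(C, 7.5))


class TestCutModules:
    def test_two_planted_blocks_recovered_block_pure(self):
        df = two_block_matrix(seed=7)
        labels, _ = cut_modules(_tom_dissim(df), NetworkParams())
        truth = np.array([0] * 30 + [1] * 30)
        assert len(set(labels)) == 2 and 0 not in labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_pure_noise_mostly_unassigned(self):
        fracs = []
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((50, 100))
            C = np.nan_to_num(bicor_matrix(X), nan=0.0)
            d = 1.0 - tom_similarity(signed_adjacency(C, 7.5))
            labels, _ = cut_modules(d, NetworkParams())
            fracs.append((labels > 0).mean())
        assert np.mean(fracs) <= 0.2

    def test_too_few_elements_warns_and_unassigns(self):
        d = _tom_dissim(two_block_matrix(seed=1).iloc[:, :15])
        with pytest.warns(UserWarning, match="too few"):
            labels, _ = cut_modules(d, NetworkParams(min_module_size=10))
        assert (labels == 0).all()


class TestEigenprotein:
    def test_identical_members_give_rank_one_summary(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        df = pd.DataFrame({f"P{i}": base for i in range(4)})
        score, ve = module_eigenprotein(df, list(df.columns))
        assert ve == pytest.approx(1.0)
        standardized = (base - base.mean()) / base.std(ddof=1)
        assert np.allclose(score, standardized)

    def test_matches_direct_svd_up_to_sign(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(5, 4)))
        score, ve = module_eigenprotein(df, list(df.columns))
        Z = (df - df.mean()) / df.std(ddof=1)
        U, s, _ = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        ref = U[:, 0] / U[:, 0].std(ddof=1)
        assert (np.allclose(score, ref, atol=1e-8)
                or np.allclose(score, -ref, atol=1e-8))
        assert ve == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_sign_convention_mean_member_correlation_positive(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=50)
        df = pd.DataFrame({f"P{i}": -f + 0.3 * rng.normal(size=50) for i in range(5)})
        score, _ = module_eigenprotein(df, list(df.columns))
        cors = [np.corrcoef(df[c], score)[0, 1] for c in df.columns]
        assert np.mean(cors) > 0

    def test_unit_variance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        score, _ = module_eigenprotein(df, list(df.columns))
        assert score.std(ddof=1) == pytest.approx(1.0)


class TestMergeAndKme:
    def test_modules_driven_by_same_factor_merge(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal(60)
        X = np.sqrt(0.8) * f[:, None] + np.sqrt(0.2) * rng.standard_normal((60, 30))
        df = pd.DataFrame(X, columns=[f"P{j}" for j in range(30)])
        labels = pd.Series([1] * 15 + [2] * 15, index=df.columns)
        merged = merge_close_modules(df, labels, 0.07)
        assert merged.nunique() == 1

    def test_distant_modules_do_not_merge(self):
        df = two_block_matrix(seed=9)
        labels = pd.Series([1] * 30 + [2] * 30, index=df.columns)
        merged = merge_close_modules(df, labels, 0.07)
        assert merged.nunique() == 2

    def test_kme_of_eigenprotein_column_is_one_and_bounded(self, network_model, clean_cohort):
        kme = network_model.kme
        assert ((kme.to_numpy() >= -1) & (kme.to_numpy() <= 1) | np.isnan(kme.to_numpy())).all()
        # a protein identical to the eigenprotein correlates at 1
        mes = network_model.eigenproteins
        df = clean_cohort["clean"].copy()
        df["_me_clone"] = mes.iloc[:, 0]
        k = kme_table(df[["_me_clone"]], mes)
        assert k.iloc[0, 0] == pytest.approx(1.0)

    def test_hub_protein_has_top_own_module_kme(self, network_model, clean_cohort):
        truth = clean_cohort["truth"]
        kme = network_model.kme
        labels = network_model.module_labels
        # for each detected module, its peak-kME protein belongs to it
        for m in sorted(labels[labels > 0].unique()):
            hub = kme[f"M{m}"].idxmax()
            assert labels[hub] == m

    def test_consistency_enforcement_reaches_fixed_point(self):
        df = two_block_matrix(seed=10)
        labels = pd.Series([1] * 30 + [2] * 30, index=df.columns)
        # plant a cross-assignment: protein from block 2 labeled block 1
        labels.iloc[45] = 1
        out, converged = enforce_kme_consistency(df, labels)
        assert converged
        assert out.iloc[45] == 2
        again, _ = enforce_kme_consistency(df, out)
        pd.testing.assert_series_equal(out, again)

    def test_post_convergence_every_member_is_argmax_and_above_floor(self, network_model, clean_cohort):
        kme = network_model.kme
        labels = network_model.module_labels
        arr = kme.to_numpy()
        for i, p in enumerate(kme.index):
            m = labels[p]
            if m > 0:
                own = kme.at[p, f"M{m}"]
                assert own >= 0.30 - 1e-9
                assert own == pytest.approx(np.nanmax(arr[i]), abs=1e-9)


class TestEndToEnd:
    def test_nine_module_fixture_recovered(self, network_model, clean_cohort):
        truth = clean_cohort["truth"].module_of.reindex(network_model.module_labels.index)
        assert network_model.n_modules == 9
        assert adjusted_rand_score(truth, network_model.module_labels) >= 0.8

    def test_module_ids_ordered_by_size(self, network_model):
        sizes = network_model.module_labels[network_model.module_labels > 0].value_counts()
        ordered = sizes.sort_index()
        assert (ordered.to_numpy() == sorted(ordered, reverse=True)).all()

    def test_partition_invariant_under_protein_permutation(self):
        df = two_block_matrix(seed=12, n=35, block=20)
        rng = np.random.default_rng(0)
        perm = rng.permutation(df.columns)
        m1 = build_network(df)
        m2 = build_network(df[perm])
        l1 = m1.module_labels
        l2 = m2.module_labels.reindex(l1.index)
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_eigenprotein_columns_unit_variance(self, network_model):
        stds = network_model.eigenproteins.std(ddof=1)
        assert np.allclose(stds, 1.0)
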