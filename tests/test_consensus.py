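import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from endosig.consensus import (
    center_genes,
    cluster_samples,
    consensus_cluster,
    fold_change_heatmap_table,
    random_signature_baseline,
)
from endosig.pipeline import preprocess_study
from endosig.simulate import generate_multicondition

TABLE4_GROUPS = [("air", 6), ("lps", 5), ("smoke", 6), ("lps_smoke", 5)]
TABLE4_EFFECTS = {"air": 0.0, "lps": 2.0, "smoke": 4.0, "lps_smoke": 2.0}


def two_cluster_frame(n_genes=20, n_per=4, shift=5.0, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, noise, size=(n_genes, 2 * n_per))
    X[:, n_per:] += shift * np.where(np.arange(n_genes) % 2 == 0, 1, -1)[:, None]
    return (
        pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{i}" for i in range(2 * n_per)]),
        ["a"] * n_per + ["b"] * n_per,
    )


class TestCenterGenes:
    def test_rows_centered_idempotent_and_constant_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], columns=list("xyz"))
        out = center_genes(m)
        np.testing.assert_allclose(out.iloc[0], [-1, 0, 1])
        np.testing.assert_allclose(out.iloc[1], [0, 0, 0])
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        pd.testing.assert_frame_equal(center_genes(out), out)


class TestClusterSamples:
    def test_perfect_two_group_separation(self):
        m, labels = two_cluster_frame()
        part = cluster_samples(center_genes(m), k=2)
        assert adjusted_rand_score(labels, part) == 1.0

    def test_k_equals_samples_gives_singletons(self):
        m, _ = two_cluster_frame()
        part = cluster_samples(m, k=m.shape[1])
        assert len(set(part)) == m.shape[1]

    def test_zero_variance_sample_error_names_sample(self):
        m, _ = two_cluster_frame()
        m["s0"] = 3.14
        with pytest.raises(ValueError, match="s0"):
            cluster_samples(m, k=2)

    def test_four_condition_study_recovered_at_k4(self):
        st = generate_multicondition(
            [f"sig{i}" for i in range(100)], TABLE4_GROUPS, TABLE4_EFFECTS,
            seed=3, noise_sd=0.1,
        )
        gm = preprocess_study(st)
        labels = [st.groups[s] for s in gm.columns]
        part = cluster_samples(gm, k=4, gene_set={f"sym:sig{i}" for i in range(100)})
        assert adjusted_rand_score(labels, part) == 1.0

    def test_invalid_k_and_unknown_metric(self):
        m, _ = two_cluster_frame()
        with pytest.raises(ValueError, match="k="):
            cluster_samples(m, k=99)
        with pytest.raises(ValueError, match="metric"):
            cluster_samples(m, k=2, metric="cosine")


class TestConsensusCluster:
    def _study_matrix(self, seed=0, noise_sd=0.5):
        st = generate_multicondition(
            [f"sig{i}" for i in range(60)], TABLE4_GROUPS, TABLE4_EFFECTS,
            seed=seed, noise_sd=noise_sd,
        )
        gm = preprocess_study(st)
        return gm, [st.groups[s] for s in gm.columns], {f"sym:sig{i}" for i in range(60)}

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        gm, labels, sig = self._study_matrix()
        res = consensus_cluster(gm, labels, sig, reps=50, seed=1)
        C = res.consensus_matrix.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert ((C >= 0) & (C <= 1)).all()

    def test_frac_one_is_deterministic(self):
        gm, labels, sig = self._study_matrix()
        res = consensus_cluster(gm, labels, sig, frac=1.0, reps=20, seed=5)
        C = res.consensus_matrix.to_numpy()
        assert set(np.unique(C)) <= {0.0, 1.0}
        assert res.signature_accuracy in (0.0, 1.0)

    def test_reproducible_given_seed(self):
        gm, labels, sig = self._study_matrix()
        r1 = consensus_cluster(gm, labels, sig, reps=40, seed=7)
        r2 = consensus_cluster(gm, labels, sig, reps=40, seed=7)
        pd.testing.assert_frame_equal(r1.consensus_matrix, r2.consensus_matrix)
        assert r1.signature_accuracy == r2.signature_accuracy

    def test_sample_order_permutation_equivariance(self):
        gm, labels, sig = self._study_matrix()
        perm = np.random.default_rng(2).permutation(gm.shape[1])
        gm_p = gm.iloc[:, perm]
        labels_p = [labels[i] for i in perm]
        r1 = consensus_cluster(gm, labels, sig, reps=30, seed=3)
        r2 = consensus_cluster(gm_p, labels_p, sig, reps=30, seed=3)
        C1 = r1.consensus_matrix.to_numpy()[np.ix_(perm, perm)]
        np.testing.assert_allclose(C1, r2.consensus_matrix.to_numpy(), atol=1e-12)

    def test_perfectly_separated_groups(self):
        gm, labels, sig = self._study_matrix(noise_sd=0.05)
        res = consensus_cluster(gm, labels, sig, reps=30, seed=2)
        assert res.signature_accuracy == 1.0
        assert res.mean_between_group_consensus == pytest.approx(0.0, abs=1e-12)

    def test_too_few_signature_genes_rejected(self):
        gm, labels, _ = self._study_matrix()
        with pytest.raises(ValueError, match=">= 5"):
            consensus_cluster(gm, labels, {"sym:sig0"}, reps=5)


class TestRandomBaseline:
    def test_full_universe_draws_are_all_identical(self):
        st = generate_multicondition(
            [f"sig{i}" for i in range(30)], TABLE4_GROUPS, TABLE4_EFFECTS,
            seed=1, noise_sd=0.3, n_background=20,
        )
        gm = preprocess_study(st)
        labels = [st.groups[s] for s in gm.columns]
        accs, mean = random_signature_baseline(
            gm, labels, size=gm.shape[0], n_signatures=5, reps_per_signature=10,
            seed=4, frac=1.0,
        )
        assert len(set(accs)) == 1
        assert mean == accs[0]

    def test_size_larger_than_universe_rejected(self):
        st = generate_multicondition(["a", "b", "c", "d", "e"], TABLE4_GROUPS, {}, seed=0,
                                     n_background=5)
        gm = preprocess_study(st)
        with pytest.raises(ValueError, match="size"):
            random_signature_baseline(gm, [st.groups[s] for s in gm.columns],
                                      size=100, n_signatures=2, reps_per_signature=2)


class TestFoldChangeTable:
    def test_planted_shift_recovered_and_reference_excluded(self):
        sig = [f"sig{i}" for i in range(40)]
        st = generate_multicondition(
            sig, TABLE4_GROUPS, {"lps": 2.0}, seed=6, noise_sd=0.2, sign_mode="fixed",
        )
        # collapse without quantile normalization: a one-sided planted shift
        # is deliberately asymmetric, which cross-sample normalization shrinks
        from endosig.preprocess import collapse_probes

        gm = collapse_probes(st)
        labels = [st.groups[s] for s in gm.columns]
        table = fold_change_heatmap_table(gm, labels, {f"sym:{g}" for g in sig}, "air")
        assert "air" not in table.columns
        assert set(table.columns) == {"lps", "smoke", "lps_smoke"}
        lps = table["lps"].to_numpy()
        se = lps.std(ddof=1) / np.sqrt(lps.size)
        assert abs(lps.mean() - 2.0) < 3 * se
        assert abs(table["smoke"].to_numpy().mean()) < 0.3  # no planted shift

    def test_missing_signature_genes_dropped_with_warning(self, caplog):
        st = generate_multicondition(["a", "b", "c", "d", "e", "f"], TABLE4_GROUPS,
                                     {}, seed=0, n_background=10)
        gm = preprocess_study(st)
        labels = [st.groups[s] for s in gm.columns]
        with caplog.at_level("WARNING"):
            table = fold_change_heatmap_table(
                gm, labels, {"sym:a", "sym:b", "sym:notthere"}, "air"
            )
        assert len(table) == 2
        assert "absent" in caplog.text

    def test_missing_reference_group_rejected(self):
        st = generate_multicondition(["a", "b", "c", "d", "e"], TABLE4_GROUPS, {}, seed=0)
        gm = preprocess_study(st)
        with pytest.raises(ValueError, match="reference group"):
            fold_change_heatmap_table(gm, [st.groups[s] for s in gm.columns],
                                      {"sym:a"}, "vacuum")
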