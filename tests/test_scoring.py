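"""Signature scoring: module-score contracts, AUC recovery oracle, and
the ssGSEA running sum against a hand-traced oracle."""

import numpy as np
import pandas as pd
import pytest

from tmenet.scoring import (
    SsgseaConfig,
    SsgseaScorer,
    auc_set_score,
    module_score,
    ssgsea,
)
from tmenet.synthetic import SyntheticBulkConfig, gen_bulk_mixtures

from _oracles import auc_recovery_oracle, ssgsea_oracle
from conftest import make_adata


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        adata = make_adata(np.full((10, 60), 3.0))
        scores = module_score(adata, {"set": ["g0", "g1", "g2"]}, n_bins=5, seed=0)
        np.testing.assert_allclose(scores["set"], 0.0, atol=1e-12)

    def test_spiked_type_scores_highest(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.poisson(3.0, size=(90, 80)).astype(float)
            labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
            sig = [f"g{j}" for j in range(5)]
            X[:30, :5] *= np.exp(2)  # +2 log-units in type a
            scores = module_score(make_adata(X, labels=labels), {"s": sig}, seed=seed)
            means = scores.groupby(np.array(labels))["s"].mean()
            hits += means.idxmax() == "a"
        assert hits == 10

    def test_seed_determinism(self, rng):
        X = rng.poisson(2.0, size=(20, 100)).astype(float)
        adata = make_adata(X)
        a = module_score(adata, {"s": ["g0", "g5"]}, seed=42)
        b = module_score(adata, {"s": ["g0", "g5"]}, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_fully_absent_signature_rejected(self, rng):
        adata = make_adata(rng.poisson(2.0, size=(5, 30)).astype(float))
        with pytest.raises(ValueError, match="nope"):
            module_score(adata, {"nope": ["zz1", "zz2"]})

    def test_gene_order_invariance(self, rng):
        X = rng.poisson(2.0, size=(15, 50)).astype(float)
        adata = make_adata(X)
        perm = rng.permutation(50)
        shuffled = make_adata(X[:, perm], genes=[f"g{j}" for j in perm])
        a = module_score(adata, {"s": ["g3", "g7", "g11"]}, seed=1)
        b = module_score(shuffled, {"s": ["g3", "g7", "g11"]}, seed=1)
        # same control-bin structure regardless of column order
        np.testing.assert_allclose(a["s"], b["s"], atol=1e-10)


class TestAucSetScore:
    def test_all_top_ranks_score_one(self):
        X = np.tile(np.arange(100, 0, -1.0), (3, 1))  # g0 highest ... g99 lowest
        adata = make_adata(X)
        scores = auc_set_score(adata, {"s": ["g0", "g1", "g2"]}, top_frac=0.1)
        np.testing.assert_allclose(scores["s"], 1.0)

    def test_no_gene_in_top_fraction_scores_zero(self):
        X = np.tile(np.arange(100, 0, -1.0), (3, 1))
        adata = make_adata(X)
        scores = auc_set_score(adata, {"s": ["g98", "g99"]}, top_frac=0.05)
        np.testing.assert_allclose(scores["s"], 0.0)

    def test_matches_step_function_oracle(self, rng):
        X = rng.random((6, 100))
        adata = make_adata(X)
        sig = [f"g{j}" for j in rng.choice(100, 10, replace=False)]
        top_frac = 0.2
        scores = auc_set_score(adata, {"s": sig}, top_frac=top_frac, seed=0)
        for i in range(6):
            ranking = [f"g{j}" for j in np.argsort(-X[i], kind="stable")]
            expected = auc_recovery_oracle(ranking, sig, int(np.ceil(top_frac * 100)))
            assert scores["s"].iloc[i] == pytest.approx(expected)

    def test_monotone_rank_transform_invariance(self, rng):
        X = rng.random((5, 60))
        sig = {"s": ["g1", "g2", "g3", "g30"]}
        a = auc_set_score(make_adata(X), sig, top_frac=0.2, seed=3)
        b = auc_set_score(make_adata(np.exp(4 * X)), sig, top_frac=0.2, seed=3)
        np.testing.assert_allclose(a["s"], b["s"])

    def test_appending_last_ranked_gene_never_increases_score(self, rng):
        X = rng.random((8, 50))
        X[:, 49] = -1.0  # g49 ranks last in every sample
        adata = make_adata(X)
        base = auc_set_score(adata, {"s": ["g0", "g1", "g2"]}, top_frac=0.2, seed=0)
        extended = auc_set_score(adata, {"s": ["g0", "g1", "g2", "g49"]}, top_frac=0.2, seed=0)
        assert (extended["s"] <= base["s"] + 1e-12).all()

    def test_invalid_top_frac(self, rng):
        adata = make_adata(rng.random((3, 10)))
        with pytest.raises(ValueError):
            auc_set_score(adata, {"s": ["g0"]}, top_frac=0.0)


class TestSsgsea:
    def test_set_gene_ranks_drive_the_score(self):
        """Sample ranking set genes on top scores above the reversed sample."""
        genes = [f"g{j}" for j in range(10)]
        up = np.arange(10, 0, -1.0)
        df = pd.DataFrame([up, up[::-1]], index=["A", "B"], columns=genes)
        scores = ssgsea(df, {"s": ["g0", "g1", "g2"]}, SsgseaConfig(normalize=False))
        assert scores.loc["A", "s"] > scores.loc["B", "s"]

    def test_monotone_transform_invariance(self, rng):
        X = rng.random((4, 40))
        genes = [f"g{j}" for j in range(40)]
        df = pd.DataFrame(X, columns=genes)
        sig = {"s": genes[:8]}
        a = ssgsea(df, sig, SsgseaConfig(normalize=False))
        b = ssgsea(df * 100 + 3, sig, SsgseaConfig(normalize=False))
        pd.testing.assert_frame_equal(a, b)

    def test_matches_hand_traced_running_sum(self, rng):
        """8-gene/3-sample worked matrix against the independent oracle."""
        X = np.array(
            [
                [5.0, 3.0, 8.0, 1.0, 2.0, 7.0, 4.0, 6.0],
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                [2.0, 2.0, 2.0, 9.0, 1.0, 5.0, 5.0, 3.0],  # includes ties
            ]
        )
        genes = [f"g{j}" for j in range(8)]
        in_set = np.array([True, False, True, False, False, True, False, False])
        df = pd.DataFrame(X, index=["s1", "s2", "s3"], columns=genes)
        scores = ssgsea(
            df, {"s": ["g0", "g2", "g5"]}, SsgseaConfig(alpha=0.25, normalize=False)
        )
        for i in range(3):
            expected = ssgsea_oracle(X[i], in_set, alpha=0.25)
            assert scores["s"].iloc[i] == pytest.approx(expected)

    def test_normalization_divides_by_range(self, rng):
        X = rng.random((5, 30))
        df = pd.DataFrame(X, columns=[f"g{j}" for j in range(30)])
        sig = {"s": [f"g{j}" for j in range(6)]}
        raw = ssgsea(df, sig, SsgseaConfig(normalize=False))
        norm = ssgsea(df, sig, SsgseaConfig(normalize=True))
        rng_ = raw["s"].max() - raw["s"].min()
        np.testing.assert_allclose(norm["s"], raw["s"] / rng_)

    def test_small_signature_skipped_with_warning(self, rng):
        df = pd.DataFrame(rng.random((3, 20)), columns=[f"g{j}" for j in range(20)])
        with pytest.warns(UserWarning, match="skipped"):
            scores = ssgsea(df, {"tiny": ["g0"], "ok": ["g1", "g2", "g3"]})
        assert list(scores.columns) == ["ok"]

    def test_planted_subtype_ordering(self):
        """Mean score per subtype follows the planted effect ordering."""
        sigs = {f"sig{j}": list(range(20 * j, 20 * j + 10)) for j in range(3)}
        eff = np.array([[4.0, 0, 0], [2.0, 0, 0], [0.0, 0, 0]])
        for seed in range(10):
            cfg = SyntheticBulkConfig(
                n_samples=30, n_genes=100, signatures=sigs, k_true=3,
                group_effect=eff, noise_sd=1.0, seed=seed,
            )
            bulk = gen_bulk_mixtures(cfg)
            scores = ssgsea(bulk, bulk.uns["signatures"])
            means = scores.groupby(np.asarray(bulk.obs["subtype"]))["sig0"].mean()
            assert means["S1"] > means["S2"] > means["S3"]

    def test_sklearn_transformer_roundtrip(self, rng):
        df = pd.DataFrame(rng.random((4, 20)), columns=[f"g{j}" for j in range(20)])
        sigs = {"s": ["g0", "g1", "g2"]}
        scorer = SsgseaScorer(signatures=sigs).fit(df)
        out = scorer.transform(df)
        pd.testing.assert_frame_equal(out, ssgsea(df, sigs))
        params = scorer.get_params()
        assert params["alpha"] == 0.25
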