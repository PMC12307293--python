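"""Hill communication score: zeros, half-saturation, planted-pair
recovery, aggregation, and the group permutation test."""

import numpy as np
import pandas as pd
import pytest

from tmenet.communication import (
    CommConfig,
    LRPair,
    _set_level,
    _type_means,
    aggregate_network,
    comm_strength,
    compare_groups,
)
from tmenet.synthetic import SyntheticScConfig, gen_sc_expression

from conftest import make_adata


def simple_adata(rng, n_types=3, cells=30, genes=40):
    X = rng.poisson(2.0, size=(n_types * cells, genes)).astype(float)
    labels = np.repeat([f"t{i}" for i in range(n_types)], cells)
    return make_adata(X, labels=labels)


class TestCommStrength:
    def test_zero_ligand_gives_zero_strength(self, rng):
        adata = simple_adata(rng)
        X = np.asarray(adata.X)
        X[np.asarray(adata.obs["cell_type"] == "t0"), 0] = 0  # silence ligand in t0
        adata.X = X
        tab = comm_strength(adata, [LRPair(ligand=["g0"], receptor=["g1"])])
        t0_rows = tab[tab["sender"] == "t0"]
        assert (t0_rows["strength"] == 0).all()

    def test_half_saturation_at_hill_k(self, rng):
        """strength = 0.5 exactly when L*R equals the half-saturation constant."""
        adata = simple_adata(rng)
        config = CommConfig()
        _, means, _, gene_idx = _type_means(adata, config, "cell_type")
        L = _set_level(means["t0"], ["g0"], gene_idx)
        R = _set_level(means["t1"], ["g1"], gene_idx)
        tab = comm_strength(
            adata, [LRPair(ligand=["g0"], receptor=["g1"])], CommConfig(hill_k=L * R)
        )
        row = tab[(tab["sender"] == "t0") & (tab["receiver"] == "t1")]
        assert row["strength"].iloc[0] == pytest.approx(0.5)

    def test_strengths_bounded_and_monotone(self, rng):
        adata = simple_adata(rng)
        tab = comm_strength(adata, [LRPair(ligand=["g0"], receptor=["g1"])])
        assert ((tab["strength"] >= 0) & (tab["strength"] < 1)).all()
        # doubling ligand expression never decreases any strength from that sender
        X = np.asarray(adata.X).copy()
        X[:, 0] *= 5
        boosted = comm_strength(
            make_adata(X, labels=list(adata.obs["cell_type"])),
            [LRPair(ligand=["g0"], receptor=["g1"])],
        )
        merged = tab.merge(boosted, on=["pair", "sender", "receiver"], suffixes=("", "_b"))
        assert (merged["strength_b"] >= merged["strength"] - 1e-12).all()

    def test_absent_gene_scores_zero(self, rng):
        adata = simple_adata(rng)
        tab = comm_strength(adata, [LRPair(ligand=["missing"], receptor=["g1"])])
        assert (tab["strength"] == 0).all()

    def test_planted_pair_is_strongest_direction(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticScConfig(
                n_cell_types=4, cells_per_type=100, n_genes=200,
                lr_plants=[(150, 160, 0, 1, 8.0)], seed=seed,
            )
            adata = gen_sc_expression(cfg)
            lig, rec, s, r, _ = adata.uns["synthetic"]["lr_plants"][0]
            tab = comm_strength(adata, [LRPair(ligand=[lig], receptor=[rec])])
            best = tab.loc[tab["strength"].idxmax()]
            hits += (best["sender"], best["receiver"]) == (s, r)
        assert hits >= 9

    def test_multi_subunit_geometric_mean(self, rng):
        adata = simple_adata(rng)
        config = CommConfig()
        _, means, _, gene_idx = _type_means(adata, config, "cell_type")
        lv = _set_level(means["t0"], ["g0", "g2"], gene_idx)
        expected = np.sqrt(means["t0"][0] * means["t0"][2])
        assert lv == pytest.approx(expected)


class TestAggregateNetwork:
    def test_pair_strengths_add(self):
        tab = pd.DataFrame(
            {
                "pair": ["p1", "p2"],
                "pathway": ["x", "y"],
                "sender": ["A", "A"],
                "receiver": ["B", "B"],
                "strength": [0.2, 0.3],
            }
        )
        tab.attrs["cell_types"] = ["A", "B"]
        net = aggregate_network(tab)
        assert net["A"]["B"]["weight"] == pytest.approx(0.5)
        assert net["A"]["B"]["pathways"] == pytest.approx({"x": 0.2, "y": 0.3})

    def test_below_min_cells_type_is_isolated(self, rng):
        X = np.asarray(simple_adata(rng, cells=30).X)
        adata = make_adata(X, labels=["t0"] * 40 + ["t1"] * 3 + ["t2"] * 47)
        tab = comm_strength(
            adata, [LRPair(ligand=["g0"], receptor=["g1"])], CommConfig(min_cells=5)
        )
        net = aggregate_network(tab)
        assert "t1" in net.nodes
        assert net.degree("t1") == 0

    def test_random_table_matches_groupby_oracle(self, rng):
        tab = pd.DataFrame(
            {
                "pair": rng.choice(["p1", "p2", "p3"], 60),
                "pathway": "w",
                "sender": rng.choice(list("ABC"), 60),
                "receiver": rng.choice(list("ABC"), 60),
                "strength": rng.random(60),
            }
        )
        net = aggregate_network(tab)
        oracle = tab.groupby(["sender", "receiver"])["strength"].sum()
        for (s, r), w in oracle.items():
            assert net[s][r]["weight"] == pytest.approx(w)

    def test_total_weight_invariant_under_relabeling(self, rng):
        adata = simple_adata(rng)
        pairs = [LRPair(ligand=["g0"], receptor=["g1"])]
        net = aggregate_network(comm_strength(adata, pairs))
        renamed = make_adata(
            np.asarray(adata.X),
            labels=[{"t0": "zz", "t1": "aa", "t2": "mm"}[t] for t in adata.obs["cell_type"]],
        )
        net2 = aggregate_network(comm_strength(renamed, pairs))
        assert sum(d["weight"] for _, _, d in net.edges(data=True)) == pytest.approx(
            sum(d["weight"] for _, _, d in net2.edges(data=True))
        )

    def test_removing_a_pair_never_increases_weights(self, rng):
        adata = simple_adata(rng)
        pairs = [
            LRPair(ligand=["g0"], receptor=["g1"]),
            LRPair(ligand=["g2"], receptor=["g3"]),
        ]
        full = aggregate_network(comm_strength(adata, pairs))
        reduced = aggregate_network(comm_strength(adata, pairs[:1]))
        for u, v, d in reduced.edges(data=True):
            assert d["weight"] <= full[u][v]["weight"] + 1e-12


class TestCompareGroups:
    PAIRS = [LRPair(ligand=["g0"], receptor=["g1"])]

    def sample(self, seed, boost=1.0):
        cfg = SyntheticScConfig(
            n_cell_types=3, cells_per_type=40, n_genes=50,
            lr_plants=[(30, 35, 0, 1, boost)], seed=seed,
        )
        return gen_sc_expression(cfg)

    def test_identical_groups_give_p_one(self):
        samples = [self.sample(s) for s in range(2)]
        pairs = [LRPair(ligand=["g0030"], receptor=["g0035"])]
        res = compare_groups({"R": samples, "NR": samples}, pairs, n_perm=99, seed=0)
        assert (res["p_perm"] == 1.0).all()

    def test_add_one_smoothing_bound(self):
        groups = {
            "R": [self.sample(s, boost=1.0) for s in range(4)],
            "NR": [self.sample(s, boost=8.0) for s in range(100, 104)],
        }
        pairs = [LRPair(ligand=["g0030"], receptor=["g0035"])]
        res = compare_groups(groups, pairs, n_perm=99, seed=0)
        assert (res["p_perm"] >= 1 / 100).all()

    def test_planted_difference_detected(self):
        wins = 0
        for seed in range(10):
            groups = {
                "R": [self.sample(1000 * seed + s, boost=1.0) for s in range(10)],
                "NR": [self.sample(1000 * seed + 500 + s, boost=8.0) for s in range(10)],
            }
            pairs = [LRPair(ligand=["g0030"], receptor=["g0035"])]
            res = compare_groups(groups, pairs, n_perm=199, seed=seed)
            planted = res[(res["sender"] == "ct0") & (res["receiver"] == "ct1")]
            wins += (planted["p_perm"].iloc[0] < 0.05) and (planted["diff"].iloc[0] > 0)
        assert wins >= 8

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            compare_groups(
                {"R": [self.sample(0)], "NR": [self.sample(1), self.sample(2)]},
                self.PAIRS,
            )
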