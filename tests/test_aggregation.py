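"""Signatures, regulon activity, Tukey biweight, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altexpress import (
    ConfigError,
    ExpressionMatrix,
    GeneCluster,
    Regulon,
    aggregate_clusters,
    build_signature,
    cluster_genes,
    regulon_activity,
    tukey_biweight,
)


def _expr(arr, genes=None, samples=None, units="normalized"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), units)


class TestSignature:
    def test_constant_gene_gets_zero_row(self):
        sig = build_signature(_expr([[5, 5, 5], [1, 2, 3]]))
        assert (sig.loc["g0"] == 0).all()

    def test_rows_are_zscores_with_population_sd(self):
        sig = build_signature(_expr([[1, 2, 3]]))
        np.testing.assert_allclose(
            sig.loc["g0"].to_numpy(), [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_requires_three_samples(self):
        with pytest.raises(ConfigError, match="3 samples"):
            build_signature(_expr([[1, 2]]))


class TestRegulonActivity:
    def _regulon(self, n=16, mode=1):
        return Regulon("TF", {f"g{i}": mode for i in range(n)})

    def test_sixteen_half_signatures_give_two(self):
        sig = pd.DataFrame(
            0.5, index=[f"g{i}" for i in range(16)], columns=["s"]
        )
        act = regulon_activity(sig, [self._regulon(16)])
        assert act.at["TF", "s"] == pytest.approx(np.sqrt(16) * 0.5)

    def test_zero_signature_zero_activity(self):
        sig = pd.DataFrame(0.0, index=[f"g{i}" for i in range(12)], columns=["s"])
        assert regulon_activity(sig, [self._regulon(12)]).at["TF", "s"] == 0.0

    def test_negating_signature_negates_activity(self):
        rng = np.random.default_rng(0)
        sig = pd.DataFrame(
            rng.normal(size=(20, 5)), index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(5)],
        )
        a = regulon_activity(sig, [self._regulon(20)])
        b = regulon_activity(-sig, [self._regulon(20)])
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy())

    def test_sqrt_scaling_gives_unit_null_variance(self):
        """i.i.d. N(0,1) target signatures -> activity variance ~1 for any size."""
        rng = np.random.default_rng(3)
        for n in (10, 40, 160):
            sig = pd.DataFrame(
                rng.normal(size=(n, 1000)), index=[f"g{i}" for i in range(n)],
                columns=[f"s{j}" for j in range(1000)],
            )
            act = regulon_activity(sig, [self._regulon(n)])
            assert act.loc["TF"].var() == pytest.approx(1.0, rel=0.2)

    def test_undersized_regulons_dropped_and_all_dropped_raises(self):
        sig = pd.DataFrame(0.0, index=["g0", "g1"], columns=["s"])
        with pytest.raises(ConfigError, match="no regulon"):
            regulon_activity(sig, [self._regulon(16)])


class TestTukeyBiweight:
    def test_constant_vector_returns_value(self):
        assert tukey_biweight([7.0, 7.0, 7.0]) == 7.0

    def test_symmetric_vector_returns_center(self):
        assert tukey_biweight([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_outlier_zero_weighted(self):
        # M=1, MAD=0 -> u huge for the outlier, weight 0, result exactly 1
        assert tukey_biweight([1, 1, 1, 1, 100]) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tukey_biweight([])

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1, max_size=30,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_order_invariant(self, values, rnd):
        est = tukey_biweight(values)
        assert min(values) - 1e-9 <= est <= max(values) + 1e-9
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert tukey_biweight(shuffled) == pytest.approx(est, rel=1e-9, abs=1e-9)


class TestClusterGenes:
    def _planted(self, n_blocks=2, size=20, n_noise=0, seed=0):
        rng = np.random.default_rng(seed)
        rows, names = [], []
        for b in range(n_blocks):
            latent = rng.normal(size=60)
            for i in range(size):
                rows.append(latent * (1 + 0.01 * i))
                names.append(f"b{b}_g{i}")
        for i in range(n_noise):
            rows.append(rng.normal(size=60))
            names.append(f"noise_{i}")
        return _expr(np.array(rows), genes=names)

    def test_recovers_planted_blocks(self):
        clusters = cluster_genes(self._planted(), min_size=10)
        assert len(clusters) == 2
        memberships = [set(c.members) for c in clusters]
        expected = [
            {f"b0_g{i}" for i in range(20)},
            {f"b1_g{i}" for i in range(20)},
        ]
        assert all(e in memberships for e in expected)

    def test_clusters_disjoint_and_min_size(self):
        clusters = cluster_genes(self._planted(n_noise=15), min_size=10)
        seen = set()
        for c in clusters:
            assert c.size >= 10
            assert not (set(c.members) & seen)
            seen |= set(c.members)

    def test_no_cluster_mixes_planted_blocks(self):
        clusters = cluster_genes(self._planted(n_noise=10, seed=5), min_size=10)
        for c in clusters:
            blocks = {m.split("_")[0] for m in c.members if m.startswith("b")}
            assert len(blocks) <= 1

    def test_constant_matrix_raises(self):
        with pytest.raises(ConfigError):
            cluster_genes(_expr(np.ones((12, 6))), min_size=10)


class TestAggregateClusters:
    def test_constant_cluster_gives_constant_row(self):
        expr = _expr(np.full((10, 4), 3.0))
        agg = aggregate_clusters(expr, [GeneCluster("c", [f"g{i}" for i in range(10)])])
        np.testing.assert_allclose(agg.loc["c"], 3.0)

    def test_robust_to_single_outlier(self):
        rng = np.random.default_rng(2)
        base = rng.normal(5, 0.3, size=(10, 6))
        expr = _expr(base.copy())
        clusters = [GeneCluster("c", [f"g{i}" for i in range(10)])]
        clean = aggregate_clusters(expr, clusters)
        spiked = base.copy()
        spiked[0, 2] = 500.0
        dirty = aggregate_clusters(_expr(spiked), clusters)
        rel = abs(dirty.at["c", "s2"] - clean.at["c", "s2"]) / abs(clean.at["c", "s2"])
        assert rel < 0.05

    def test_equals_mean_when_members_agree(self):
        expr = _expr(np.tile([[1.0, 2.0, 3.0]], (10, 1)))
        agg = aggregate_clusters(expr, [GeneCluster("c", [f"g{i}" for i in range(10)])])
        np.testing.assert_allclose(agg.loc["c"], [1.0, 2.0, 3.0])

    def test_unknown_gene_raises(self):
        expr = _expr(np.ones((3, 3)))
        with pytest.raises(ConfigError, match="unknown gene"):
            aggregate_clusters(expr, [GeneCluster("c", ["nope"] * 1)])


def test_aggregates_have_fewer_rows_than_genes(small_cohort):
    from altexpress import normalize_counts

    norm = normalize_counts(small_cohort.counts)
    sig = build_signature(norm)
    act = regulon_activity(sig, small_cohort.regulons)
    assert act.shape[0] < norm.n_genes
    agg = aggregate_clusters(norm, small_cohort.clusters)
    assert agg.shape[0] < norm.n_genes
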