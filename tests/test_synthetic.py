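"""Generator contract: determinism, planted prevalence, coupling, dosage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altexpress import (
    CohortSimConfig,
    ConfigError,
    DriverEventSpec,
    PassengerEventSpec,
    simulate_cnv_segments,
    simulate_cohort,
    simulate_single_cell,
)


def _cfg(**kw):
    base = dict(
        n_samples=100, n_genes=200, n_tfs=2, targets_per_tf=15,
        library_size=10_000, seed=0,
    )
    base.update(kw)
    return CohortSimConfig(**base)


def test_fixed_seed_is_bitwise_deterministic():
    cfg = _cfg(driver_events=[DriverEventSpec("mutation", 0.3, 1.0, 0)])
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
    pd.testing.assert_frame_equal(a.truth_events.values, b.truth_events.values)
    assert [r.targets for r in a.regulons] == [r.targets for r in b.regulons]


def test_invalid_config_names_the_field():
    with pytest.raises(ConfigError, match="prevalence"):
        _cfg(driver_events=[DriverEventSpec("mutation", 1.5, 1.0, 0)])
    with pytest.raises(ConfigError, match="effect_size"):
        _cfg(driver_events=[DriverEventSpec("mutation", 0.3, -1.0, 0)])
    with pytest.raises(ConfigError, match="targets_per_tf"):
        _cfg(targets_per_tf=5)


def test_driver_prevalence_matches_binomial_expectation():
    """Mean carrier fraction over seeds stays within 0.3 +/- 0.05."""
    fracs = []
    for seed in range(30):
        cfg = CohortSimConfig(
            n_samples=1000, n_genes=60, n_tfs=1, targets_per_tf=20,
            driver_events=[DriverEventSpec("mutation", 0.3, 1.0, 0)],
            library_size=3_000, seed=seed,
        )
        co = simulate_cohort(cfg)
        fracs.append(co.truth_events.frequency()["carrier_fraction"].iloc[0])
    assert abs(np.mean(fracs) - 0.3) < 0.05


def test_zero_effect_driver_is_a_null():
    """With effect_size 0, carrier and non-carrier target means agree."""
    n_large_t = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = CohortSimConfig(
            n_samples=400, n_genes=60, n_tfs=1, targets_per_tf=20,
            driver_events=[DriverEventSpec("mutation", 0.5, 0.0, 0)],
            library_size=3_000, seed=seed,
        )
        co = simulate_cohort(cfg)
        carriers = co.truth_events.values.iloc[0].astype(bool).to_numpy()
        target = next(iter(co.regulons[0].targets))
        x = co.counts.values.loc[target].to_numpy()
        t, _ = stats.ttest_ind(x[carriers], x[~carriers])
        n_large_t += abs(t) >= 4
    assert n_large_t <= max(1, int(0.05 * n_seeds))


def test_regulon_targets_coexpress_above_background(small_cohort):
    """Median within-regulon |r| exceeds the 95th percentile of random pairs."""
    rng = np.random.default_rng(0)
    logc = np.log1p(small_cohort.counts.values.to_numpy())
    reg = small_cohort.regulons[0]
    idx = {g: i for i, g in enumerate(small_cohort.counts.genes)}
    rows = [idx[g] for g in reg.targets]
    corr = np.corrcoef(logc[rows])
    within = np.abs(corr[np.triu_indices_from(corr, k=1)])
    n_bg = 300
    bg = []
    for _ in range(n_bg):
        i, j = rng.choice(logc.shape[0], size=2, replace=False)
        bg.append(abs(np.corrcoef(logc[i], logc[j])[0, 1]))
    assert np.median(within) > np.quantile(bg, 0.95)


def test_cnv_driver_doubles_expected_count(cnv_cohort):
    """Amplification log2=+1 doubles, deletion log2=-1 halves, the mean."""
    for eid, ev in cnv_cohort.driver_specs.items():
        gene = eid.rsplit(":", 1)[0]
        carriers = cnv_cohort.truth_events.values.loc[eid].astype(bool).to_numpy()
        mu = cnv_cohort.mean_counts.loc[gene].to_numpy()
        ratio = mu[carriers].mean() / mu[~carriers].mean()
        expected = 2.0 ** ev.resolved_log2()
        # regulon shift also touches the TF's factor; dosage dominates
        assert ratio == pytest.approx(expected, rel=0.35)


def test_cnv_segments_require_cnv_class(small_cohort):
    with pytest.raises(ConfigError, match="amplification/deletion"):
        simulate_cnv_segments(small_cohort, small_cohort.truth_events.events[0])


def test_passenger_events_present_with_no_driver_gene_overlap(small_cohort):
    truth = small_cohort.truth_events
    assert truth.n_events == 2
    passenger_gene = truth.events[1].rsplit(":", 1)[0]
    regulon_genes = {g for r in small_cohort.regulons for g in r.targets} | {
        r.tf for r in small_cohort.regulons
    }
    assert passenger_gene not in regulon_genes


class TestSingleCell:
    def test_labels_inherited_from_source_sample(self, small_cohort):
        sc = simulate_single_cell(small_cohort, cells_per_sample=2, depth=500)
        for cell in sc.cells.samples[:20]:
            src = sc.cell_sample[cell]
            assert (
                sc.truth_events.values[cell].to_numpy()
                == small_cohort.truth_events.values[src].to_numpy()
            ).all()

    def test_full_depth_reproduces_source_profile(self, small_cohort):
        depth = int(small_cohort.counts.values.sum(axis=0).max()) + 1
        sc = simulate_single_cell(small_cohort, cells_per_sample=1, depth=depth)
        # depth >= every per-sample total -> thinning is the identity
        cell = sc.cells.samples[1]
        src = sc.cell_sample[cell]
        assert (
            sc.cells.values[cell].to_numpy()
            == small_cohort.counts.values[src].to_numpy()
        ).all()

    def test_zero_fraction_increases_as_depth_decreases(self, small_cohort):
        zf = []
        for depth in (5000, 500):
            sc = simulate_single_cell(
                small_cohort, cells_per_sample=1, depth=depth, seed=99
            )
            zf.append(float((sc.cells.values == 0).to_numpy().mean()))
        assert zf[1] > zf[0]
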