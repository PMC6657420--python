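"""CNV-to-gene assignment, binarization, mutation filters, event filters."""

import numpy as np
import pandas as pd
import pytest

from altexpress import (
    CnvSegment,
    ConfigError,
    EventMatrix,
    GeneInterval,
    SchemaError,
    assign_gene_cnv,
    binarize_cnv,
    filter_events,
    filter_silent_mutations,
    flag_hypermodified,
)


def seg(sample, start, end, log2, chrom="chr1"):
    return CnvSegment(sample, chrom, start, end, log2)


class TestAssignGeneCnv:
    GENE = [GeneInterval("g1", "chr1", 100, 200)]

    def test_unique_overlap(self):
        out = assign_gene_cnv([seg("s", 0, 300, 0.8)], self.GENE)
        assert out.at["g1", "s"] == 0.8

    def test_maximal_overlap_wins(self):
        segs = [seg("s", 0, 180, 0.8), seg("s", 180, 400, 0.1)]
        assert assign_gene_cnv(segs, self.GENE).at["g1", "s"] == 0.8

    def test_no_overlap_defaults_to_neutral(self):
        out = assign_gene_cnv([seg("s", 500, 600, 0.8)], self.GENE)
        assert out.at["g1", "s"] == 0.0

    def test_tie_prefers_larger_magnitude_then_leftmost(self):
        segs = [seg("s", 0, 150, 0.2), seg("s", 150, 300, -0.9)]
        assert assign_gene_cnv(segs, self.GENE).at["g1", "s"] == -0.9
        segs = [seg("s", 0, 150, 0.4), seg("s", 150, 300, -0.4)]
        assert assign_gene_cnv(segs, self.GENE).at["g1", "s"] == 0.4

    def test_agrees_with_per_base_counter_on_random_instances(self):
        """Brute-force oracle: count overlapping bases one by one."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            genes = []
            for gi in range(rng.integers(1, 8)):
                a = int(rng.integers(0, 900))
                genes.append(GeneInterval(f"g{gi}", "chr1", a, a + int(rng.integers(10, 100))))
            segs = []
            for si in range(rng.integers(1, 10)):
                a = int(rng.integers(0, 950))
                segs.append(seg("s", a, a + int(rng.integers(5, 120)),
                                float(rng.normal())))
            out = assign_gene_cnv(segs, genes)
            for g in genes:
                per_seg = []
                for s in segs:
                    bases = sum(
                        1 for p in range(g.start, g.end) if s.start <= p < s.end
                    )
                    per_seg.append((bases, abs(s.log2_ratio), -s.start, s.log2_ratio))
                best = max(per_seg)
                expected = best[3] if best[0] > 0 else 0.0
                assert out.at[g.gene_id, "s"] == expected, (trial, g)


class TestBinarize:
    def mat(self, v):
        return pd.DataFrame({"s": [v]}, index=["g"])

    @pytest.mark.parametrize(
        "value,amp,dele",
        [(0.6, 1, 0), (-0.7, 0, 1), (0.5, 1, 0), (-0.5, 0, 1), (0.49, 0, 0)],
    )
    def test_threshold_rule_inclusive(self, value, amp, dele):
        a, d = binarize_cnv(self.mat(value))
        assert a.values.iat[0, 0] == amp
        assert d.values.iat[0, 0] == dele

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            binarize_cnv(self.mat(np.nan))


class TestSilentFilter:
    def maf(self, rows):
        return pd.DataFrame(
            rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
        )

    def test_missense_survives_silent_dropped(self):
        m = self.maf([("TP53", "s1", "Silent"), ("TP53", "s1", "Missense_Mutation")])
        out = filter_silent_mutations(m)
        assert out.values.at["TP53:mutation", "s1"] == 1

    def test_all_silent_gives_empty_matrix(self):
        m = self.maf([("TP53", "s1", "Silent"), ("KRAS", "s2", "Intron")])
        out = filter_silent_mutations(m)
        assert out.n_events == 0
        assert list(out.samples) == ["s1", "s2"]

    def test_binary_collapse_of_repeated_rows(self):
        m = self.maf(
            [("KRAS", "s1", "Missense_Mutation"), ("KRAS", "s1", "Nonsense_Mutation")]
        )
        assert filter_silent_mutations(m).values.at["KRAS:mutation", "s1"] == 1

    def test_blacklist_removed_and_schema_checked(self):
        m = self.maf([("TTN", "s1", "Missense_Mutation"), ("TP53", "s1", "Missense_Mutation")])
        out = filter_silent_mutations(m, blacklist={"TTN"})
        assert list(out.events) == ["TP53:mutation"]
        with pytest.raises(SchemaError, match="Variant_Classification"):
            filter_silent_mutations(m.drop(columns="Variant_Classification"))


def _events_with_carriers(n_carriers, n_samples=200):
    row = np.zeros(n_samples, dtype=int)
    row[:n_carriers] = 1
    return EventMatrix(
        pd.DataFrame([row], index=["g:mutation"],
                     columns=[f"s{i}" for i in range(n_samples)])
    )


class TestFilterEvents:
    @pytest.mark.parametrize(
        "carriers,kept",
        [(9, False), (10, True), (190, True), (191, False)],
    )
    def test_boundary_decisions(self, carriers, kept):
        out = filter_events(_events_with_carriers(carriers))
        assert out.n_events == (1 if kept else 0)

    def test_idempotent(self, small_cohort):
        once = filter_events(small_cohort.truth_events)
        twice = filter_events(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigError, match="min_frac"):
            filter_events(_events_with_carriers(10), min_frac=0.9, max_frac=0.1)


class TestHypermodified:
    def mat(self, n_altered, n_genes=120):
        vals = np.zeros((n_genes, 1), dtype=int)
        vals[:n_altered, 0] = 1
        return EventMatrix(
            pd.DataFrame(vals, index=[f"g{i}:mutation" for i in range(n_genes)],
                         columns=["s"])
        )

    def test_strictly_more_than_half_percent(self):
        # 101/20000 = 0.505% > 0.5% -> flagged; 100/20000 = exactly 0.5% -> not
        assert flag_hypermodified(self.mat(101), 20_000)["s"]
        assert not flag_hypermodified(self.mat(100), 20_000)["s"]
        assert not flag_hypermodified(self.mat(0), 20_000)["s"]

    def test_gene_counted_once_across_classes(self):
        vals = pd.DataFrame(
            [[1], [1]], index=["g0:mutation", "g0:deletion"], columns=["s"]
        )
        # one distinct gene / 300 = 0.33% -> not flagged; double counting
        # the two classes would give 0.67% and flip the flag
        flags = flag_hypermodified(EventMatrix(vals), genome_size=300)
        assert not flags["s"]

    def test_bad_genome_size(self):
        with pytest.raises(ConfigError):
            flag_hypermodified(self.mat(5), 0)


def test_cnv_round_trip_recovers_truth(cnv_cohort):
    """Planted segments -> gene CNV -> binarize reproduces the truth rows."""
    from altexpress import assign_gene_cnv, binarize_cnv

    cnv = assign_gene_cnv(cnv_cohort.segments, cnv_cohort.gene_models)
    amp, dele = binarize_cnv(cnv)
    for eid in cnv_cohort.truth_events.events:
        cls = eid.rsplit(":", 1)[1]
        block = amp if cls == "amplification" else dele
        rec = block.values.loc[eid].reindex(cnv_cohort.truth_events.samples)
        truth = cnv_cohort.truth_events.values.loc[eid]
        assert (rec.to_numpy() == truth.to_numpy()).all()
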