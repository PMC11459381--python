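import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spikequant.io_ingest import CountTable, InputError
from spikequant.quantify import (EstimateSet, StandardDropout,
                                 build_abundance_matrix,
                                 percent_error_summary, standard_reads,
                                 volumetric_estimate)
from spikequant.synthetic import SimulationConfig, simulate_study

from conftest import make_sample, make_standard


class TestVolumetricEstimate:
    def test_basic_arithmetic(self):
        assert volumetric_estimate(100, 1e6, 50, 2) == 1e6

    def test_zero_numerator(self):
        assert volumetric_estimate(0, 1e6, 50, 2) == 0.0
        assert volumetric_estimate(0, 123.0, 7, 0.5) == 0.0

    def test_spreadsheet_oracle(self):
        # independent arithmetic: 37 * 4.94e6 / (121 * 1.8)
        expected = 37 * 4.94e6 / (121 * 1.8)
        assert volumetric_estimate(37, 4.94e6, 121, 1.8) == \
            pytest.approx(expected, rel=1e-12)

    def test_standard_dropout_signal(self):
        with pytest.raises(StandardDropout):
            volumetric_estimate(100, 1e6, 0, 2)

    @pytest.mark.parametrize("kwargs", [
        dict(r_ij=1, c_s=0, r_sj=1, v_j=1),
        dict(r_ij=1, c_s=1, r_sj=1, v_j=0),
        dict(r_ij=-1, c_s=1, r_sj=1, v_j=1),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InputError):
            volumetric_estimate(**kwargs)

    @given(r=st.integers(0, 10**6), c=st.floats(1e3, 1e9),
           rs=st.integers(1, 10**5), v=st.floats(0.1, 10),
           k=st.integers(2, 50))
    def test_scale_equivariance(self, r, c, rs, v, k):
        base = volumetric_estimate(r, c, rs, v)
        # scaling all reads by k: unchanged
        assert volumetric_estimate(k * r, c, k * rs, v) == \
            pytest.approx(base, rel=1e-9)
        # scaling only community reads: scales by k
        assert volumetric_estimate(k * r, c, rs, v) == \
            pytest.approx(k * base, rel=1e-9)
        # doubling volume halves it
        assert volumetric_estimate(r, c, rs, 2 * v) == \
            pytest.approx(base / 2, rel=1e-9)


class TestStandardReads:
    def test_sum_across_split_asvs(self):
        table = CountTable(["x", "y"], ["s1"], np.array([[40], [10]]))
        std = make_standard("S", 1e6, ("x", "y"))
        assert standard_reads(table, std, "s1") == 50

    def test_absent_asv_counts_zero(self):
        table = CountTable(["x"], ["s1"], np.array([[40]]))
        std = make_standard("S", 1e6, ("nope",))
        assert standard_reads(table, std, "s1") == 0

    def test_overlapping_standards_rejected_at_build(self):
        table = CountTable(["x", "a"], ["s1"], np.array([[40], [1]]))
        stds = [make_standard("S1", 1e6, ("x",)),
                make_standard("S2", 1e6, ("x",))]
        with pytest.raises(InputError, match="x"):
            build_abundance_matrix(table, [make_sample("s1", "S1")], stds)


def brute_force_matrix(table, meta, standards):
    """Independent nested-loop recomputation of every estimate set."""
    by_sample = {r.sample_id: r for r in meta}
    std_asvs = {a for s in standards for a in s.asv_ids}
    out = {}
    sites = sorted({r.site_id for r in meta})
    for site in sites:
        recs = sorted((r for r in meta if r.site_id == site),
                      key=lambda r: r.replicate)
        for asv in table.asv_ids:
            if asv in std_asvs:
                continue
            if all(table.reads(asv, s) == 0 for s in table.sample_ids):
                continue
            ests = []
            for rec in recs:
                for std in standards:
                    r_sj = sum(table.reads(a, rec.sample_id)
                               for a in std.asv_ids)
                    if r_sj == 0:
                        continue
                    val = table.reads(asv, rec.sample_id) * \
                        std.copies_added / (r_sj * rec.volume_L)
                    ests.append((rec.replicate, std.name, val))
            if ests:
                vals = [v for _, _, v in ests]
                out[(site, asv)] = (sorted(ests), sum(vals) / len(vals))
    return out


class TestBuildAbundanceMatrix:
    def test_nine_estimates_per_set(self, site_counts):
        table, meta, standards = site_counts
        matrix = build_abundance_matrix(table, meta, standards)
        assert set(matrix.sets) == {("S001", "A"), ("S001", "B")}
        for es in matrix.sets.values():
            assert es.n == 9
            vals = [v for _, _, v in es.estimates]
            assert es.mean == pytest.approx(np.mean(vals))
            assert es.min <= es.mean <= es.max

    def test_one_dropout_gives_n8(self, site_counts):
        table, meta, standards = site_counts
        table.counts[3, 1] = 0  # sB in replicate 2
        matrix = build_abundance_matrix(table, meta, standards)
        for es in matrix.sets.values():
            assert es.n == 8
            assert not any(r == 2 and s == "stdB"
                           for r, s, _ in es.estimates)
        assert matrix.dropouts == [{
            "site_id": "S001", "sample_id": "S001R2", "replicate": 2,
            "standard": "stdB", "reason": "zero standard reads"}]

    def test_symmetric_replicates_collapse_range(self):
        asvs = ["A", "sA", "sB"]
        samples = ["S1R1", "S1R2", "S1R3"]
        counts = np.array([[100] * 3, [50] * 3, [25] * 3])
        table = CountTable(asvs, samples, counts)
        meta = [make_sample(f"S1R{r}", "S1", r) for r in (1, 2, 3)]
        stds = [make_standard("a", 1e6, ("sA",)),
                make_standard("b", 5e5, ("sB",))]
        matrix = build_abundance_matrix(table, meta, stds)
        es = matrix.sets[("S1", "A")]
        assert es.min == es.max == es.mean

    def test_brute_force_oracle_2x4x2(self):
        """2 sites x 4 ASVs x 2 standards: exact nested-loop equality."""
        rng = np.random.default_rng(11)
        asvs = ["A", "B", "C", "D", "s1", "s2"]
        samples = [f"S{i}R{r}" for i in (1, 2) for r in (1, 2, 3)]
        counts = rng.integers(0, 200, size=(6, 6))
        counts[4:, :] = rng.integers(20, 80, size=(2, 6))
        table = CountTable(asvs, samples, counts)
        meta = [make_sample(f"S{i}R{r}", f"S{i}", r,
                            volume_L=1.5 + 0.25 * r)
                for i in (1, 2) for r in (1, 2, 3)]
        stds = [make_standard("alpha", 2.5e6, ("s1",)),
                make_standard("beta", 1.1e6, ("s2",))]
        matrix = build_abundance_matrix(table, meta, stds)
        oracle = brute_force_matrix(table, meta, stds)
        assert set(matrix.sets) == set(oracle)
        for key, es in matrix.sets.items():
            ests, mean = oracle[key]
            assert sorted(es.estimates) == ests  # bit-exact
            assert es.mean == mean

    def test_all_zero_everywhere_asv_excluded(self, site_counts):
        table, meta, standards = site_counts
        table.counts[1, :] = 0  # B zero everywhere
        matrix = build_abundance_matrix(table, meta, standards)
        assert set(matrix.sets) == {("S001", "A")}

    def test_site_excluded_when_all_standards_drop(self, site_counts):
        table, meta, standards = site_counts
        table.counts[2:, :] = 0  # all standard reads zero
        matrix = build_abundance_matrix(table, meta, standards)
        assert matrix.sets == {}
        assert matrix.excluded_sites[0]["site_id"] == "S001"

    def test_missing_metadata_sample_named(self, site_counts):
        table, _, standards = site_counts
        meta = [make_sample("S001R1", "S001", 1)]
        with pytest.raises(InputError, match="S001R2"):
            build_abundance_matrix(table, meta, standards)

    def test_volume_equivariance(self, site_counts):
        table, meta, standards = site_counts
        m1 = build_abundance_matrix(table, meta, standards)
        meta2 = [make_sample(r.sample_id, r.site_id, r.replicate,
                             volume_L=2 * r.volume_L, lat=r.lat, lon=r.lon)
                 for r in meta]
        m2 = build_abundance_matrix(table, meta2, standards)
        for key in m1.sets:
            assert m2.sets[key].mean == \
                pytest.approx(m1.sets[key].mean / 2, rel=1e-9)

    def test_read_scaling_equivariance(self, site_counts):
        table, meta, standards = site_counts
        m1 = build_abundance_matrix(table, meta, standards)
        scaled = CountTable(table.asv_ids, table.sample_ids,
                            table.counts * 7)
        m2 = build_abundance_matrix(scaled, meta, standards)
        for key in m1.sets:
            assert m2.sets[key].mean == \
                pytest.approx(m1.sets[key].mean, rel=1e-9)

    def test_median_aggregator(self, site_counts):
        table, meta, standards = site_counts
        m = build_abundance_matrix(table, meta, standards,
                                   aggregator="median")
        for es in m.sets.values():
            vals = [v for _, _, v in es.estimates]
            assert es.mean == pytest.approx(np.median(vals))


class TestConvergenceToTruth:
    def test_deep_sequencing_recovers_truth(self):
        """Unbiased simulation at 1e6 reads recovers true copies/L to <2%
        for every community ASV, per site (no replicate noise)."""
        cfg = SimulationConfig(n_sites=4, reads_per_sample=1_000_000,
                               replicate_noise_sigma=0.0,
                               depth_jitter=0.0, volume_jitter=0.0)
        for seed in (0, 1, 2):
            study = simulate_study(cfg, seed=seed)
            matrix = build_abundance_matrix(
                study.reads.counts, study.reads.samples,
                study.reads.standards)
            truth = study.truth.true_copies
            total = {s: truth.loc[s].sum() for s in study.truth.site_ids}
            for (site, asv), es in matrix.sets.items():
                taxon = study.reads.asv_taxon[asv]
                prof = next(t for t in cfg.taxa if t.name == taxon)
                k = int(asv.rsplit("_", 1)[1]) - 1
                expected = truth.loc[site, taxon] * prof.asv_weights()[k]
                if expected / total[site] < 0.01:
                    continue  # below the stated relative-abundance floor
                assert es.mean == pytest.approx(expected, rel=0.02)


class TestPercentErrorSummary:
    def _matrix_of(self, values):
        es = EstimateSet.from_estimates(
            "S1", "A", [(1, "s", v) for v in values])
        from spikequant.quantify import AbundanceMatrix
        return AbundanceMatrix(sets={("S1", "A"): es}, slot_order=[])

    def test_zero_spread(self):
        summ = percent_error_summary(self._matrix_of([100.0] * 9))
        assert np.all(summ.percent_errors == 0)
        assert summ.p_value == 0.0

    def test_symmetric_triple(self):
        summ = percent_error_summary(self._matrix_of([90.0, 100.0, 110.0]))
        assert sorted(summ.percent_errors) == [0.0, 10.0, 10.0]
        assert summ.p_value == pytest.approx(10.0)

    def test_empty_pool_is_error(self):
        m = self._matrix_of([0.0, 0.0])  # zero mean -> skipped
        with pytest.raises(InputError, match="no estimates"):
            percent_error_summary(m)

    def test_subset_filter(self, site_counts):
        table, meta, standards = site_counts
        matrix = build_abundance_matrix(table, meta, standards)
        summ = percent_error_summary(matrix, asv_subset={"A"})
        assert summ.n == 9

    def test_p95_monotone_in_noise(self):
        """Simulation oracle: more replicate noise, larger p95."""
        for seed in (0, 1, 2):
            p95s = []
            for sigma in (0.05, 0.1, 0.2):
                cfg = SimulationConfig(n_sites=8, reads_per_sample=50_000,
                                       replicate_noise_sigma=sigma)
                study = simulate_study(cfg, seed=seed)
                matrix = build_abundance_matrix(
                    study.reads.counts, study.reads.samples,
                    study.reads.standards)
                p95s.append(percent_error_summary(matrix).p_value)
            assert p95s[0] < p95s[1] < p95s[2]
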