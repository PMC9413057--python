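"""Generator contracts: determinism and parameter recovery."""

import math

import numpy as np
import pytest

from asc_time.io import Component, Region
from asc_time.mif import region_proportions
from asc_time.phenotype import ImmunePhenotype, classify_phenotype, \
    mean_til_density
from asc_time.synthetic import (
    ACC_PHENOTYPE_PERCENTS,
    SCCC_PHENOTYPE_PERCENTS,
    gen_mif_cells,
    gen_outcomes,
    gen_repertoire,
    gen_til_fields,
    gen_variants,
)
from asc_time.tmb import filter_somatic, union_tmb


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        for maker in (
            lambda s: gen_til_fields("inflamed", 5, 2.0, seed=s),
            lambda s: gen_mif_cells(500, seed=s),
            lambda s: gen_variants(3, 1, 1, 1, 1, seed=s),
            lambda s: gen_repertoire(30, 0.2, seed=s),
            lambda s: gen_outcomes(50, seed=s),
        ):
            assert maker(123) == maker(123)
            assert maker(123) != maker(124)


class TestTilFields:
    def test_desert_target_recovered(self):
        fields = gen_til_fields("desert", 5, 1.0, seed=7)
        assert classify_phenotype(*mean_til_density(fields)) is \
            ImmunePhenotype.DESERT

    def test_zero_noise_fields_identical(self):
        fields = gen_til_fields("excluded", 5, 0.0, seed=99)
        assert len({(f.intratumoral_density, f.stromal_density)
                    for f in fields}) == 1
        assert fields[0].stromal_density >= 10.0
        assert fields[0].intratumoral_density < 10.0

    def test_inflamed_recovery_rate_under_noise(self):
        # Monte-Carlo check that clipping + per-field noise rarely flips
        # the classification of the 5-field mean
        hits = 0
        n = 1000
        for s in range(n):
            fields = gen_til_fields("inflamed", 5, 2.0, seed=s)
            ph = classify_phenotype(*mean_til_density(fields))
            hits += ph is ImmunePhenotype.INFLAMED
        assert hits / n >= 0.99

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_til_fields("inflamed", 0)
        with pytest.raises(ValueError):
            gen_til_fields("inflamed", 5, noise_sd=-1.0)


class TestMifCells:
    def test_proportion_recovered_within_binomial_error(self):
        n = 10_000
        cells = gen_mif_cells(n, phenotype_props={"Treg": 5.0}, seed=1)
        row = next(r for r in region_proportions(cells)
                   if r.phenotype == "Treg" and r.region == "total")
        se = 100 * math.sqrt(0.05 * 0.95 / n)
        assert abs(row.percent - 5.0) <= 3 * se

    def test_region_geometry(self):
        cells = gen_mif_cells(2000, tumor_fraction=0.6, seed=2)
        tumor = [c for c in cells if c.region is Region.TUMOR]
        stroma = [c for c in cells if c.region is Region.STROMA]
        assert len(tumor) == 1200
        assert all(math.hypot(c.x, c.y) <= 1.0 + 1e-9 for c in tumor)
        assert all(1.0 - 1e-9 <= math.hypot(c.x, c.y) <= 1.5 + 1e-9
                   for c in stroma)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            gen_mif_cells(0)

    def test_proportions_above_100_rejected(self):
        with pytest.raises(ValueError):
            gen_mif_cells(100, phenotype_props={"Treg": 60.0, "NK": 50.0})

    def test_all_zero_proportions_only_background(self):
        cells = gen_mif_cells(5000, phenotype_props={}, seed=3,
                              background_fp_rate=0.002)
        positives = sum(any(c.markers.values()) for c in cells)
        # each of 11 markers flips at 0.2%: expect ~2.2% of cells
        assert positives / 5000 < 0.1

    def test_component_defaults_encode_effect_directions(self):
        assert SCCC_PHENOTYPE_PERCENTS["PDL1+"] > ACC_PHENOTYPE_PERCENTS["PDL1+"]
        assert SCCC_PHENOTYPE_PERCENTS["PD1+"] > ACC_PHENOTYPE_PERCENTS["PD1+"]
        assert SCCC_PHENOTYPE_PERCENTS["Treg"] > ACC_PHENOTYPE_PERCENTS["Treg"]
        assert SCCC_PHENOTYPE_PERCENTS["NK"] < ACC_PHENOTYPE_PERCENTS["NK"]


class TestVariants:
    def test_category_counts_exact(self):
        variants = gen_variants(3, 2, 4, 1, 2, seed=5)
        passed, rejected = filter_somatic(variants)
        assert len(passed) == 5
        reasons = sorted(r for _, r in rejected)
        assert reasons == ["bias", "bias", "reads", "vaf", "vaf", "vaf",
                           "vaf"]
        assert sum(v.consequence == "nonsynonymous" for v in passed) == 3

    def test_shared_trunk_mutations_union(self):
        acc = gen_variants(3, seed=11)
        sccc = gen_variants(2, shared_with=acc, shared_k=2, seed=12)
        acc_pass, _ = filter_somatic(acc)
        sccc_pass, _ = filter_somatic(sccc)
        assert union_tmb(acc_pass, sccc_pass).n_nonsyn_pass == 3

    def test_shared_k_bounds(self):
        acc = gen_variants(2, seed=1)
        with pytest.raises(ValueError):
            gen_variants(5, shared_with=acc, shared_k=3, seed=2)

    def test_unique_identity_keys(self):
        variants = gen_variants(50, 20, 10, 10, 10, seed=8)
        keys = [v.key for v in variants]
        assert len(set(keys)) == len(keys)


class TestOutcomes:
    def test_km_median_recovery_at_n2000(self):
        from asc_time.efficacy import km_fit

        out = gen_outcomes(2000, median_pfs=6.0, median_os=24.0,
                           censor_rate=0.2, seed=3)
        km = km_fit([p.pfs_months for p in out],
                    [p.pfs_event for p in out])
        assert 5.5 <= km.median <= 6.5
        km_os = km_fit([p.os_months for p in out],
                       [p.os_event for p in out])
        assert 22.0 <= km_os.median <= 26.0

    def test_os_never_below_pfs(self):
        out = gen_outcomes(500, seed=9)
        assert all(p.os_months >= p.pfs_months for p in out)

    def test_zero_censoring_all_events_and_sample_median(self):
        out = gen_outcomes(200, censor_rate=0.0, seed=4)
        assert all(p.pfs_event and p.os_event for p in out)
        from asc_time.efficacy import km_fit

        times = sorted(p.pfs_months for p in out)
        km = km_fit([p.pfs_months for p in out],
                    [p.pfs_event for p in out])
        # no censoring: S(t_(k)) = 1 - k/n, so the first time with
        # S <= 0.5 is the (n/2)-th order statistic
        assert km.median == pytest.approx(times[len(times) // 2 - 1])

    def test_pure_pr_cohort_has_full_orr(self):
        from asc_time.efficacy import response_summary
        from asc_time.io import BestResponse

        out = gen_outcomes(60, response_probs={BestResponse.PR: 1.0},
                           seed=6)
        assert response_summary(out).orr_percent == 100

    def test_censor_rate_calibration(self):
        out = gen_outcomes(4000, censor_rate=0.3, seed=21)
        frac = 1 - sum(p.pfs_event for p in out) / 4000
        assert abs(frac - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 4000)
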