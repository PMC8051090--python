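"""TMB CV machinery: thinning simulation, MSD decomposition, intrinsic fit."""

import math

import numpy as np
import pandas as pd
import pytest

from oncoqc.callsets import Call, CallSet, KnownVariant, Variant
from oncoqc.regions import GenomicInterval, RegionSet
from oncoqc.simulate import default_panel_coverages, generate_tmb_catalog
from oncoqc.tmb import (
    CVEstimate,
    IntrinsicModel,
    PanelProjection,
    ThinningConfig,
    TMBCatalog,
    build_base_region,
    cv_from_round_counts,
    fit_intrinsic_model,
    msd_decompose,
    overall_cv,
    project_tmb,
    technical_cv,
)


def make_kps(vafs, start=10):
    return [
        KnownVariant(Variant("chr1", start + 10 * i, "A", "G"), float(v))
        for i, v in enumerate(vafs)
    ]


class TestThinning:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ThinningConfig(k_values=(150,))
        with pytest.raises(ValueError):
            ThinningConfig(n_rounds=0)

    def test_k100_retains_everything(self, rng):
        kps = make_kps([0.2] * 50)
        assert build_base_region(kps, 100, rng).all()

    def test_retention_rates_match_binomial_oracle(self, rng):
        n_high, n_mid = 6000, 4000
        kps = make_kps([0.2] * n_high + [0.07] * n_mid)
        mask = build_base_region(kps, 10, rng)
        got_high = mask[:n_high].sum()
        got_mid = mask[n_high:].sum()
        assert got_high == pytest.approx(
            0.10 * n_high, abs=3 * math.sqrt(n_high * 0.10 * 0.90)
        )
        assert got_mid == pytest.approx(
            0.05 * n_mid, abs=3 * math.sqrt(n_mid * 0.05 * 0.95)
        )

    def test_possible_empty_retention(self, rng):
        kps = make_kps([0.2] * 3)
        masks = [build_base_region(kps, 1, rng) for _ in range(50)]
        assert any(not m.any() for m in masks)  # tiny k can retain nothing


class TestCvFromCounts:
    def test_identical_counts_zero_cv(self):
        counts = np.full((4, 100), 37.0)
        mean, var, cv, *_ = cv_from_round_counts(counts)
        assert (mean, var, cv) == (37.0, 0.0, 0.0)

    def test_formula_hand_arithmetic(self):
        est = CVEstimate(
            panel="P", k=5, cutoff=0.025, mean_count=100.0, variance=25.0,
            mean_tmb=10.0, n_rounds=1, n_replicates=4,
        )
        assert est.cv == pytest.approx(0.05)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            cv_from_round_counts(np.ones((1, 10)))


class TestTechnicalCv:
    REGION = RegionSet.from_pairs([("chr1", 0, 1_000_000)], name="CTR")

    def _cs(self, kps, rep, extra=()):
        calls = [Call(kv.variant, kv.vaf_a / 2) for kv in kps] + list(extra)
        return CallSet("P", "L1", "C", rep, calls=calls)

    def test_identical_replicates_zero_cv(self):
        kps = make_kps(np.linspace(0.06, 0.39, 40))
        css = [self._cs(kps, r) for r in (1, 2, 3)]
        cfg = ThinningConfig(k_values=(20,), n_rounds=50, vaf_cutoffs=(0.025,), seed=0)
        (est,) = technical_cv(css, kps, self.REGION, cfg)
        assert est.cv == 0.0

    def test_requires_replicates(self):
        kps = make_kps([0.2])
        with pytest.raises(ValueError):
            technical_cv([self._cs(kps, 1)], kps, self.REGION)

    def test_ineligible_and_excluded_loci_dropped(self):
        # one eligible KP, one too-high-VAF KP, one germline-excluded call
        kps = make_kps([0.2, 0.9])
        germ = Variant("chr1", 500, "C", "T")
        extra = [Call(germ, 0.25)]
        css = [self._cs(kps, r, extra=extra) for r in (1, 2)]
        cfg = ThinningConfig(k_values=(100,), n_rounds=10, vaf_cutoffs=(0.025,), seed=0)
        (est,) = technical_cv(css, kps, self.REGION, cfg, excluded_variants=[germ])
        # only the eligible KP (retained at k=100) is ever counted
        assert est.mean_count == pytest.approx(1.0)

    def test_fp_floor_reported_separately(self):
        kps = make_kps([0.2] * 10)
        css = [self._cs(kps, r) for r in (1, 2)]
        cfg = ThinningConfig(
            k_values=(5,), n_rounds=20, vaf_cutoffs=(0.025,), seed=0,
            include_k_zero=True,
        )
        ests = technical_cv(css, kps, self.REGION, cfg)
        floors = [e for e in ests if e.is_fp_floor]
        assert len(floors) == 1 and math.isnan(floors[0].cv)
        assert floors[0].mean_count == 0.0  # no injected errors here


def toy_catalog(counts, size=1_000_000, chrom="chrT"):
    """Catalog on a 1-Mb shared region with given per-sample counts placed
    uniformly-deterministically."""
    shared = RegionSet([GenomicInterval(chrom, 0, size)], name="shared")
    rows = []
    rng = np.random.default_rng(0)
    for i, n in enumerate(counts):
        pos = rng.choice(size, size=n, replace=False) + 1
        for p in pos:
            rows.append((f"S{i}", chrom, int(p)))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "pos"])
    return TMBCatalog(
        mutations=df, shared_region=shared,
        samples=pd.Index([f"S{i}" for i in range(len(counts))]),
    )


class TestProjection:
    def test_full_coverage_reproduces_reference(self):
        cat = toy_catalog([10, 25, 40])
        proj = project_tmb(cat, cat.shared_region)
        pd.testing.assert_series_equal(proj.tmb, cat.tmb, check_names=False)

    def test_zero_mutation_sample(self):
        cat = toy_catalog([0, 10])
        proj = project_tmb(cat, cat.shared_region)
        assert proj.tmb.loc["S0"] == 0.0

    def test_counts_match_brute_force(self, rng):
        cat = toy_catalog([50, 80, 120])
        cov = RegionSet.from_pairs([("chrT", 200_000, 600_000)], name="cov")
        proj = project_tmb(cat, cov)
        for s in cat.samples:
            sub = cat.mutations[cat.mutations["sample"] == s]
            manual = sum(
                200_000 < p <= 600_000 for p in sub["pos"]
            )
            assert proj.counts.loc[s] == manual

    def test_undersized_panel_rejected(self):
        cat = toy_catalog([10])
        tiny = RegionSet.from_pairs([("chrT", 0, 100_000)])
        with pytest.raises(ValueError, match="250"):
            project_tmb(cat, tiny)


class TestMSD:
    def _proj(self, cat, tmb_values):
        return PanelProjection(
            panel="X",
            cov=cat.shared_region,
            tmb=pd.Series(tmb_values, index=cat.samples),
            counts=pd.Series(tmb_values, index=cat.samples),
        )

    def test_perfect_projection_zero_components(self):
        cat = toy_catalog([10, 12, 14, 16, 18])
        proj = self._proj(cat, cat.tmb.values)
        (res,) = msd_decompose(proj, cat, group_size=5, outlier_sd=100)
        assert res.msd == res.bias2 == 0.0
        assert res.adj_variance == pytest.approx(0.0)

    def test_hand_summed_msd(self):
        cat = toy_catalog([10, 12, 14, 16, 18])
        ref = cat.tmb.sort_values()
        p = ref.values + np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        proj = self._proj(cat, pd.Series(p, index=ref.index))
        (res,) = msd_decompose(proj, cat, group_size=5, outlier_sd=100)
        assert res.msd == pytest.approx(np.mean([1, 4, 0.25, 9, 2.25]))

    def test_msd_prime_exact_decomposition(self, rng):
        cat = toy_catalog(list(rng.integers(20, 60, size=12)))
        noise = rng.normal(0, 2, size=12)
        proj = self._proj(cat, cat.tmb.values + noise)
        results = msd_decompose(proj, cat, group_size=6, outlier_sd=100)
        for r in results:
            assert r.msd_prime == pytest.approx(r.bias2 + r.var_panel)

    def test_msd_approx_identity_tightens_with_group_homogeneity(self, rng):
        """msd ~ msd' - var(ref) up to 2*(var_ref - cov(ref, panel));
        shrinking the within-group reference spread shrinks the error."""
        errs = []
        for spread in (4.0, 0.5):
            counts = [int(30 + rng.uniform(-spread, spread)) for _ in range(10)]
            cat = toy_catalog(counts)
            proj = self._proj(cat, cat.tmb.values + rng.normal(0, 3, size=10))
            (r,) = msd_decompose(proj, cat, group_size=10, outlier_sd=100)
            errs.append(abs(r.msd - (r.msd_prime - r.var_ref)))
        assert errs[1] < errs[0]

    def test_group_size_floor(self):
        cat = toy_catalog([10, 12, 14])
        with pytest.raises(ValueError):
            msd_decompose(self._proj(cat, cat.tmb.values), cat, group_size=2)


class TestIntrinsicModel:
    def test_exact_proportional_points(self):
        from oncoqc.tmb import MSDResult

        results = []
        for panel, size in (("P1", 1.0), ("P2", 2.0)):
            for g, x in enumerate((10.0, 20.0, 30.0)):
                results.append(
                    MSDResult(
                        panel=panel, group=g, n=100,
                        msd=0, msd_prime=0, bias2=0,
                        adj_variance=1.44 * x / size**2,  # count var = 1.44 * count
                        mean_ref_tmb=x / size, mean_panel_tmb=x / size,
                        var_panel=0, var_ref=0,
                    )
                )
        m = fit_intrinsic_model(results, {"P1": 1.0, "P2": 2.0})
        assert m.slope == pytest.approx(1.44)
        assert m.coef == pytest.approx(1.2)
        assert m.intrinsic_cv(36) == pytest.approx(0.2)

    def test_single_panel_rejected(self):
        from oncoqc.tmb import MSDResult

        res = [
            MSDResult("P1", 0, 10, 0, 0, 0, 1.0, 1.0, 1.0, 0, 0),
            MSDResult("P1", 1, 10, 0, 0, 0, 2.0, 2.0, 2.0, 0, 0),
        ]
        with pytest.raises(ValueError):
            fit_intrinsic_model(res, {"P1": 1.0})

    def test_poisson_thinning_recovers_unit_slope(self):
        cat = generate_tmb_catalog(
            n_samples=800, overdispersion=1.0, rng=3
        )
        covs = default_panel_coverages()
        results, sizes = [], {}
        for name, cov in covs.items():
            proj = project_tmb(cat, cov)
            results += msd_decompose(proj, cat, group_size=100)
            sizes[name] = cov.size_mb
        m = fit_intrinsic_model(results, sizes)
        assert 0.9 <= m.coef <= 1.1

    def test_reference_model_formula(self):
        m = IntrinsicModel.reference()
        assert m.intrinsic_cv(21) == pytest.approx(1.15 / math.sqrt(21))


class TestOverallCv:
    def test_zero_technical_gives_intrinsic(self):
        assert overall_cv(0.0, 0.21) == 0.21

    def test_equal_components_root_two(self):
        assert overall_cv(0.1, 0.1) == pytest.approx(0.1 * math.sqrt(2))

    def test_dominates_each_component(self, rng):
        for _ in range(20):
            a, b = rng.random(2)
            assert overall_cv(a, b) >= max(a, b)
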