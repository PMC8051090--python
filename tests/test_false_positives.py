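"""The three FP-rate estimators and FP recurrence across replicates."""

import numpy as np
import pytest

from oncoqc.callsets import (
    Call,
    CallSet,
    KnownNegativeSet,
    Variant,
    derive_sample_c_negatives,
)
from oncoqc.false_positives import (
    FPMethodUnavailable,
    fp_b_low,
    fp_by_subregion,
    fp_c_only,
    fp_reproducibility,
    fp_via_kn,
)
from oncoqc.regions import RegionError, RegionSet, build_subregions

REGION = RegionSet.from_pairs([("chr1", 0, 1_000_000)], name="CTR")


def cs(calls, sample="B", lab="L1", rep=1):
    return CallSet("P", lab, sample, rep, calls=calls)


def call(pos, vaf, chrom="chr1"):
    return Call(Variant(chrom, pos, "A", "G"), vaf)


class TestViaKN:
    def test_rate_definition(self):
        kn = KnownNegativeSet(("chr1", p) for p in range(1, 4_000_001))
        calls = [call(10, 0.02), call(20, 0.03)]
        res = fp_via_kn(cs(calls, sample="A"), kn)
        assert res.n_fp == 2 and res.denominator == 4_000_000
        assert res.rate_per_million == pytest.approx(0.5)

    def test_no_overlap_zero(self):
        kn = KnownNegativeSet([("chr1", 999)])
        res = fp_via_kn(cs([call(10, 0.02)], sample="A"), kn)
        assert res.n_fp == 0 and res.rate_per_million == 0.0

    def test_empty_kn_rejected(self):
        with pytest.raises(ValueError):
            fp_via_kn(cs([], sample="A"), KnownNegativeSet())

    def test_recovers_injected_rate(self, small_bundle):
        b = small_bundle
        region = b.regions.panel_in_ctr
        kn = b.truth.kn.restrict(region)
        tot = sum(
            fp_via_kn(c.restrict(region), kn).n_fp
            for c in b.callsets_for(sample="A")
        )
        denom = kn.count * len(b.callsets_for(sample="A")) / 1e6
        truth_rate = b.cfg.fp_rate_in_ctr * 1e6
        se = np.sqrt(max(tot, 1)) / denom
        assert tot / denom == pytest.approx(truth_rate, abs=3 * se)


class TestBLow:
    def test_low_vaf_call_is_fp(self):
        res = fp_b_low(cs([call(10, 0.05)]), [cs([], rep=2)], REGION)
        assert res.n_fp == 1

    def test_high_vaf_call_is_not_fp(self):
        res = fp_b_low(cs([call(10, 0.50)]), [cs([], rep=2)], REGION)
        assert res.n_fp == 0

    def test_sibling_high_vaf_excludes(self):
        # flagged at 5% but seen at 45% in a sibling replicate: not an FP
        sibling = cs([call(10, 0.45)], rep=2)
        res = fp_b_low(cs([call(10, 0.05)]), [sibling], REGION)
        assert res.n_fp == 0

    def test_window_boundaries_inclusive(self):
        res = fp_b_low(
            cs([call(10, 0.01), call(20, 0.10), call(30, 0.101)]),
            [cs([], rep=2)],
            REGION,
        )
        assert res.n_fp == 2

    def test_missing_siblings_warns(self):
        with pytest.warns(UserWarning):
            fp_b_low(cs([call(10, 0.05)]), [], REGION)

    def test_requires_sample_b(self):
        with pytest.raises(ValueError):
            fp_b_low(cs([], sample="C"), [], REGION)


class TestCOnly:
    def _libs(self, sample, calls_per_rep):
        return [
            cs(calls, sample=sample, rep=i + 1)
            for i, calls in enumerate(calls_per_rep)
        ]

    def test_call_in_a_library_not_fp(self):
        c_lib = cs([call(10, 0.02)], sample="C")
        a_libs = self._libs("A", [[call(10, 0.04)], [], [], []])
        b_libs = self._libs("B", [[], [], [], []])
        assert fp_c_only(c_lib, a_libs, b_libs, REGION).n_fp == 0

    def test_call_nowhere_else_is_fp(self):
        c_lib = cs([call(10, 0.02)], sample="C")
        a_libs = self._libs("A", [[], [], [], []])
        b_libs = self._libs("B", [[], [], [], []])
        assert fp_c_only(c_lib, a_libs, b_libs, REGION).n_fp == 1

    def test_b_library_counts_only_above_ten_percent(self):
        c_lib = cs([call(10, 0.02)], sample="C")
        b_low = self._libs("B", [[call(10, 0.05)], [], [], []])
        assert fp_c_only(c_lib, self._libs("A", [[]]), b_low, REGION).n_fp == 1
        b_high = self._libs("B", [[call(10, 0.45)], [], [], []])
        assert fp_c_only(c_lib, self._libs("A", [[]]), b_high, REGION).n_fp == 0

    def test_missing_companions_unavailable(self):
        with pytest.raises(FPMethodUnavailable):
            fp_c_only(cs([], sample="C"), [], self._libs("B", [[]]), REGION)

    def test_recovers_lab_specific_error_rate(self, small_bundle):
        """Library-specific injected errors are recovered; shared true
        variants are not flagged."""
        b = small_bundle
        region = b.regions.panel_in_ctr
        tot = denom = 0
        for c_lib in b.callsets_for(sample="C"):
            res = fp_c_only(
                c_lib,
                b.callsets_for(sample="A", lab=c_lib.lab),
                b.callsets_for(sample="B", lab=c_lib.lab),
                region,
            )
            tot += res.n_fp
            denom += res.denominator
        rate = tot / (denom / 1e6)
        truth_rate = b.cfg.fp_rate_in_ctr * 1e6
        se = np.sqrt(max(tot, 1)) / (denom / 1e6)
        assert rate == pytest.approx(truth_rate, abs=3 * se)


class TestSubregions:
    def _setup(self):
        hccr = RegionSet.from_pairs([("chr1", 0, 3_000_000)])
        ctr = RegionSet.from_pairs([("chr1", 0, 1_000_000)], name="CTR")
        panel = RegionSet.from_pairs([("chr1", 0, 4_000_000)])
        return build_subregions(panel, ctr, hccr)

    def test_viakn_outside_ctr_rejected(self):
        sub = self._setup()
        kn = KnownNegativeSet([("chr1", 5)])
        with pytest.raises(RegionError):
            fp_by_subregion(sub, "viaKN", [0.0], cs([], sample="A"), kn=kn)

    def test_calls_partition_into_parts(self):
        sub = self._setup()
        b_calls = cs([call(100, 0.05), call(2_000_000, 0.05), call(3_500_000, 0.05)])
        results = fp_by_subregion(
            sub, "B_low", [0.0], b_calls, sibling_b_cs=[cs([], rep=2)]
        )
        by_label = {r.region_label: r.n_fp for r in results}
        assert by_label == {"in_CTR": 1, "in_HCCR_out_CTR": 1, "rest": 1}

    def test_rate_non_increasing_in_cutoff(self):
        sub = self._setup()
        b_calls = cs([call(100, 0.012), call(200, 0.03), call(300, 0.06)])
        results = fp_by_subregion(
            sub, "B_low", [0.01, 0.025, 0.05], b_calls,
            sibling_b_cs=[cs([], rep=2)],
        )
        in_ctr = [r.n_fp for r in results if r.region_label == "in_CTR"]
        assert in_ctr == sorted(in_ctr, reverse=True)

    def test_higher_error_rate_outside_ctr_recovered(self, small_bundle):
        b = small_bundle
        sub = b.regions.subregions
        in_ctr = out_ctr = 0
        for b_cs in b.callsets_for(sample="B"):
            siblings = [
                s
                for s in b.callsets_for(sample="B", lab=b_cs.lab)
                if s.replicate != b_cs.replicate
            ]
            in_ctr += fp_b_low(b_cs, siblings, sub.in_ctr).n_fp
            out_ctr += fp_b_low(b_cs, siblings, sub.in_hccr_out_ctr).n_fp
        rate_in = in_ctr / sub.in_ctr.size_mb
        rate_out = out_ctr / sub.in_hccr_out_ctr.size_mb
        ratio_truth = b.cfg.fp_rate_out_ctr / b.cfg.fp_rate_in_ctr
        assert rate_out > rate_in
        se_ratio = (rate_out / rate_in) * np.sqrt(1 / max(in_ctr, 1) + 1 / max(out_ctr, 1))
        assert rate_out / rate_in == pytest.approx(ratio_truth, abs=3 * se_ratio)


class TestRecurrence:
    def test_shared_fp_fully_recurrent(self):
        key = ("chr1", 10, "A", "G")
        res = fp_reproducibility([[key], [key], [key]])
        assert res.recurrence_fraction == 1.0
        assert res.recurring_keys == [key]

    def test_no_fps_undefined(self):
        res = fp_reproducibility([[], []])
        assert res.recurrence_fraction is None

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            fp_reproducibility([[("chr1", 1, "A", "G")]])

    def test_independent_errors_match_collision_expectation(self, rng):
        """With n errors per replicate uniform over N loci (q = n/N), the
        fraction of distinct flagged loci seen in >= 2 of R replicates is
        P(>=2 hits) / P(>=1 hit) for hits ~ Binomial(R, q)."""
        n_loci, n_per_rep, n_rep = 3000, 60, 4
        fracs = []
        for _ in range(40):
            reps = [
                [("chr1", int(p), "A", "G") for p in rng.choice(n_loci, n_per_rep, replace=False)]
                for _ in range(n_rep)
            ]
            fracs.append(fp_reproducibility(reps).recurrence_fraction)
        observed = np.mean(fracs)
        q = n_per_rep / n_loci
        p_any = 1 - (1 - q) ** n_rep
        p_two = p_any - n_rep * q * (1 - q) ** (n_rep - 1)
        expected = p_two / p_any
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert observed == pytest.approx(expected, abs=max(3 * se, 0.01))

    def test_study_fps_mostly_irreproducible(self, small_bundle):
        """Injected errors are library-specific, so recurrence stays low."""
        b = small_bundle
        region = b.regions.panel_in_ctr
        kn = b.truth.kn.restrict(region)
        per_rep = []
        for c in b.callsets_for(sample="A", lab="LAB1"):
            per_rep.append(fp_via_kn(c.restrict(region), kn).fp_keys)
        res = fp_reproducibility(per_rep)
        if res.recurrence_fraction is not None:
            assert res.recurrence_fraction < 0.5
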