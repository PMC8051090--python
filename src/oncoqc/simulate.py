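"""Synthetic reference-sample studies with known generative parameters.

The generator emulates the statistical structure of a multi-laboratory
oncopanel validation study built on characterized reference samples:

* **Sample A** — a pooled cancer-cell-line DNA sample carrying thousands of
  known positives (KPs) whose VAF spectrum is concentrated at low allele
  fractions (about 7% of KPs in 1–2.5%, 18% in 2.5–5%, 25% in 5–10%, 18% in
  10–20%, remainder above 20%), plus a catalog of known-negative (KN)
  positions covering half of the consensus targeted region (CTR).
* **Sample B** — a diploid normal background with germline variants at 50%
  (heterozygous) or 100% (homozygous) VAF.
* **Sample C** — a 1:1 mass mixture of A and B: every A-origin KP appears at
  half its sample-A VAF; B's heterozygous/homozygous germline alleles drop
  to 25%/50%.
* **Spike-in** — sample B carrying synthetic hotspot variants at a fixed
  design VAF of 5%.

Each of ``n_labs`` laboratories prepares ``n_reps`` replicate libraries per
sample.  Per library, each expected variant's alternate-read count is drawn
``Binomial(depth, expected VAF)`` with the library depth drawn from a
negative binomial around the configured mean (sample C is sequenced twice as
deep); a call is emitted iff the observed VAF clears the panel's reporting
threshold and a minimum alternate-read count — the mechanism behind the
threshold "boundary effect".  False positives are injected as a Poisson
process over the panel target, at separate per-base rates inside and outside
the CTR, with VAFs drawn from an exponential tail truncated above 10% (the
regime where real panels report essentially no FPs).

Every generated call is traceable to a KP, germline, spike-in or injected
error origin, and the closed-form detection probability of the generative
model is exposed so estimators can be validated against analytic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callsets import Call, CallSet, KnownNegativeSet, KnownVariant, Variant
from .regions import GenomicInterval, PanelSubregions, RegionSet, build_subregions
from .tmb import TMBCatalog

__all__ = [
    "GeneratorConfig",
    "StudyRegions",
    "StudyTruth",
    "StudyBundle",
    "generate_truth",
    "generate_callsets",
    "generate_study",
    "generate_tmb_catalog",
    "default_panel_coverages",
    "detection_probability",
    "fp_vaf_survival",
    "expected_fp_count",
]

_BASES = np.array(list("ACGT"))

SAMPLES: tuple[str, ...] = ("A", "B", "C", "SPIKEIN")


@dataclass(frozen=True)
class GeneratorConfig:
    """Generative parameters of a synthetic study.

    The defaults define the reference study conditions: a 30-Mb toy genome
    with a 2-Mb CTR inside a 4-Mb high-confidence coding region (HC_CR), KP
    density matching the characterized reference sample (~2 KPs per kb of
    CTR), a KN catalog covering half the CTR, three laboratories with four
    replicate libraries per sample, and per-base error rates four-fold
    higher outside the CTR than inside.
    """

    # toy genome and regions (BED-style 0-based half-open pairs)
    chrom_sizes: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
    )
    hccr_intervals: tuple[tuple[str, int, int], ...] = (
        ("chr1", 1_000_000, 2_400_000),
        ("chr2", 1_000_000, 2_400_000),
        ("chr3", 1_000_000, 2_200_000),
    )
    ctr_intervals: tuple[tuple[str, int, int], ...] = (
        ("chr1", 1_100_000, 1_800_000),
        ("chr2", 1_100_000, 1_800_000),
        ("chr3", 1_100_000, 1_700_000),
    )
    panel_intervals: tuple[tuple[str, int, int], ...] = (
        ("chr1", 1_000_000, 2_600_000),
        ("chr2", 1_050_000, 1_900_000),
        ("chr3", 900_000, 1_750_000),
    )
    panel: str = "PANEL1"

    # truth content
    n_kp: int = 4000
    vaf_spectrum: tuple[tuple[float, float, float], ...] = (
        (0.010, 0.025, 0.07),
        (0.025, 0.050, 0.18),
        (0.050, 0.100, 0.25),
        (0.100, 0.200, 0.18),
        (0.200, 0.750, 0.32),
    )
    indel_fraction: float = 0.012  # non-SNV share (small indels + MNVs)
    n_kn: int = 1_000_000
    n_germline: int = 3000
    germline_hom_fraction: float = 0.4
    n_spikein: int = 300
    spikein_vaf: float = 0.05

    # study layout
    n_labs: int = 3
    n_reps: int = 4

    # sequencing / calling model
    depth: float = 1500.0
    depth_dispersion: float | None = 50.0  # NB size; None = fixed depth
    c_depth_factor: float = 2.0  # sample C sequenced twice as deep
    min_alt_reads: int = 3
    vaf_threshold: float = 0.01  # panel reporting threshold

    # error model
    fp_rate_in_ctr: float = 4e-6  # per base per library
    fp_rate_out_ctr: float = 1.6e-5
    fp_vaf_scale: float = 0.02
    fp_vaf_max: float = 0.10
    batch_effect: tuple[tuple[str, float], ...] | None = None

    @property
    def labs(self) -> tuple[str, ...]:
        return tuple(f"LAB{i + 1}" for i in range(self.n_labs))

    def lab_modifier(self, lab: str) -> float:
        if self.batch_effect is None:
            return 1.0
        return dict(self.batch_effect).get(lab, 1.0)


@dataclass
class StudyRegions:
    panel: RegionSet
    ctr: RegionSet
    hccr: RegionSet
    subregions: PanelSubregions

    @property
    def panel_in_ctr(self) -> RegionSet:
        return self.subregions.in_ctr

    @property
    def panel_out_ctr(self) -> RegionSet:
        return self.panel.subtract(self.ctr, name="panel_out_CTR")


@dataclass
class StudyTruth:
    kps: list[KnownVariant]
    kn: KnownNegativeSet
    germline: list[tuple[Variant, float]]  # (variant, VAF in pure sample B)
    spikein: list[KnownVariant]

    @property
    def germline_variants(self) -> list[Variant]:
        return [v for v, _ in self.germline]

    def truth_for(self, sample: str) -> list[KnownVariant]:
        """The known-positive catalog applicable to one sample."""
        if sample in ("A", "C"):
            return self.kps
        if sample == "SPIKEIN":
            return self.spikein
        raise ValueError(f"no KP catalog for sample {sample!r}")

    def expected_vafs(self, sample: str) -> dict[tuple, float]:
        """Expected VAF per variant key for one reference sample."""
        out: dict[tuple, float] = {}
        if sample == "A":
            out.update({kv.variant.key: kv.vaf_a for kv in self.kps})
        elif sample == "B":
            out.update({v.key: vaf for v, vaf in self.germline})
        elif sample == "C":
            out.update({kv.variant.key: kv.vaf_a / 2.0 for kv in self.kps})
            out.update({v.key: vaf / 2.0 for v, vaf in self.germline})
        elif sample == "SPIKEIN":
            out.update({v.key: vaf for v, vaf in self.germline})
            out.update({kv.variant.key: kv.vaf_a for kv in self.spikein})
        else:
            raise ValueError(f"unknown sample {sample!r}")
        return out


@dataclass
class StudyBundle:
    """A complete synthetic study plus its generative ground truth."""

    cfg: GeneratorConfig
    regions: StudyRegions
    truth: StudyTruth
    callsets: dict[tuple[str, str, int], CallSet]  # (lab, sample, rep)
    seed: int | None = None

    def callsets_for(
        self, sample: str | None = None, lab: str | None = None
    ) -> list[CallSet]:
        out = [
            cs
            for (l, s, _r), cs in sorted(self.callsets.items())
            if (sample is None or s == sample) and (lab is None or l == lab)
        ]
        return out

    def classify_call(self, sample: str, key: tuple) -> str:
        """Origin of a called variant: kp / germline / spikein / error."""
        if sample in ("A", "C") and key in {kv.variant.key for kv in self.truth.kps}:
            return "kp"
        if sample in ("B", "C", "SPIKEIN") and key in {
            v.key for v in self.truth.germline_variants
        }:
            return "germline"
        if sample == "SPIKEIN" and key in {
            kv.variant.key for kv in self.truth.spikein
        }:
            return "spikein"
        return "error"


# ---------------------------------------------------------------------------
# allele construction
# ---------------------------------------------------------------------------

def _random_alleles(
    rng: np.random.Generator, n: int, indel_fraction: float
) -> tuple[list[str], list[str]]:
    """Random (ref, alt) pairs: mostly SNVs with a small indel/MNV share."""
    refs: list[str] = []
    alts: list[str] = []
    kinds = rng.random(n)
    for i in range(n):
        base = str(rng.choice(_BASES))
        if kinds[i] < indel_fraction:
            sub = rng.random()
            if sub < 0.375:  # insertion
                ins = "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
                refs.append(base)
                alts.append(base + ins)
            elif sub < 0.75:  # deletion
                extra = "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
                refs.append(base + extra)
                alts.append(base)
            else:  # dinucleotide MNV
                b2 = str(rng.choice(_BASES))
                a1 = str(rng.choice(_BASES[_BASES != base]))
                a2 = str(rng.choice(_BASES[_BASES != b2]))
                refs.append(base + b2)
                alts.append(a1 + a2)
        else:
            alt = str(rng.choice(_BASES[_BASES != base]))
            refs.append(base)
            alts.append(alt)
    return refs, alts


def _spectrum_vafs(
    rng: np.random.Generator,
    n: int,
    spectrum: Sequence[tuple[float, float, float]],
) -> np.ndarray:
    weights = np.array([w for _, _, w in spectrum], dtype=float)
    weights = weights / weights.sum()
    strata = rng.choice(len(spectrum), size=n, p=weights)
    lows = np.array([lo for lo, _, _ in spectrum])[strata]
    highs = np.array([hi for _, hi, _ in spectrum])[strata]
    return lows + rng.random(n) * (highs - lows)


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def generate_truth(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[StudyRegions, StudyTruth]:
    """Build regions, KP/KN catalogs, germline background and spike-ins."""
    genome = dict(cfg.chrom_sizes)
    hccr = RegionSet.from_pairs(cfg.hccr_intervals, name="HC_CR")
    ctr = RegionSet.from_pairs(cfg.ctr_intervals, name="CTR")
    panel = RegionSet.from_pairs(cfg.panel_intervals, name=f"panel:{cfg.panel}")
    for chrom, _s, e in cfg.hccr_intervals + cfg.ctr_intervals + cfg.panel_intervals:
        if chrom not in genome or e > genome[chrom]:
            raise ValueError(f"region interval exceeds chromosome {chrom}")
    subregions = build_subregions(panel, ctr, hccr)
    regions = StudyRegions(panel=panel, ctr=ctr, hccr=hccr, subregions=subregions)

    ctr_size = ctr.size_bases
    if cfg.n_kp + cfg.n_kn > ctr_size:
        raise ValueError("n_kp + n_kn exceeds the CTR size")

    # KP and KN positions: disjoint by construction
    offsets = rng.choice(ctr_size, size=cfg.n_kp + cfg.n_kn, replace=False)
    kp_off, kn_off = offsets[: cfg.n_kp], offsets[cfg.n_kp :]
    kp_chroms, kp_pos0 = ctr.positions_from_offsets(np.sort(kp_off))
    kn_chroms, kn_pos0 = ctr.positions_from_offsets(np.sort(kn_off))

    vafs = _spectrum_vafs(rng, cfg.n_kp, cfg.vaf_spectrum)
    refs, alts = _random_alleles(rng, cfg.n_kp, cfg.indel_fraction)
    kps = [
        KnownVariant(
            Variant(str(kp_chroms[i]), int(kp_pos0[i]) + 1, refs[i], alts[i]),
            vaf_a=float(vafs[i]),
            provenance="cellline",
        )
        for i in range(cfg.n_kp)
    ]
    kn = KnownNegativeSet.from_arrays(kn_chroms, kn_pos0 + 1)

    # germline background over HC_CR (may coincide with KN positions — that
    # is exactly why the mixture sample needs its own derived KN list)
    kp_loci = {(kv.variant.chrom, kv.variant.pos) for kv in kps}
    germline: list[tuple[Variant, float]] = []
    taken: set[tuple[str, int]] = set(kp_loci)
    hccr_size = hccr.size_bases
    g_refs, g_alts = _random_alleles(rng, cfg.n_germline, cfg.indel_fraction)
    n_placed = 0
    while n_placed < cfg.n_germline:
        batch = cfg.n_germline - n_placed
        off = rng.integers(0, hccr_size, size=batch)
        chroms, pos0 = hccr.positions_from_offsets(off)
        for c, p0 in zip(chroms, pos0):
            locus = (str(c), int(p0) + 1)
            if locus in taken:
                continue
            taken.add(locus)
            vaf = 1.0 if rng.random() < cfg.germline_hom_fraction else 0.5
            germline.append(
                (Variant(locus[0], locus[1], g_refs[n_placed], g_alts[n_placed]), vaf)
            )
            n_placed += 1
            if n_placed == cfg.n_germline:
                break

    # spike-ins inside the panel's CTR portion, at the fixed design VAF
    spike_region = subregions.in_ctr
    s_refs, s_alts = _random_alleles(rng, cfg.n_spikein, 0.0)
    spikein: list[KnownVariant] = []
    n_placed = 0
    while n_placed < cfg.n_spikein:
        batch = cfg.n_spikein - n_placed
        off = rng.integers(0, spike_region.size_bases, size=batch)
        chroms, pos0 = spike_region.positions_from_offsets(off)
        for c, p0 in zip(chroms, pos0):
            locus = (str(c), int(p0) + 1)
            if locus in taken:
                continue
            taken.add(locus)
            spikein.append(
                KnownVariant(
                    Variant(locus[0], locus[1], s_refs[n_placed], s_alts[n_placed]),
                    vaf_a=cfg.spikein_vaf,
                    provenance="spikein",
                )
            )
            n_placed += 1
            if n_placed == cfg.n_spikein:
                break

    return regions, StudyTruth(kps=kps, kn=kn, germline=germline, spikein=spikein)


# ---------------------------------------------------------------------------
# call-set generation
# ---------------------------------------------------------------------------

def _truncexp_vafs(
    rng: np.random.Generator, n: int, lo: float, hi: float, scale: float
) -> np.ndarray:
    """Exponential-tailed VAFs truncated to [lo, hi] (inverse CDF)."""
    u = rng.random(n)
    z = 1.0 - math.exp(-(hi - lo) / scale)
    return lo - scale * np.log(1.0 - u * z)


def _draw_depths(
    rng: np.random.Generator, n: int, mean: float, dispersion: float | None
) -> np.ndarray:
    if dispersion is None:
        return np.full(n, max(1, round(mean)), dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=n), 1)


def generate_callsets(
    regions: StudyRegions,
    truth: StudyTruth,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[tuple[str, str, int], CallSet]:
    """Simulate every (lab, sample, replicate) library of the study."""
    panel = regions.panel
    truth_loci = (
        {(kv.variant.chrom, kv.variant.pos) for kv in truth.kps}
        | {(v.chrom, v.pos) for v in truth.germline_variants}
        | {(kv.variant.chrom, kv.variant.pos) for kv in truth.spikein}
    )
    fp_zones = (
        (regions.panel_in_ctr, cfg.fp_rate_in_ctr),
        (regions.panel_out_ctr, cfg.fp_rate_out_ctr),
    )

    # per-sample expected variants restricted to the panel target
    per_sample: dict[str, tuple[list[Variant], np.ndarray]] = {}
    for sample in SAMPLES:
        evaf_map = truth.expected_vafs(sample)
        variants = [
            Variant(*key[:4])
            for key in evaf_map
            if panel.contains(key[0], key[1] - 1)
        ]
        variants.sort()
        evafs = np.array([evaf_map[v.key] for v in variants], dtype=float)
        per_sample[sample] = (variants, evafs)

    callsets: dict[tuple[str, str, int], CallSet] = {}
    for lab in cfg.labs:
        modifier = min(cfg.lab_modifier(lab), 1.0)
        for sample in SAMPLES:
            variants, evafs = per_sample[sample]
            depth_mean = cfg.depth * (
                cfg.c_depth_factor if sample == "C" else 1.0
            )
            for rep in range(1, cfg.n_reps + 1):
                n = len(variants)
                depths = _draw_depths(rng, n, depth_mean, cfg.depth_dispersion)
                alt_reads = rng.binomial(depths, evafs)
                obs = alt_reads / depths
                called = (alt_reads >= cfg.min_alt_reads) & (
                    obs >= cfg.vaf_threshold
                )
                if modifier < 1.0:
                    called &= rng.random(n) < modifier
                calls = [
                    Call(variants[i], float(obs[i]))
                    for i in np.flatnonzero(called)
                ]
                # injected errors (library-specific, low-VAF)
                seen = {c.variant.key for c in calls}
                for zone, rate in fp_zones:
                    if zone.is_empty or rate <= 0:
                        continue
                    n_fp = rng.poisson(rate * zone.size_bases)
                    if n_fp == 0:
                        continue
                    off = rng.integers(0, zone.size_bases, size=n_fp)
                    chroms, pos0 = zone.positions_from_offsets(off)
                    fvafs = _truncexp_vafs(
                        rng, n_fp, cfg.vaf_threshold, cfg.fp_vaf_max,
                        cfg.fp_vaf_scale,
                    )
                    frefs, falts = _random_alleles(rng, n_fp, 0.0)
                    for j in range(n_fp):
                        locus = (str(chroms[j]), int(pos0[j]) + 1)
                        if locus in truth_loci:
                            continue
                        v = Variant(locus[0], locus[1], frefs[j], falts[j])
                        if v.key in seen:
                            continue
                        seen.add(v.key)
                        calls.append(Call(v, float(fvafs[j])))
                calls.sort(key=lambda c: c.variant)
                callsets[(lab, sample, rep)] = CallSet(
                    panel=cfg.panel,
                    lab=lab,
                    sample=sample,
                    replicate=rep,
                    calls=calls,
                )
    return callsets


def generate_study(
    cfg: GeneratorConfig | None = None, seed: int | None = 0
) -> StudyBundle:
    """Generate a full study bundle; identical seeds give identical bundles."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    regions, truth = generate_truth(cfg, rng)
    callsets = generate_callsets(regions, truth, cfg, rng)
    return StudyBundle(
        cfg=cfg, regions=regions, truth=truth, callsets=callsets, seed=seed
    )


# ---------------------------------------------------------------------------
# analytic oracles for the generative model
# ---------------------------------------------------------------------------

def detection_probability(
    evaf: np.ndarray | float,
    depth_mean: float,
    depth_dispersion: float | None,
    threshold: float,
    min_alt: int,
    modifier: float = 1.0,
) -> np.ndarray:
    """Exact per-library detection probability under the generative model.

    Marginalizes the binomial read-sampling tail over the negative-binomial
    depth distribution:  P(call) = sum_d P(D = d) * P(Bin(d, v) >= k(d))
    with k(d) = max(ceil(threshold * d), min_alt).  ``threshold`` may be an
    artificial cutoff above the panel's reporting threshold, which yields
    the probability that the call survives that cutoff.
    """
    evaf = np.atleast_1d(np.asarray(evaf, dtype=float))
    if depth_dispersion is None:
        depths = np.array([max(1, round(depth_mean))])
        pmf = np.array([1.0])
    else:
        nb = stats.nbinom(depth_dispersion, depth_dispersion / (depth_dispersion + depth_mean))
        lo = max(int(nb.ppf(1e-8)), 1)
        hi = int(nb.isf(1e-8))
        depths = np.arange(lo, hi + 1)
        pmf = nb.pmf(depths)
        pmf = pmf / pmf.sum()
    k = np.maximum(np.ceil(threshold * depths - 1e-9), min_alt)  # (m,)
    tail = stats.binom.sf(k[:, None] - 1, depths[:, None], evaf[None, :])
    return np.clip(modifier * (pmf @ tail), 0.0, 1.0)


def fp_vaf_survival(
    cutoff: float, threshold: float, vaf_max: float, scale: float
) -> float:
    """P(injected-error VAF >= cutoff) under the truncated exponential."""
    if cutoff <= threshold:
        return 1.0
    if cutoff > vaf_max:
        return 0.0
    z = 1.0 - math.exp(-(vaf_max - threshold) / scale)
    return (
        math.exp(-(cutoff - threshold) / scale)
        - math.exp(-(vaf_max - threshold) / scale)
    ) / z


def expected_fp_count(
    region_bases: int, rate: float, cfg: GeneratorConfig, cutoff: float = 0.0
) -> float:
    """Expected injected errors per library in a region, above a cutoff."""
    return (
        rate
        * region_bases
        * fp_vaf_survival(cutoff, cfg.vaf_threshold, cfg.fp_vaf_max, cfg.fp_vaf_scale)
    )


# ---------------------------------------------------------------------------
# pan-cancer mutation catalog (for the intrinsic-CV analysis)
# ---------------------------------------------------------------------------

DEFAULT_SHARED_REGION = RegionSet.from_pairs(
    [("chrE", 0, 22_000_000)], name="CDS_x_CTR"
)

#: Six synthetic panel coverages (panel ∩ CTR ∩ CDS), all above the 250-kb
#: projection floor, as disjoint blocks of the shared region.
_PANEL_COV_SIZES_MB: tuple[float, ...] = (0.25, 0.30, 0.40, 0.50, 0.60, 0.80)


def default_panel_coverages(
    shared_region: RegionSet = DEFAULT_SHARED_REGION,
) -> dict[str, RegionSet]:
    """Disjoint panel coverage regions laid out inside the shared region."""
    chrom = shared_region.chroms[0]
    start = shared_region.intervals[0].start
    out: dict[str, RegionSet] = {}
    cursor = start
    for i, size_mb in enumerate(_PANEL_COV_SIZES_MB):
        size = int(size_mb * 1e6)
        name = f"P{i + 1}"
        out[name] = RegionSet(
            [GenomicInterval(chrom, cursor, cursor + size)], name=name
        )
        cursor += size + 1_000_000  # gap between panels
    if cursor > shared_region.intervals[0].end:
        raise ValueError("panel coverages exceed the shared region")
    return out


def generate_tmb_catalog(
    n_samples: int = 2400,
    tmb_range: tuple[float, float] = (5.0, 40.0),
    overdispersion: float = 1.0,
    shared_region: RegionSet = DEFAULT_SHARED_REGION,
    rng: np.random.Generator | int | None = None,
) -> TMBCatalog:
    """Synthetic pan-cancer mutation catalog with tunable overdispersion.

    Each sample's mutations arrive as a compound-Poisson process over the
    shared region: mutation events are uniform in position, and an event is
    a tight doublet (two adjacent mutations, emulating clustered mutational
    processes) with probability pi = (phi - 1) / (3 - phi) where ``phi`` is
    the target overdispersion.  A panel sampling a fraction f of the region
    then sees an adjusted count variance of phi * (1 - f) times the mean
    count, so for small panels the fitted intrinsic slope recovers ``phi``.
    ``phi`` must lie in [1, 3).
    """
    if not 1.0 <= overdispersion < 3.0:
        raise ValueError("overdispersion must be in [1, 3)")
    rng = np.random.default_rng(rng)
    if n_samples == 0:
        empty = pd.DataFrame({"sample": [], "chrom": [], "pos": []})
        return TMBCatalog(
            mutations=empty, shared_region=shared_region, samples=pd.Index([])
        )
    pi = (overdispersion - 1.0) / (3.0 - overdispersion)
    size_mb = shared_region.size_mb
    tmb_targets = rng.uniform(tmb_range[0], tmb_range[1], size=n_samples)
    lam_events = tmb_targets * size_mb / (1.0 + pi)
    n_events = rng.poisson(lam_events)

    sample_ids = np.repeat(np.arange(n_samples), n_events)
    total = int(n_events.sum())
    offsets = rng.integers(0, shared_region.size_bases, size=total)
    is_doublet = rng.random(total) < pi

    # doublet partner sits on the adjacent base (kept inside the region)
    partner = np.where(
        offsets + 1 < shared_region.size_bases, offsets + 1, offsets - 1
    )
    all_offsets = np.concatenate([offsets, partner[is_doublet]])
    all_samples = np.concatenate([sample_ids, sample_ids[is_doublet]])

    chroms, pos0 = shared_region.positions_from_offsets(all_offsets)
    labels = pd.Index([f"S{i:05d}" for i in range(n_samples)])
    df = pd.DataFrame(
        {
            "sample": labels[all_samples],
            "chrom": chroms.astype(str),
            "pos": pos0 + 1,
        }
    )
    return TMBCatalog(mutations=df, shared_region=shared_region, samples=labels)
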