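"""Tumor-mutational-burden (TMB) coefficient-of-variation analysis.

Two CV components are modelled:

* **Technical CV** — run-to-run variability of a panel's reported mutation
  count across library replicates, measured by a KP-thinning simulation that
  dilutes the reference sample's unrealistically dense truth set down to
  clinically plausible TMB levels.  For each retention level ``k``, k% of
  eligible known positives with sample-A VAF in (10%, 40%] are retained and
  0.5*k% of those with VAF in [5%, 10%]; all other KP loci are excluded from
  the report region.  Counting reported calls above a VAF cutoff per
  replicate over many simulation rounds gives

      CV = sqrt(overall average of variance) / overall average of mean count.

* **Intrinsic CV** — the variability of panel-projected TMB around the
  exome-wide TMB that is due purely to the panel sampling a small genomic
  subset.  For each panel, the mean squared deviation (MSD) between
  reference and panel TMB over groups of samples is decomposed into a mean
  bias and an adjusted variance (panel variance minus reference variance).
  Converting the adjusted variance to mutation-count scale and regressing it
  through the origin on the mean mutation count yields a slope whose square
  root is the intrinsic coefficient:  intrinsic CV(c) = coef / sqrt(c).

The overall CV combines the two components in quadrature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .callsets import CallSet, KnownVariant, Variant
from .regions import RegionSet

__all__ = [
    "ThinningConfig",
    "CVEstimate",
    "TMBCatalog",
    "PanelProjection",
    "MSDResult",
    "IntrinsicModel",
    "REFERENCE_INTRINSIC_COEF",
    "build_base_region",
    "cv_from_round_counts",
    "technical_cv",
    "project_tmb",
    "msd_decompose",
    "fit_intrinsic_model",
    "overall_cv",
]

logger = logging.getLogger(__name__)

#: Replication-mode intrinsic coefficient (sqrt of the regression slope
#: fitted on the consortium's pan-cancer catalog).  Estimators never use
#: this constant implicitly; it is available for reproducing published
#: intrinsic-CV curves without refitting.
REFERENCE_INTRINSIC_COEF: float = 1.15

#: Sample-A VAF band retained at the full k% rate.
FULL_RATE_BAND: tuple[float, float] = (0.10, 0.40)  # (open, closed]
#: Sample-A VAF band retained at half rate, 0.5*k%.
HALF_RATE_BAND: tuple[float, float] = (0.05, 0.10)  # [closed, closed]


@dataclass(frozen=True)
class ThinningConfig:
    """Configuration of the KP-thinning simulation."""

    k_values: tuple[int, ...] = (1, 2, 5, 10, 20)
    n_rounds: int = 5000
    vaf_cutoffs: tuple[float, ...] = (0.025, 0.05)
    include_k_zero: bool = False  # k = 0 rounds report the FP floor only
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(not 0 <= k <= 100 for k in self.k_values):
            raise ValueError("retention percentages must lie in [0, 100]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class CVEstimate:
    """Technical-CV estimate for one (k, cutoff) combination."""

    panel: str
    k: int
    cutoff: float
    mean_count: float
    variance: float
    mean_tmb: float
    n_rounds: int
    n_replicates: int
    is_fp_floor: bool = False  # k = 0: counts are FPs only, CV not defined
    round_means: np.ndarray | None = field(default=None, repr=False)
    round_vars: np.ndarray | None = field(default=None, repr=False)

    @property
    def cv(self) -> float:
        if self.is_fp_floor or self.mean_count == 0:
            return float("nan")
        return math.sqrt(self.variance) / self.mean_count

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "k": self.k,
            "cutoff": self.cutoff,
            "mean_count": self.mean_count,
            "variance": self.variance,
            "cv": self.cv,
            "mean_tmb": self.mean_tmb,
            "n_rounds": self.n_rounds,
            "fp_floor": self.is_fp_floor,
        }


def cv_from_round_counts(
    counts: np.ndarray,
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """CV from a matrix of reported counts, replicates x simulation rounds.

    Per round, the mean and the (ddof=1) variance across replicates are
    taken; the CV is the square root of the round-averaged variance over the
    round-averaged mean.  Returns ``(mean, variance, cv, round_means,
    round_vars)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("counts must be (n_replicates >= 2, n_rounds)")
    round_means = counts.mean(axis=0)
    round_vars = counts.var(axis=0, ddof=1)
    avg_mean = float(round_means.mean())
    avg_var = float(round_vars.mean())
    cv = math.sqrt(avg_var) / avg_mean if avg_mean > 0 else float("nan")
    return avg_mean, avg_var, cv, round_means, round_vars


def _eligibility(kps: Sequence[KnownVariant], region: RegionSet):
    """Split targeted KPs into the retained-eligible band and the rest."""
    eligible: list[KnownVariant] = []
    ineligible_pos: set[tuple[str, int]] = set()
    for kv in kps:
        v = kv.variant
        if not region.contains(v.chrom, v.pos - 1):
            continue
        if HALF_RATE_BAND[0] <= kv.vaf_a <= FULL_RATE_BAND[1]:
            eligible.append(kv)
        else:
            ineligible_pos.add((v.chrom, v.pos))
    return eligible, ineligible_pos


def build_base_region(
    eligible_kps: Sequence[KnownVariant],
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One simulation round's retention mask over the eligible KPs.

    KPs with sample-A VAF in (10%, 40%] are retained with probability k%,
    those in [5%, 10%] with probability 0.5*k%; the non-retained loci are
    excluded from the report region for the round.
    """
    vafs = np.array([kv.vaf_a for kv in eligible_kps], dtype=float)
    p = np.where(vafs > FULL_RATE_BAND[0], k / 100.0, 0.5 * k / 100.0)
    mask = rng.random(len(vafs)) < p
    if len(vafs) and not mask.any():
        logger.warning("k=%d retained no KPs in this round", k)
    return mask


def technical_cv(
    callsets: Sequence[CallSet],
    kps: Sequence[KnownVariant],
    region: RegionSet,
    cfg: ThinningConfig = ThinningConfig(),
    excluded_variants: Iterable[Variant] = (),
    rng: np.random.Generator | int | None = None,
) -> list[CVEstimate]:
    """Technical run-to-run CV of reported counts via KP thinning.

    ``callsets`` are the mixture-sample (C) library replicates of one panel
    at one site; ``region`` is the panel's CTR portion (the report region
    before thinning).  ``excluded_variants`` (normally the diploid
    background's germline catalog) are removed from the report region
    outright, as are KP loci outside the eligible [5%, 40%] sample-A band.
    Reported counts per replicate include calls at retained KP loci plus any
    other surviving calls (FPs, uncharacterized variants) above the cutoff.
    """
    if len(callsets) < 2:
        raise ValueError("technical CV needs >= 2 library replicates")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    panel = callsets[0].panel

    eligible, ineligible_pos = _eligibility(kps, region)
    always_excluded = {
        (v.chrom, v.pos)
        for v in excluded_variants
        if region.contains(v.chrom, v.pos - 1)
    } | ineligible_pos
    elig_index = {
        (kv.variant.chrom, kv.variant.pos): i for i, kv in enumerate(eligible)
    }
    n_elig = len(eligible)
    vafs_a = np.array([kv.vaf_a for kv in eligible], dtype=float)

    restricted = [cs.restrict(region) for cs in callsets]
    n_rep = len(restricted)

    estimates: list[CVEstimate] = []
    k_values = tuple(cfg.k_values)
    if cfg.include_k_zero and 0 not in k_values:
        k_values = (0,) + k_values

    for cutoff in cfg.vaf_cutoffs:
        # per replicate: detection flag per eligible KP locus + residual count
        det = np.zeros((n_rep, n_elig), dtype=np.float32)
        other = np.zeros(n_rep, dtype=np.float64)
        for r, cs in enumerate(restricted):
            for c in cs.calls:
                if c.vaf < cutoff:
                    continue
                locus = (c.variant.chrom, c.variant.pos)
                idx = elig_index.get(locus)
                if idx is not None:
                    det[r, idx] = 1.0
                elif locus not in always_excluded:
                    other[r] += 1.0
        for k in k_values:
            p = np.where(vafs_a > FULL_RATE_BAND[0], k / 100.0, 0.5 * k / 100.0)
            retain = (
                rng.random((n_elig, cfg.n_rounds)) < p[:, None]
            ).astype(np.float32)
            counts = det @ retain + other[:, None]  # (n_rep, n_rounds)
            avg_mean, avg_var, _cv, round_means, round_vars = cv_from_round_counts(
                counts
            )
            n_retained = retain.sum(axis=0)
            report_bases = (
                region.size_bases
                - len(always_excluded)
                - (n_elig - n_retained)
            )
            mean_tmb = avg_mean / float(report_bases.mean() / 1e6)
            estimates.append(
                CVEstimate(
                    panel=panel,
                    k=k,
                    cutoff=cutoff,
                    mean_count=avg_mean,
                    variance=avg_var,
                    mean_tmb=mean_tmb,
                    n_rounds=cfg.n_rounds,
                    n_replicates=n_rep,
                    is_fp_floor=(k == 0),
                    round_means=np.asarray(round_means, dtype=float),
                    round_vars=np.asarray(round_vars, dtype=float),
                )
            )
    return estimates


# ---------------------------------------------------------------------------
# intrinsic CV: panel projection, MSD decomposition, regression
# ---------------------------------------------------------------------------

@dataclass
class TMBCatalog:
    """Per-sample somatic mutation catalog with an exome-scale baseline.

    ``mutations`` is a tidy frame (columns ``sample``, ``chrom``, ``pos``
    with 1-based positions); ``shared_region`` is the region over which the
    baseline (reference) TMB rate is defined — mutations per Mb of the
    shared region.
    """

    mutations: pd.DataFrame
    shared_region: RegionSet
    samples: pd.Index | None = None

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "pos"}
        if not required <= set(self.mutations.columns):
            raise ValueError(f"mutations frame needs columns {sorted(required)}")
        if self.samples is None:
            self.samples = pd.Index(pd.unique(self.mutations["sample"]))

    def counts_in(self, region: RegionSet) -> pd.Series:
        """Mutation count per sample inside ``region`` (zeros included)."""
        df = self.mutations.reset_index(drop=True)
        inside = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            inside[sub.index] = region.contains_many(
                str(chrom), sub["pos"].to_numpy() - 1
            )
        counts = df.loc[inside].groupby("sample").size()
        return counts.reindex(self.samples, fill_value=0).astype(float)

    @property
    def tmb(self) -> pd.Series:
        """Reference TMB rate: mutations per Mb of the shared region."""
        return self.counts_in(self.shared_region) / self.shared_region.size_mb


@dataclass
class PanelProjection:
    """TMB of each catalog sample projected onto a panel's covered region."""

    panel: str
    cov: RegionSet  # panel target ∩ CTR ∩ CDS
    tmb: pd.Series  # per-sample panel TMB rate (mutations / Mb of cov)
    counts: pd.Series

    @property
    def size_mb(self) -> float:
        return self.cov.size_mb


def project_tmb(
    catalog: TMBCatalog,
    panel_cov: RegionSet,
    min_cov_bases: int = 250_000,
) -> PanelProjection:
    """Project every catalog sample's TMB onto a panel's covered region.

    Panels covering fewer than ``min_cov_bases`` of the shared region are
    rejected: tiny panels sample far too few mutations for rate estimation.
    """
    if panel_cov.size_bases < min_cov_bases:
        raise ValueError(
            f"panel coverage {panel_cov.size_bases} bp below the "
            f"{min_cov_bases} bp minimum for TMB projection"
        )
    counts = catalog.counts_in(panel_cov)
    return PanelProjection(
        panel=panel_cov.name or "panel",
        cov=panel_cov,
        tmb=counts / panel_cov.size_mb,
        counts=counts,
    )


@dataclass
class MSDResult:
    """MSD decomposition for one TMB-sorted group of samples."""

    panel: str
    group: int
    n: int
    msd: float
    msd_prime: float
    bias2: float
    adj_variance: float  # var(panel TMB) - var(reference TMB), per group
    mean_ref_tmb: float
    mean_panel_tmb: float
    var_panel: float
    var_ref: float

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "group": self.group,
            "n": self.n,
            "msd": self.msd,
            "msd_prime": self.msd_prime,
            "bias2": self.bias2,
            "adj_variance": self.adj_variance,
            "mean_ref_tmb": self.mean_ref_tmb,
            "mean_panel_tmb": self.mean_panel_tmb,
        }


def msd_decompose(
    proj: PanelProjection,
    catalog: TMBCatalog,
    group_size: int = 100,
    tmb_range: tuple[float, float] = (5.0, 40.0),
    outlier_sd: float = 5.0,
) -> list[MSDResult]:
    """Group samples by reference TMB and decompose MSD per group.

    Samples with reference TMB inside ``tmb_range`` are sorted by TMB and
    chunked into consecutive groups of ``group_size`` (a trailing partial
    group is dropped).  Within each group, samples whose deviation
    (reference minus panel TMB) lies more than ``outlier_sd`` group standard
    deviations from the group mean deviation are excluded and logged.

    MSD' substitutes the group-mean reference TMB for each sample's own, so
    it decomposes exactly into squared mean bias plus the panel-TMB variance
    (population variances throughout); MSD itself is approximately MSD'
    minus the reference-TMB variance when the group is TMB-homogeneous.
    """
    if group_size < 3:
        raise ValueError("group size must be >= 3")
    ref = catalog.tmb
    sel = ref[(ref >= tmb_range[0]) & (ref <= tmb_range[1])].sort_values()
    results: list[MSDResult] = []
    n_groups = len(sel) // group_size
    n_outliers = 0
    for g in range(n_groups):
        members = sel.index[g * group_size : (g + 1) * group_size]
        r = ref.loc[members].to_numpy()
        p = proj.tmb.loc[members].to_numpy()
        dev = r - p
        sd = dev.std()
        if sd > 0:
            keep = np.abs(dev - dev.mean()) <= outlier_sd * sd
            n_outliers += int((~keep).sum())
            r, p = r[keep], p[keep]
        msd = float(np.mean((r - p) ** 2))
        mean_r, mean_p = float(r.mean()), float(p.mean())
        var_p = float(p.var())  # population variance: exact decomposition
        var_r = float(r.var())
        msd_prime = float(np.mean((mean_r - p) ** 2))
        bias2 = (mean_r - mean_p) ** 2
        results.append(
            MSDResult(
                panel=proj.panel,
                group=g,
                n=len(r),
                msd=msd,
                msd_prime=msd_prime,
                bias2=bias2,
                adj_variance=var_p - var_r,
                mean_ref_tmb=mean_r,
                mean_panel_tmb=mean_p,
                var_panel=var_p,
                var_ref=var_r,
            )
        )
    if n_outliers:
        logger.info(
            "%s: excluded %d outlier sample(s) beyond %.0f group SDs",
            proj.panel,
            n_outliers,
            outlier_sd,
        )
    return results


@dataclass
class IntrinsicModel:
    """Through-origin fit of adjusted count variance on mean count.

    ``intrinsic_cv(c) = coef / sqrt(c)`` with ``coef = sqrt(slope)``; the
    free-intercept fit is reported alongside as a diagnostic of the
    proportionality assumption.
    """

    slope: float
    coef: float
    r2: float
    n_points: int
    slope_free: float = float("nan")
    intercept_free: float = float("nan")

    def intrinsic_cv(self, mean_count: float) -> float:
        if mean_count <= 0:
            raise ValueError("mean mutation count must be positive")
        return self.coef / math.sqrt(mean_count)

    @classmethod
    def reference(cls) -> "IntrinsicModel":
        """Replication-mode model with the published coefficient."""
        coef = REFERENCE_INTRINSIC_COEF
        return cls(slope=coef**2, coef=coef, r2=float("nan"), n_points=0)


def fit_intrinsic_model(
    msd_results: Sequence[MSDResult],
    panel_sizes: Mapping[str, float],
    weights: np.ndarray | None = None,
) -> IntrinsicModel:
    """Fit the intrinsic-variance slope over pooled per-group points.

    For each group of each panel, x = mean panel TMB x panel size (the mean
    mutation count) and y = adjusted TMB variance x panel size squared (the
    adjusted count variance).  Groups from at least two panels must be
    pooled.  The slope is the through-origin least-squares estimate
    (optionally weighted); a non-positive slope invalidates the model.
    """
    panels = {r.panel for r in msd_results}
    if len(panels) < 2:
        raise ValueError("pool groups from >= 2 panels before fitting")
    x = np.array(
        [r.mean_panel_tmb * panel_sizes[r.panel] for r in msd_results], dtype=float
    )
    y = np.array(
        [r.adj_variance * panel_sizes[r.panel] ** 2 for r in msd_results], dtype=float
    )
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    slope = float(np.sum(w * x * y) / np.sum(w * x * x))
    if slope <= 0:
        raise ValueError(f"non-positive fitted slope {slope}: model invalid")
    resid = y - slope * x
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    import statsmodels.api as sm

    free = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return IntrinsicModel(
        slope=slope,
        coef=math.sqrt(slope),
        r2=r2,
        n_points=len(x),
        slope_free=float(free.params[1]),
        intercept_free=float(free.params[0]),
    )


def overall_cv(cv_technical: float, cv_intrinsic: float) -> float:
    """Combine independent technical and intrinsic CV components in
    quadrature."""
    return math.hypot(cv_technical, cv_intrinsic)
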