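"""VAF-stratified sensitivity with clustered-bootstrap confidence intervals.

Sensitivity is the fraction of known positives (KPs) targeted by a panel
that are detected, pooled over library replicates: summed detections divided
by (number of KPs x number of libraries).  Stratification uses the
*expected* (truth) VAF of each KP — not the observed VAF — so that the
boundary effect of reporting thresholds can be analysed: a KP whose expected
VAF sits just above a cutoff is detected only when its sampled observed VAF
clears the cutoff.

Library replicates within a laboratory are not independent, so confidence
intervals use a two-stage clustered bootstrap: laboratories are resampled
with replacement, then libraries within each selected laboratory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .callsets import CallSet, KnownVariant
from .regions import RegionSet

__all__ = [
    "VafStratum",
    "DEFAULT_STRATA",
    "SPIKEIN_STRATUM",
    "SensitivityResult",
    "DetectionStudy",
    "detection_study",
    "estimate_sensitivity",
    "bootstrap_ci",
    "cutoff_sweep",
    "expected_vaf",
]


@dataclass(frozen=True)
class VafStratum:
    """A VAF interval ``(low, high]``; the lowest study stratum is closed
    below so that the strata partition the assessed range exactly."""

    low: float
    high: float
    label: str = ""
    closed_low: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError(f"invalid stratum bounds [{self.low}, {self.high}]")

    def contains(self, vaf: np.ndarray | float) -> np.ndarray | bool:
        vaf = np.asarray(vaf, dtype=float)
        if self.closed_low:
            res = (vaf >= self.low) & (vaf <= self.high)
        else:
            res = (vaf > self.low) & (vaf <= self.high)
        return res if res.ndim else bool(res)

    def __str__(self) -> str:
        return self.label or f"({self.low:g}, {self.high:g}]"


#: The four study VAF ranges: 1-2.5%, 2.5-5%, 5-10%, 10-20%.
DEFAULT_STRATA: tuple[VafStratum, ...] = (
    VafStratum(0.01, 0.025, "1-2.5%", closed_low=True),
    VafStratum(0.025, 0.05, "2.5-5%"),
    VafStratum(0.05, 0.10, "5-10%"),
    VafStratum(0.10, 0.20, "10-20%"),
)

#: The spike-in sample carries a single stratum around its design VAF of 5%.
SPIKEIN_STRATUM = VafStratum(0.025, 0.10, "spike-in ~5%", closed_low=True)


def expected_vaf(kv: KnownVariant, sample: str) -> float:
    """Expected VAF of a known positive in a given reference sample.

    Sample A carries the catalog VAF; the 1:1 mixture sample C carries half
    of it; spike-in positives carry their design VAF (stored as ``vaf_a``).
    """
    if sample == "C":
        return kv.vaf_a / 2.0
    return kv.vaf_a


@dataclass
class DetectionStudy:
    """Per-library x per-KP detection flags for one panel/sample."""

    flags: np.ndarray  # bool, shape (n_libraries, n_kp)
    labs: np.ndarray  # str, shape (n_libraries,)
    truth: list[KnownVariant]
    expected_vafs: np.ndarray  # shape (n_kp,)
    panel: str = ""
    sample: str = ""

    @property
    def n_libraries(self) -> int:
        return self.flags.shape[0]

    @property
    def n_kp(self) -> int:
        return self.flags.shape[1]


def detection_study(
    callsets: Sequence[CallSet],
    truth: Sequence[KnownVariant],
    region: RegionSet | None = None,
    cutoff: float = 0.0,
) -> DetectionStudy:
    """Match each library against the truth catalog.

    ``region`` restricts both truth and calls (KPs outside the panel's
    assessed region are not targeted and must not enter the denominator).
    ``cutoff`` applies an artificial VAF filter to the calls before matching.
    """
    if not callsets:
        raise ValueError("no call sets supplied")
    sample = callsets[0].sample
    if region is not None:
        truth = [
            kv
            for kv in truth
            if region.contains(kv.variant.chrom, kv.variant.pos - 1)
        ]
    keys = [kv.variant.key for kv in truth]
    flags = np.zeros((len(callsets), len(keys)), dtype=bool)
    labs = []
    for i, cs in enumerate(callsets):
        work = cs.restrict(region) if region is not None else cs
        if cutoff > 0.0:
            work = work.filter_vaf(cutoff)
        call_keys = work.keys()
        flags[i] = [k in call_keys for k in keys]
        labs.append(cs.lab)
    evafs = np.array([expected_vaf(kv, sample) for kv in truth], dtype=float)
    return DetectionStudy(
        flags=flags,
        labs=np.asarray(labs, dtype=object),
        truth=list(truth),
        expected_vafs=evafs,
        panel=callsets[0].panel,
        sample=sample,
    )


@dataclass
class SensitivityResult:
    panel: str
    sample: str
    stratum: VafStratum
    n_kp: int
    n_libraries: int
    detected: int
    sensitivity: float
    ci_low: float
    ci_high: float
    assessable: bool = True
    degenerate_ci: bool = False
    cutoff: float = 0.0

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "sample": self.sample,
            "stratum": str(self.stratum),
            "cutoff": self.cutoff,
            "n_kp": self.n_kp,
            "n_libraries": self.n_libraries,
            "detected": self.detected,
            "sensitivity": self.sensitivity,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "assessable": self.assessable,
        }


def bootstrap_ci(
    flags: np.ndarray,
    labs: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, bool]:
    """Two-stage clustered percentile bootstrap of pooled sensitivity.

    Stage one resamples laboratories with replacement; stage two resamples
    libraries within each selected laboratory.  Returns ``(low, high,
    degenerate)`` where ``degenerate`` marks the single-lab single-library
    case in which the interval collapses to the point estimate.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable percentile interval")
    rng = np.random.default_rng(rng)
    labs = np.asarray(labs, dtype=object)
    lab_members = [np.flatnonzero(labs == lab) for lab in pd.unique(labs)]
    n_labs = len(lab_members)
    if n_labs == 1 and len(labs) == 1:
        point = float(flags.mean())
        return point, point, True
    # pooled sensitivity is the unweighted mean of per-library means when
    # every library is scored on the same KP set
    lib_means = flags.mean(axis=1)
    stats = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        chosen = rng.integers(0, n_labs, size=n_labs)
        rows: list[np.ndarray] = []
        for c in chosen:
            members = lab_members[c]
            rows.append(members[rng.integers(0, len(members), size=len(members))])
        stats[b] = lib_means[np.concatenate(rows)].mean()
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), False


def estimate_sensitivity(
    study: DetectionStudy,
    stratum: VafStratum,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    cutoff: float = 0.0,
) -> SensitivityResult:
    """Pooled sensitivity in one expected-VAF stratum, with a 95% (by
    default) clustered-bootstrap CI.

    A stratum containing no targeted KPs is flagged not-assessable (the
    "N/A" situation for panels whose reporting threshold sits above the
    stratum).
    """
    mask = np.asarray(stratum.contains(study.expected_vafs))
    n_kp = int(mask.sum())
    if n_kp == 0:
        return SensitivityResult(
            panel=study.panel,
            sample=study.sample,
            stratum=stratum,
            n_kp=0,
            n_libraries=study.n_libraries,
            detected=0,
            sensitivity=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            assessable=False,
            cutoff=cutoff,
        )
    sub = study.flags[:, mask]
    detected = int(sub.sum())
    sens = detected / (n_kp * study.n_libraries)
    lo, hi, degenerate = bootstrap_ci(
        sub, study.labs, n_boot=n_boot, alpha=alpha, rng=rng
    )
    return SensitivityResult(
        panel=study.panel,
        sample=study.sample,
        stratum=stratum,
        n_kp=n_kp,
        n_libraries=study.n_libraries,
        detected=detected,
        sensitivity=float(sens),
        ci_low=min(lo, sens),
        ci_high=max(hi, sens),
        degenerate_ci=degenerate,
        cutoff=cutoff,
    )


def cutoff_sweep(
    callsets: Sequence[CallSet],
    truth: Sequence[KnownVariant],
    cutoffs: Sequence[float],
    stratum: VafStratum,
    region: RegionSet | None = None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sensitivity after applying each artificial VAF cutoff in turn.

    Calls below the cutoff are removed before matching, reproducing the
    boundary-effect analysis: sensitivity is non-increasing in the cutoff.
    Returns a tidy frame (one row per cutoff).
    """
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be sorted ascending")
    rng = np.random.default_rng(rng)
    rows = []
    for cutoff in cutoffs:
        study = detection_study(callsets, truth, region=region, cutoff=cutoff)
        res = estimate_sensitivity(
            study, stratum, n_boot=n_boot, alpha=alpha, rng=rng, cutoff=cutoff
        )
        rows.append(res.to_dict())
    return pd.DataFrame(rows)
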