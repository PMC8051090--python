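"""Three false-positive-rate estimators for reference-sample call sets.

``viaKN``
    Counts calls landing on characterized known-negative (KN) positions.
    The KN list is defined only inside the consensus targeted region (CTR);
    the rate is FP calls per million KN positions.
``B_low``
    In the diploid normal sample B, any call with VAF in [1%, 10%] is an FP
    (true germline alleles sit near 50% or 100%), except calls whose variant
    is seen above 10% VAF in another B replicate at the same site — those are
    plausibly real alleles with distorted measurement.  The denominator is
    the evaluated region size, so the rate is FPs per Mb.
``C_only``
    In the mixture sample C, a call is an FP if it is absent from all of the
    lab's sample-A libraries (at any VAF) and from all of its sample-B
    libraries above 10% VAF, since every true C variant must originate in A
    or B.  This method cannot see systematic (panel-bias) errors, which are
    shared across the samples.  The denominator is the region size.

Only ``B_low`` and ``C_only`` extend outside the CTR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .callsets import CallSet, KnownNegativeSet
from .regions import PanelSubregions, RegionError, RegionSet

__all__ = [
    "FPResult",
    "FPMethodUnavailable",
    "fp_via_kn",
    "fp_b_low",
    "fp_c_only",
    "fp_by_subregion",
    "fp_reproducibility",
    "FPReproducibility",
    "B_LOW_WINDOW",
    "B_HIGH_VAF",
]

#: VAF window (inclusive both ends) marking normal-sample calls as FPs.
B_LOW_WINDOW: tuple[float, float] = (0.01, 0.10)
#: VAF above which a sample-B call counts as a real allele for exclusions.
B_HIGH_VAF: float = 0.10


class FPMethodUnavailable(RuntimeError):
    """The estimator's required companion libraries are missing."""


@dataclass
class FPResult:
    panel: str
    sample: str
    method: str  # "viaKN" | "B_low" | "C_only"
    region_label: str
    cutoff: float
    n_fp: int
    denominator: int  # KN positions (viaKN) or bases (B_low / C_only)
    fp_keys: list = None  # the flagged variant keys, for inspection

    @property
    def rate_per_million(self) -> float:
        """FPs per million KN positions (viaKN) or per Mb (B_low/C_only)."""
        return self.n_fp / (self.denominator / 1e6)

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "sample": self.sample,
            "method": self.method,
            "region": self.region_label,
            "cutoff": self.cutoff,
            "n_fp": self.n_fp,
            "denominator": self.denominator,
            "rate_per_million": self.rate_per_million,
        }


def fp_via_kn(
    cs: CallSet,
    kn: KnownNegativeSet,
    cutoff: float = 0.0,
    region_label: str = "CTR",
) -> FPResult:
    """FP rate from calls overlapping known-negative positions.

    ``cs`` and ``kn`` should both already be restricted to the CTR.  Multiple
    alternate alleles at one KN position count as distinct FP calls.
    """
    if kn.count == 0:
        raise ValueError("empty known-negative set")
    fp_keys = [
        c.variant.key
        for c in cs.calls
        if c.vaf >= cutoff and kn.contains(c.variant.chrom, c.variant.pos)
    ]
    return FPResult(
        panel=cs.panel,
        sample=cs.sample,
        method="viaKN",
        region_label=region_label,
        cutoff=cutoff,
        n_fp=len(fp_keys),
        denominator=kn.count,
        fp_keys=fp_keys,
    )


def fp_b_low(
    b_cs: CallSet,
    sibling_b_cs: Sequence[CallSet],
    region: RegionSet,
    cutoff: float = 0.0,
    window: tuple[float, float] = B_LOW_WINDOW,
) -> FPResult:
    """FP rate from low-VAF calls in the diploid normal sample.

    ``sibling_b_cs`` are the other sample-B replicates from the same site,
    used for the high-VAF exclusion; with fewer than one sibling available
    the exclusion is skipped with a warning.
    """
    if b_cs.sample != "B" or any(s.sample != "B" for s in sibling_b_cs):
        raise ValueError("fp_b_low requires sample-B call sets")
    low = max(window[0], cutoff)
    high = window[1]
    if sibling_b_cs:
        high_keys = {
            c.variant.key
            for s in sibling_b_cs
            for c in s.calls
            if c.vaf > B_HIGH_VAF
        }
    else:
        warnings.warn(
            f"{b_cs.id}: no sibling B replicates; high-VAF exclusion skipped",
            stacklevel=2,
        )
        high_keys = set()
    work = b_cs.restrict(region)
    fp_keys = [
        c.variant.key
        for c in work.calls
        if low <= c.vaf <= high and c.variant.key not in high_keys
    ]
    return FPResult(
        panel=b_cs.panel,
        sample="B",
        method="B_low",
        region_label=region.name or "region",
        cutoff=cutoff,
        n_fp=len(fp_keys),
        denominator=region.size_bases,
        fp_keys=fp_keys,
    )


def fp_c_only(
    c_cs: CallSet,
    a_libs: Sequence[CallSet],
    b_libs: Sequence[CallSet],
    region: RegionSet,
    cutoff: float = 0.0,
) -> FPResult:
    """FP rate from mixture-sample calls absent from both source samples.

    All inputs must come from the same laboratory.  A call is an FP if its
    key is in no sample-A library (any VAF) and in no sample-B library above
    10% VAF.
    """
    if not a_libs or not b_libs:
        raise FPMethodUnavailable(
            "C_only needs the lab's sample A and sample B libraries"
        )
    labs = {c_cs.lab} | {cs.lab for cs in a_libs} | {cs.lab for cs in b_libs}
    if len(labs) != 1:
        raise ValueError("C_only compares libraries within a single laboratory")
    a_keys = {c.variant.key for cs in a_libs for c in cs.calls}
    b_high = {
        c.variant.key for cs in b_libs for c in cs.calls if c.vaf > B_HIGH_VAF
    }
    work = c_cs.restrict(region)
    fp_keys = [
        c.variant.key
        for c in work.calls
        if c.vaf >= cutoff
        and c.variant.key not in a_keys
        and c.variant.key not in b_high
    ]
    return FPResult(
        panel=c_cs.panel,
        sample="C",
        method="C_only",
        region_label=region.name or "region",
        cutoff=cutoff,
        n_fp=len(fp_keys),
        denominator=region.size_bases,
        fp_keys=fp_keys,
    )


def fp_by_subregion(
    subregions: PanelSubregions,
    method: str,
    cutoffs: Sequence[float],
    cs: CallSet,
    kn: KnownNegativeSet | None = None,
    sibling_b_cs: Sequence[CallSet] = (),
    a_libs: Sequence[CallSet] = (),
    b_libs: Sequence[CallSet] = (),
) -> list[FPResult]:
    """One FP estimate per panel sub-region per VAF cutoff.

    ``viaKN`` is valid only inside the CTR (the KN catalog exists nowhere
    else) and raises :class:`RegionError` if requested for the outer parts.
    """
    results: list[FPResult] = []
    for label, region in subregions.parts.items():
        for cutoff in cutoffs:
            if method == "viaKN":
                if label != "in_CTR":
                    raise RegionError(
                        "viaKN is defined only within the CTR sub-region"
                    )
                if kn is None:
                    raise ValueError("viaKN requires the known-negative set")
                res = fp_via_kn(
                    cs.restrict(region), kn.restrict(region), cutoff=cutoff,
                    region_label=label,
                )
            elif method == "B_low":
                res = fp_b_low(cs, sibling_b_cs, region, cutoff=cutoff)
                res.region_label = label
            elif method == "C_only":
                res = fp_c_only(cs, a_libs, b_libs, region, cutoff=cutoff)
                res.region_label = label
            else:
                raise ValueError(f"unknown FP method {method!r}")
            results.append(res)
    return results


@dataclass
class FPReproducibility:
    """Recurrence of flagged FP variants across library replicates."""

    n_fp_variants: int
    n_recurring: int
    recurring_keys: list
    counts: Mapping

    @property
    def recurrence_fraction(self) -> float | None:
        """Fraction of distinct FP variants seen in >= 2 libraries, or
        ``None`` when no FPs were flagged at all (undefined)."""
        if self.n_fp_variants == 0:
            return None
        return self.n_recurring / self.n_fp_variants


def fp_reproducibility(fp_keys_per_replicate: Sequence[Iterable]) -> FPReproducibility:
    """Recurrence analysis of FP calls across replicates.

    Independent sequencing errors should essentially never recur; variants
    flagged as FPs in two or more replicates are candidates for systematic
    errors and are listed for inspection.
    """
    if len(fp_keys_per_replicate) < 2:
        raise ValueError("need >= 2 replicates to assess FP recurrence")
    counts: dict = {}
    for keys in fp_keys_per_replicate:
        for key in set(keys):
            counts[key] = counts.get(key, 0) + 1
    recurring = sorted(k for k, n in counts.items() if n >= 2)
    return FPReproducibility(
        n_fp_variants=len(counts),
        n_recurring=len(recurring),
        recurring_keys=recurring,
        counts=counts,
    )


def results_frame(results: Sequence[FPResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
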