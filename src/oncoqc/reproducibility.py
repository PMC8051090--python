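"""Non-symmetric pairwise reproducibility between library replicates.

For an ordered pair of libraries (Libx, Liby) of the same panel and sample,
reproducibility is the fraction of Libx's calls that are also called in
Liby.  The measure is directional — value(x->y) generally differs from
value(y->x) — and VAF stratification is applied *asymmetrically*: the
stratum restricts Libx's calls only, while membership in Liby is checked by
normalized variant key with no VAF restriction.

Pairs whose libraries share a laboratory contribute intra-lab measurements;
pairs across laboratories contribute cross-lab measurements.  Aggregation is
the mean over ordered pairs by default (a pooled-count variant is exposed).

Values are often displayed on the Phred scale, -10*log10(1 - r), where
1 - r is the miss fraction; r = 1 maps to a configurable cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import pandas as pd

from .callsets import CallSet
from .regions import RegionSet
from .sensitivity import VafStratum

__all__ = [
    "ReproPair",
    "pair_reproducibility",
    "aggregate",
    "phred",
    "PHRED_CAP",
]

#: Phred value reported for perfect reproducibility (r = 1).
PHRED_CAP: float = 60.0


@dataclass(frozen=True)
class ReproPair:
    from_lib: tuple
    to_lib: tuple
    stratum: VafStratum | None
    value: float | None  # None when Libx has no calls in the stratum
    scope: str  # "intra" | "cross"
    n_from: int
    n_shared: int

    def to_dict(self) -> dict:
        return {
            "from": "/".join(map(str, self.from_lib)),
            "to": "/".join(map(str, self.to_lib)),
            "stratum": str(self.stratum) if self.stratum else "all",
            "scope": self.scope,
            "n_from": self.n_from,
            "n_shared": self.n_shared,
            "value": self.value,
        }


def pair_reproducibility(
    libx: CallSet,
    liby: CallSet,
    stratum: VafStratum | None = None,
    region: RegionSet | None = None,
) -> ReproPair:
    """Directional reproducibility of Libx's (stratum-restricted) calls in Liby.

    Returns a :class:`ReproPair` whose ``value`` is ``None`` (undefined, not
    zero) when Libx has no calls in the stratum.
    """
    if (libx.panel, libx.sample) != (liby.panel, liby.sample):
        raise ValueError("pair must share panel and sample")
    x = libx.restrict(region) if region is not None else libx
    y = liby.restrict(region) if region is not None else liby
    x_calls = [
        c for c in x.calls if stratum is None or stratum.contains(c.vaf)
    ]
    y_keys = y.keys()  # no VAF restriction on the target library
    n_from = len(x_calls)
    n_shared = sum(1 for c in x_calls if c.variant.key in y_keys)
    scope = "intra" if libx.lab == liby.lab else "cross"
    value = None if n_from == 0 else n_shared / n_from
    return ReproPair(
        from_lib=libx.id,
        to_lib=liby.id,
        stratum=stratum,
        value=value,
        scope=scope,
        n_from=n_from,
        n_shared=n_shared,
    )


def aggregate(
    callsets: Sequence[CallSet],
    stratum: VafStratum | None = None,
    region: RegionSet | None = None,
    scope: str = "both",
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean reproducibility over all ordered pairs, split intra vs cross lab.

    With ``pooled=True`` the aggregate is total shared calls over total
    stratum calls instead of the per-pair mean.  Returns a tidy frame with
    one row per scope, carrying the pair count and the aggregate value; an
    empty scope (fewer than two libraries, or all pairs undefined) yields a
    ``NaN`` aggregate.
    """
    if scope not in ("intra", "cross", "both"):
        raise ValueError("scope must be 'intra', 'cross' or 'both'")
    if len(callsets) < 2:
        raise ValueError("need >= 2 libraries")
    pairs = [
        pair_reproducibility(x, y, stratum=stratum, region=region)
        for x, y in permutations(callsets, 2)
    ]
    wanted = ("intra", "cross") if scope == "both" else (scope,)
    rows = []
    for sc in wanted:
        sub = [p for p in pairs if p.scope == sc]
        defined = [p for p in sub if p.value is not None]
        if pooled:
            tot_from = sum(p.n_from for p in defined)
            value = (
                sum(p.n_shared for p in defined) / tot_from if tot_from else float("nan")
            )
        else:
            value = (
                sum(p.value for p in defined) / len(defined)
                if defined
                else float("nan")
            )
        rows.append(
            {
                "scope": sc,
                "stratum": str(stratum) if stratum else "all",
                "n_pairs": len(sub),
                "n_defined": len(defined),
                "mean_reproducibility": value,
                "phred": phred(value) if value == value else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def pair_frame(
    callsets: Sequence[CallSet],
    stratum: VafStratum | None = None,
    region: RegionSet | None = None,
) -> pd.DataFrame:
    """Per-ordered-pair values as a tidy frame (for TSV export)."""
    pairs = [
        pair_reproducibility(x, y, stratum=stratum, region=region)
        for x, y in permutations(callsets, 2)
    ]
    return pd.DataFrame([p.to_dict() for p in pairs])


def phred(value: float, cap: float = PHRED_CAP) -> float:
    """Phred-scaled reproducibility: -10*log10(1 - r), capped at ``cap``."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"reproducibility {value} outside [0, 1]")
    if value >= 1.0:
        return cap
    return min(-10.0 * math.log10(1.0 - value), cap)
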