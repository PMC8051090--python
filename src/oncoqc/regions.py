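"""Genomic interval algebra for panel evaluation regions.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Variant positions read from VCF (1-based) are converted exactly once, at the
call-set boundary (:mod:`oncoqc.callsets`), never here.

A :class:`RegionSet` is always kept normalized: intervals sorted by
``(chrom, start)``, with overlapping *and* bookended (adjacent) intervals
merged, so that the total size in bases is unambiguous.  Chromosome names are
compared as exact strings; an optional alias map can be supplied when reading
BED files if inputs mix naming schemes.

The three evaluation sub-regions of a panel are the panel target intersected
with the consensus targeted region (CTR), the part inside the high-confidence
coding region (HC_CR) but outside the CTR, and the remainder.  The CTR is
required to lie entirely within the HC_CR, so the three parts partition the
panel target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "PanelSubregions",
    "RegionError",
    "BedParseError",
    "read_bed",
    "build_subregions",
]


class RegionError(ValueError):
    """Invalid region input (coordinates, subset violations, ...)."""


class BedParseError(RegionError):
    """Malformed BED line; the message names the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise RegionError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise RegionError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_arrays(
    raw: Mapping[str, list[tuple[int, int]]]
) -> dict[str, np.ndarray]:
    """Sort and merge per-chromosome (start, end) pairs; bookended merge."""
    out: dict[str, np.ndarray] = {}
    for chrom in sorted(raw):
        pairs = sorted(raw[chrom])
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if merged:
            out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


class RegionSet:
    """A normalized, immutable collection of genomic intervals."""

    __slots__ = ("name", "_ivs")

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.chrom, []).append((int(iv.start), int(iv.end)))
        self.name = name
        self._ivs = _normalize_arrays(raw)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, int, int]], name: str = ""
    ) -> "RegionSet":
        return cls((GenomicInterval(c, s, e) for c, s, e in pairs), name=name)

    @classmethod
    def _from_arrays(cls, ivs: dict[str, np.ndarray], name: str = "") -> "RegionSet":
        obj = cls.__new__(cls)
        obj.name = name
        obj._ivs = {c: a for c, a in ivs.items() if len(a)}
        return obj

    # -- basic queries -----------------------------------------------------
    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._ivs)

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(c, int(s), int(e))
            for c, arr in self._ivs.items()
            for s, e in arr
        )

    @property
    def size_bases(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._ivs.values()))

    @property
    def size_mb(self) -> float:
        return self.size_bases / 1e6

    @property
    def is_empty(self) -> bool:
        return not self._ivs

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivs.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._ivs.keys() == other._ivs.keys() and all(
            np.array_equal(self._ivs[c], other._ivs[c]) for c in self._ivs
        )

    def __hash__(self) -> int:  # identity-ish; RegionSet is mutated nowhere
        return hash((self.name, self.size_bases, len(self)))

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<RegionSet{label}: {len(self)} intervals, {self.size_bases} bp>"

    # -- membership --------------------------------------------------------
    def contains(self, chrom: str, pos0: int) -> bool:
        """True if 0-based position ``pos0`` lies inside the set."""
        arr = self._ivs.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
        return i >= 0 and pos0 < arr[i, 1]

    def contains_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of 0-based positions."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        arr = self._ivs.get(chrom)
        if arr is None:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < arr[idx[ok], 1]
        return out

    def issubset(self, other: "RegionSet") -> bool:
        return self.subtract(other).is_empty

    # -- set algebra -------------------------------------------------------
    def intersect(self, other: "RegionSet", name: str = "") -> "RegionSet":
        """Bases present in both sets."""
        out: dict[str, np.ndarray] = {}
        for chrom in self._ivs:
            b = other._ivs.get(chrom)
            if b is None:
                continue
            a = self._ivs[chrom]
            res: list[tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    res.append((int(s), int(e)))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = np.asarray(res, dtype=np.int64)
        return RegionSet._from_arrays(out, name=name)

    def subtract(self, other: "RegionSet", name: str = "") -> "RegionSet":
        """Bases in this set and not in ``other``."""
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._ivs.items():
            b = other._ivs.get(chrom)
            if b is None or not len(b):
                out[chrom] = a.copy()
                continue
            res: list[tuple[int, int]] = []
            j = 0
            for s, e in a:
                cur = int(s)
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                jj = j
                while jj < len(b) and b[jj, 0] < e:
                    if b[jj, 0] > cur:
                        res.append((cur, int(b[jj, 0])))
                    cur = max(cur, int(b[jj, 1]))
                    jj += 1
                if cur < e:
                    res.append((cur, int(e)))
            if res:
                out[chrom] = np.asarray(res, dtype=np.int64)
            elif chrom in out:
                del out[chrom]
        return RegionSet._from_arrays(
            {c: v for c, v in out.items() if len(v)}, name=name
        )

    def union(self, other: "RegionSet", name: str = "") -> "RegionSet":
        raw: dict[str, list[tuple[int, int]]] = {}
        for rs in (self, other):
            for chrom, arr in rs._ivs.items():
                raw.setdefault(chrom, []).extend((int(s), int(e)) for s, e in arr)
        return RegionSet._from_arrays(_normalize_arrays(raw), name=name)

    # -- offsets (used by the study simulator) -----------------------------
    def positions_from_offsets(self, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map 0-based offsets into the concatenated bases of the set.

        Returns parallel arrays (chromosome labels, 0-based positions).
        Offsets index the set's bases in (chrom, start) order, enabling
        uniform sampling of positions over the region.
        """
        offsets = np.asarray(offsets, dtype=np.int64)
        if offsets.size and (offsets.min() < 0 or offsets.max() >= self.size_bases):
            raise RegionError("offset outside region")
        chroms_out = np.empty(offsets.shape, dtype=object)
        pos_out = np.empty(offsets.shape, dtype=np.int64)
        base = 0
        for chrom, arr in self._ivs.items():
            lens = arr[:, 1] - arr[:, 0]
            cum = np.concatenate([[0], np.cumsum(lens)])
            total = int(cum[-1])
            sel = (offsets >= base) & (offsets < base + total)
            if sel.any():
                local = offsets[sel] - base
                k = np.searchsorted(cum, local, side="right") - 1
                pos_out[sel] = arr[k, 0] + (local - cum[k])
                chroms_out[sel] = chrom
            base += total
        return chroms_out, pos_out

    # -- I/O ---------------------------------------------------------------
    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self._ivs.items():
                for s, e in arr:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(
    path: str,
    name: str = "",
    chrom_aliases: Mapping[str, str] | None = None,
) -> RegionSet:
    """Read a BED3+ file into a normalized :class:`RegionSet`.

    Extra columns beyond the first three are ignored.  Lines starting with
    ``track``, ``browser`` or ``#`` are skipped.  Malformed coordinates raise
    :class:`BedParseError` naming the line number.
    """
    pairs: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                s, e = int(s_raw), int(e_raw)
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {s_raw!r}/{e_raw!r}"
                ) from None
            if s < 0 or s >= e:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{s}-{e}"
                )
            if chrom_aliases:
                chrom = chrom_aliases.get(chrom, chrom)
            pairs.append((chrom, s, e))
    return RegionSet.from_pairs(pairs, name=name or path)


@dataclass(frozen=True)
class PanelSubregions:
    """The three-part partition of a panel's target region."""

    in_ctr: RegionSet
    in_hccr_out_ctr: RegionSet
    rest: RegionSet

    @property
    def parts(self) -> dict[str, RegionSet]:
        return {
            "in_CTR": self.in_ctr,
            "in_HCCR_out_CTR": self.in_hccr_out_ctr,
            "rest": self.rest,
        }

    def summary(self) -> pd.DataFrame:
        rows = [
            {"subregion": label, "bases": rs.size_bases, "mb": rs.size_mb}
            for label, rs in self.parts.items()
        ]
        return pd.DataFrame(rows)


def build_subregions(
    panel: RegionSet, ctr: RegionSet, hccr: RegionSet
) -> PanelSubregions:
    """Partition a panel target into CTR / HC_CR-beyond-CTR / rest.

    Requires ``ctr`` to be a subset of ``hccr`` (the consensus targeted
    region lies entirely within the high-confidence coding region); raises
    :class:`RegionError` otherwise.
    """
    if not ctr.issubset(hccr):
        raise RegionError("CTR is not contained in HC_CR")
    in_ctr = panel.intersect(ctr, name="in_CTR")
    in_hccr_out_ctr = panel.intersect(hccr).subtract(ctr, name="in_HCCR_out_CTR")
    rest = panel.subtract(hccr, name="rest")
    return PanelSubregions(in_ctr=in_ctr, in_hccr_out_ctr=in_hccr_out_ctr, rest=rest)
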