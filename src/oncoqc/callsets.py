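"""Variant call sets: reading, normalization, typing and matching.

Variants are keyed by ``(chrom, pos, ref, alt)`` after normalization
(multiallelic split, parsimony trimming and — when a reference-base fetcher
is available — left alignment of indels).  Matching against truth catalogs
and between libraries is exact-key at the locus level; no distance-window or
haplotype-aware matching is attempted, because fuzzy matching would silently
change every downstream metric.

Positions are 1-based (the VCF convention).  Region membership of a call uses
the variant's leftmost (anchor) reference base, converted once to the 0-based
half-open convention of :mod:`oncoqc.regions`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np

from .regions import RegionSet

__all__ = [
    "Variant",
    "Call",
    "CallSet",
    "KnownVariant",
    "KnownNegativeSet",
    "MatchResult",
    "VcfFieldError",
    "classify_variant",
    "normalize_variant",
    "read_vcf",
    "match_truth",
    "derive_sample_c_negatives",
    "read_known_variants",
    "write_known_variants",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

VariantType = Literal["SNV", "INDEL", "MNV"]

#: Default priority of per-record VAF sources; vendors differ in where they
#: report allele fraction, so the order is configurable per study manifest.
DEFAULT_VAF_SOURCES: tuple[str, ...] = ("INFO:AF", "FORMAT:AF", "AD")


class VcfFieldError(ValueError):
    """A required field (e.g. the VAF source) is missing from a VCF record."""


def classify_variant(ref: str, alt: str) -> VariantType:
    """SNV if both alleles are single bases, MNV if equal length > 1,
    otherwise INDEL."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    return "INDEL"


@dataclass(frozen=True, order=True)
class Variant:
    chrom: str
    pos: int  # 1-based leftmost reference base
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ACGT:
                raise ValueError(
                    f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> VariantType:
        return classify_variant(self.ref, self.alt)


@dataclass(frozen=True)
class Call:
    variant: Variant
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside (0, 1] at {self.variant.key}")


@dataclass
class CallSet:
    """One library replicate's variant calls, keyed by lab/sample/replicate."""

    panel: str
    lab: str
    sample: str
    replicate: int
    calls: list[Call] = field(default_factory=list)
    n_skipped: int = 0  # symbolic/breakend/non-ACGT records dropped on read

    @property
    def id(self) -> tuple[str, str, str, int]:
        return (self.panel, self.lab, self.sample, self.replicate)

    def __len__(self) -> int:
        return len(self.calls)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {c.variant.key for c in self.calls}

    def vaf_by_key(self) -> dict[tuple[str, int, str, str], float]:
        return {c.variant.key: c.vaf for c in self.calls}

    def restrict(self, region: RegionSet) -> "CallSet":
        """Keep calls whose anchor base lies inside ``region``."""
        kept = [
            c
            for c in self.calls
            if region.contains(c.variant.chrom, c.variant.pos - 1)
        ]
        return replace(self, calls=kept)

    def filter_vaf(self, cutoff: float) -> "CallSet":
        """Apply a VAF reporting cutoff: keep calls with ``vaf >= cutoff``."""
        return replace(self, calls=[c for c in self.calls if c.vaf >= cutoff])


@dataclass(frozen=True)
class KnownVariant:
    """A truth-set positive with its expected VAF in reference sample A."""

    variant: Variant
    vaf_a: float
    provenance: str = "cellline"

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_a <= 1.0:
            raise ValueError(f"expected VAF {self.vaf_a} outside (0, 1]")


class KnownNegativeSet:
    """Positions (1-based) verified negative in a reference sample.

    Stored as sorted per-chromosome arrays so that million-scale lists stay
    compact and membership checks are O(log n).
    """

    __slots__ = ("_pos",)

    def __init__(self, positions: Iterable[tuple[str, int]] = ()):
        raw: dict[str, list[int]] = {}
        for chrom, pos in positions:
            raw.setdefault(chrom, []).append(int(pos))
        self._pos = {
            c: np.unique(np.asarray(v, dtype=np.int64)) for c, v in sorted(raw.items())
        }

    @classmethod
    def _from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "KnownNegativeSet":
        obj = cls.__new__(cls)
        obj._pos = {c: np.asarray(a, dtype=np.int64) for c, a in arrays.items() if len(a)}
        return obj

    @classmethod
    def from_arrays(
        cls, chroms: np.ndarray, positions: np.ndarray
    ) -> "KnownNegativeSet":
        arrays: dict[str, np.ndarray] = {}
        for chrom in np.unique(chroms.astype(object)):
            arrays[str(chrom)] = np.sort(positions[chroms == chrom])
        return cls._from_arrays(arrays)

    @property
    def count(self) -> int:
        return int(sum(len(a) for a in self._pos.values()))

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self._pos.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr, pos))
        return i < len(arr) and arr[i] == pos

    def __iter__(self):
        for chrom, arr in self._pos.items():
            for p in arr:
                yield (chrom, int(p))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnownNegativeSet):
            return NotImplemented
        return self._pos.keys() == other._pos.keys() and all(
            np.array_equal(self._pos[c], other._pos[c]) for c in self._pos
        )

    def restrict(self, region: RegionSet) -> "KnownNegativeSet":
        arrays = {
            c: a[region.contains_many(c, a - 1)] for c, a in self._pos.items()
        }
        return KnownNegativeSet._from_arrays(arrays)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\n")
            for chrom, arr in self._pos.items():
                fh.writelines(f"{chrom}\t{p}\n" for p in arr)

    @classmethod
    def from_tsv(cls, path: str) -> "KnownNegativeSet":
        raw: dict[str, list[int]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):
                fh.seek(0)
            for line in fh:
                chrom, pos = line.split("\t")
                raw.setdefault(chrom, []).append(int(pos))
        return cls._from_arrays(
            {c: np.unique(np.asarray(v, dtype=np.int64)) for c, v in sorted(raw.items())}
        )


def derive_sample_c_negatives(
    kn_a: KnownNegativeSet, b_variants: Iterable[Variant]
) -> KnownNegativeSet:
    """Known negatives for the 1:1 mixture sample.

    Positions of the pure-sample negative list that coincide with any
    germline variant of the diploid background sample are removed, since in
    the mixture those loci genuinely carry an alternate allele.
    """
    drop: dict[str, set[int]] = {}
    for v in b_variants:
        drop.setdefault(v.chrom, set()).add(v.pos)
    arrays = {}
    for chrom in kn_a.chroms:
        arr = kn_a.positions(chrom)
        bad = drop.get(chrom)
        if bad:
            arr = arr[~np.isin(arr, np.fromiter(bad, dtype=np.int64))]
        arrays[chrom] = arr
    return KnownNegativeSet._from_arrays(arrays)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    fetch: Callable[[str, int], str] | None = None,
) -> tuple[int, str, str]:
    """Parsimony-trim and (optionally) left-align one ref/alt pair.

    ``fetch(chrom, pos)`` must return the reference base at a 1-based
    position; when it is ``None`` indels are trimmed but not shifted, which
    is sufficient for call sets already emitted in left-aligned form.
    The returned representation keeps at least one base in each allele.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (
            fetch is not None
            and pos > 1
            and len(ref) != len(alt)
            and ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
        ):
            prev = fetch(chrom, pos - 1).upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _decompose_record(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    fetch: Callable[[str, int], str] | None,
) -> list[tuple[int, str, str]]:
    """Split a (possibly multiallelic) record into normalized per-alt calls."""
    out = []
    for alt in alts:
        out.append(normalize_variant(chrom, pos, ref, alt, fetch=fetch))
    return out


def read_vcf(
    path: str,
    panel: str,
    lab: str,
    sample: str,
    replicate: int,
    vaf_sources: Sequence[str] = DEFAULT_VAF_SOURCES,
    fetch: Callable[[str, int], str] | None = None,
) -> CallSet:
    """Read a VCF 4.x file into a normalized :class:`CallSet`.

    Multiallelic records are split into one call per alternate allele; each
    call's VAF is taken from the first available source in ``vaf_sources``
    (``INFO:AF``, ``FORMAT:AF``, or ``AD``-derived for the first sample
    column).  Records with symbolic/breakend or non-ACGT alleles are skipped
    and counted in ``CallSet.n_skipped``; a record with no usable VAF raises
    :class:`VcfFieldError` naming the site.
    """
    from cyvcf2 import VCF

    calls: list[Call] = []
    n_skipped = 0
    vcf = VCF(path)
    for rec in vcf:
        alts = rec.ALT or []
        usable: list[tuple[int, str]] = []
        for i, alt in enumerate(alts):
            if not alt or not set(alt.upper()) <= _ACGT or not set(rec.REF.upper()) <= _ACGT:
                n_skipped += 1
                continue
            usable.append((i, alt))
        if not usable:
            continue
        vafs = _record_vafs(rec, len(alts), vaf_sources, path)
        for i, alt in usable:
            vaf = vafs[i]
            if vaf is None or not np.isfinite(vaf):
                raise VcfFieldError(
                    f"{path}: no VAF for {rec.CHROM}:{rec.POS} {rec.REF}>{alt} "
                    f"(sources tried: {', '.join(vaf_sources)})"
                )
            if vaf <= 0:
                n_skipped += 1
                continue
            pos, ref_n, alt_n = normalize_variant(
                rec.CHROM, rec.POS, rec.REF, alt, fetch=fetch
            )
            calls.append(
                Call(Variant(rec.CHROM, pos, ref_n, alt_n), float(min(vaf, 1.0)))
            )
    vcf.close()
    if n_skipped:
        logger.info("%s: skipped %d unusable allele(s)", path, n_skipped)
    # de-duplicate identical keys after normalization (keep highest VAF)
    seen: dict[tuple[str, int, str, str], Call] = {}
    for c in calls:
        prev = seen.get(c.variant.key)
        if prev is None or c.vaf > prev.vaf:
            seen[c.variant.key] = c
    return CallSet(
        panel=panel,
        lab=lab,
        sample=sample,
        replicate=replicate,
        calls=sorted(seen.values(), key=lambda c: c.variant),
        n_skipped=n_skipped,
    )


def _record_vafs(rec, n_alt: int, vaf_sources: Sequence[str], path: str):
    """Per-alt VAFs from the first source that yields values."""
    for source in vaf_sources:
        if source == "INFO:AF":
            af = rec.INFO.get("AF")
            if af is None:
                continue
            vals = np.atleast_1d(np.asarray(af, dtype=float))
            if len(vals) == n_alt:
                return list(vals)
            if len(vals) == 1:
                return [float(vals[0])] * n_alt
        elif source == "FORMAT:AF":
            try:
                af = rec.format("AF")
            except KeyError:
                af = None
            if af is None:
                continue
            vals = np.asarray(af[0], dtype=float).ravel()
            if len(vals) >= n_alt:
                return list(vals[:n_alt])
            if len(vals) == 1:
                return [float(vals[0])] * n_alt
        elif source == "AD":
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                continue
            counts = np.asarray(ad[0], dtype=float).ravel()
            total = np.nansum(counts)
            if total > 0 and len(counts) >= n_alt + 1:
                return [float(counts[i + 1] / total) for i in range(n_alt)]
        else:
            raise ValueError(f"unknown VAF source {source!r}")
    return [None] * n_alt


# ---------------------------------------------------------------------------
# truth matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Per-truth detection flags plus per-call truth status."""

    truth: list[KnownVariant]
    detected: np.ndarray  # bool, aligned with truth
    call_status: list[str]  # per call: "kp_match" | "kn_overlap" | "unknown"

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())


def match_truth(
    cs: CallSet,
    truth: Sequence[KnownVariant],
    kn: KnownNegativeSet | None = None,
) -> MatchResult:
    """Exact-key matching of a call set against a truth catalog.

    A known positive counts as detected iff a call with the identical
    normalized ``(chrom, pos, ref, alt)`` exists.  Each call is labelled
    ``kp_match``, ``kn_overlap`` (its anchor position is a known negative),
    or ``unknown``.
    """
    call_keys = cs.keys()
    detected = np.fromiter(
        (kv.variant.key in call_keys for kv in truth), dtype=bool, count=len(truth)
    )
    truth_keys = {kv.variant.key for kv in truth}
    status = []
    for c in cs.calls:
        if c.variant.key in truth_keys:
            status.append("kp_match")
        elif kn is not None and kn.contains(c.variant.chrom, c.variant.pos):
            status.append("kn_overlap")
        else:
            status.append("unknown")
    return MatchResult(truth=list(truth), detected=detected, call_status=status)


# ---------------------------------------------------------------------------
# truth catalog I/O (tab-separated)
# ---------------------------------------------------------------------------

def write_known_variants(kps: Sequence[KnownVariant], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvaf_a\tprovenance\n")
        for kv in kps:
            v = kv.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{kv.vaf_a:.6g}\t{kv.provenance}\n"
            )


def read_known_variants(path: str) -> list[KnownVariant]:
    out: list[KnownVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                KnownVariant(
                    Variant(
                        f[idx["chrom"]],
                        int(f[idx["pos"]]),
                        f[idx["ref"]],
                        f[idx["alt"]],
                    ),
                    vaf_a=float(f[idx["vaf_a"]]),
                    provenance=f[idx.get("provenance", len(f) - 1)],
                )
            )
    return out
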