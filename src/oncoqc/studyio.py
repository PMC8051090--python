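"""Write and read complete study directories.

A study directory round-trips through the package's own readers:

    study/
      manifest.yaml            lab/sample/replicate per VCF, panel threshold
      regions/panel.bed        panel target (BED3)
      regions/ctr.bed          consensus targeted region
      regions/hccr.bed         high-confidence coding region
      truth/known_positives.tsv
      truth/known_negatives.tsv
      truth/b_germline.tsv
      calls/<panel>_<lab>_<sample>_rep<r>.vcf

VCFs are minimal VCF 4.2 with the call VAF in ``INFO/AF``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import yaml

from .callsets import (
    CallSet,
    KnownNegativeSet,
    Variant,
    read_known_variants,
    read_vcf,
    write_known_variants,
)
from .regions import RegionSet, read_bed
from .simulate import StudyBundle

__all__ = ["write_study", "read_study", "StudyData", "write_vcf"]


def write_vcf(cs: CallSet, path: str, contigs: dict[str, int] | None = None) -> None:
    """Write a call set as a minimal sites-only VCF with INFO/AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=oncoqc\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in cs.calls:
            v = c.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tAF={c.vaf:.6g}\n"
            )


def write_study(bundle: StudyBundle, outdir: str) -> str:
    """Write a study bundle as a directory of text files; returns the
    manifest path."""
    for sub in ("regions", "truth", "calls"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    regions = bundle.regions
    regions.panel.to_bed(os.path.join(outdir, "regions", "panel.bed"))
    regions.ctr.to_bed(os.path.join(outdir, "regions", "ctr.bed"))
    regions.hccr.to_bed(os.path.join(outdir, "regions", "hccr.bed"))

    truth = bundle.truth
    write_known_variants(
        truth.kps + truth.spikein,
        os.path.join(outdir, "truth", "known_positives.tsv"),
    )
    truth.kn.to_tsv(os.path.join(outdir, "truth", "known_negatives.tsv"))
    with open(os.path.join(outdir, "truth", "b_germline.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvaf\n")
        for v, vaf in truth.germline:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{vaf:g}\n")

    contigs = dict(bundle.cfg.chrom_sizes)
    libraries = []
    for (lab, sample, rep), cs in sorted(bundle.callsets.items()):
        fname = f"{cs.panel}_{lab}_{sample}_rep{rep}.vcf"
        write_vcf(cs, os.path.join(outdir, "calls", fname), contigs=contigs)
        libraries.append(
            {
                "path": f"calls/{fname}",
                "lab": lab,
                "sample": sample,
                "replicate": rep,
            }
        )
    manifest = {
        "panel": bundle.cfg.panel,
        "vaf_threshold": bundle.cfg.vaf_threshold,
        "vaf_sources": ["INFO:AF"],
        "regions": {
            "panel": "regions/panel.bed",
            "ctr": "regions/ctr.bed",
            "hccr": "regions/hccr.bed",
        },
        "truth": {
            "known_positives": "truth/known_positives.tsv",
            "known_negatives": "truth/known_negatives.tsv",
            "b_germline": "truth/b_germline.tsv",
        },
        "libraries": libraries,
    }
    manifest_path = os.path.join(outdir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


@dataclass
class StudyData:
    """A study directory loaded back through the package's readers."""

    panel: str
    vaf_threshold: float
    panel_region: RegionSet
    ctr: RegionSet
    hccr: RegionSet
    kps: list
    kn: KnownNegativeSet
    b_germline: list[tuple[Variant, float]]
    callsets: dict[tuple[str, str, int], CallSet]

    def callsets_for(self, sample: str | None = None, lab: str | None = None):
        return [
            cs
            for (l, s, _r), cs in sorted(self.callsets.items())
            if (sample is None or s == sample) and (lab is None or l == lab)
        ]


def read_study(study_dir: str) -> StudyData:
    """Load a study directory written by :func:`write_study`."""
    with open(os.path.join(study_dir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    join = lambda rel: os.path.join(study_dir, rel)
    panel_region = read_bed(join(manifest["regions"]["panel"]), name="panel")
    ctr = read_bed(join(manifest["regions"]["ctr"]), name="CTR")
    hccr = read_bed(join(manifest["regions"]["hccr"]), name="HC_CR")
    kps = read_known_variants(join(manifest["truth"]["known_positives"]))
    kn = KnownNegativeSet.from_tsv(join(manifest["truth"]["known_negatives"]))
    b_germline = []
    with open(join(manifest["truth"]["b_germline"])) as fh:
        fh.readline()
        for line in fh:
            chrom, pos, ref, alt, vaf = line.rstrip("\n").split("\t")
            b_germline.append((Variant(chrom, int(pos), ref, alt), float(vaf)))
    vaf_sources = tuple(manifest.get("vaf_sources", ["INFO:AF"]))
    callsets = {}
    for lib in manifest["libraries"]:
        cs = read_vcf(
            join(lib["path"]),
            panel=manifest["panel"],
            lab=lib["lab"],
            sample=lib["sample"],
            replicate=int(lib["replicate"]),
            vaf_sources=vaf_sources,
        )
        callsets[(cs.lab, cs.sample, cs.replicate)] = cs
    return StudyData(
        panel=manifest["panel"],
        vaf_threshold=float(manifest["vaf_threshold"]),
        panel_region=panel_region,
        ctr=ctr,
        hccr=hccr,
        kps=kps,
        kn=kn,
        b_germline=b_germline,
        callsets=callsets,
    )
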