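"""Non-symmetric reproducibility between library replicates, on the Phred
scale.

Comparing library x to library y, reproducibility is the fraction of x's
calls (in a VAF stratum) also called in y — direction matters, and the
stratum restricts x only.  Averaging over ordered pairs within a lab gives
intra-lab reproducibility; across labs, cross-lab.  Phred scale is
-10*log10(1 - r): 20 means 1 call in 100 is missed by the partner library.
"""

from oncoqc import VafStratum, generate_study, pair_reproducibility, phred
from oncoqc.reproducibility import aggregate
from oncoqc.simulate import GeneratorConfig

bundle = generate_study(GeneratorConfig(n_kp=1500, n_kn=20_000), seed=9)
region = bundle.regions.panel_in_ctr
libs = bundle.callsets_for(sample="A")

x, y = libs[0], libs[1]
stratum = VafStratum(0.025, 0.20, "2.5-20%", closed_low=True)
fwd = pair_reproducibility(x, y, stratum=stratum, region=region)
rev = pair_reproducibility(y, x, stratum=stratum, region=region)
print(f"{'/'.join(map(str, x.id))} -> {'/'.join(map(str, y.id))}: "
      f"{fwd.value:.4f}   reverse: {rev.value:.4f}  (directional measure)")

table = aggregate(libs, stratum=stratum, region=region)
print("\naggregate over ordered pairs, sample A, VAF 2.5-20%, inside CTR:")
print(table.to_string(index=False))
print(f"\n(phred({0.99}) = {phred(0.99):.0f}; higher is better, capped at 60)")
# With no lab batch effects and library-independent errors, intra- and
# cross-lab means coincide up to noise; injected errors set the ceiling.
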