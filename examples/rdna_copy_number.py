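"""Estimate rDNA operon copy number from read-depth ratios.

The tandem rDNA array collapses to one copy in the assembly, so its read
depth is (copy number) times the single-copy backbone depth.  The estimator
compares the median depth over the annotated operon with the median depth
over the 50 longest contigs.
"""

import tempfile

from crcurate.scenarios import rdna_scenario

with tempfile.TemporaryDirectory() as tmp:
    result = rdna_scenario(seed=51, copies=20, tmpdir=tmp, coverage=100)

est = result["estimate"]
print(f"planted tandem copies : {result['true_copies']}")
print(f"operon median depth   : {est.operon_median_depth:.0f}x")
print(f"backbone median depth : {est.backbone_median_depth:.0f}x "
      f"(over {est.n_backbone_contigs} longest contigs)")
print(f"haploid copy number   : {est.haploid_copies:.2f} "
      f"(rounded {est.rounded_copies}; {100 * result['relative_error']:.1f}% off truth)")
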