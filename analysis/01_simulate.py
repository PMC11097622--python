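#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Writes feature tracks (eight human-specific classes), candidate locus sets
(11 familial, 42 GWAS, 60 pleiotropic on the toy genome), a variant table
with planted EUR-vs-AFR frequency shifts, two GWAS association lists with
planted sub-significant hits, expression matrices, and the truth manifest,
under results/simulated/.
"""

from pathlib import Path

from rdscan.synthetic import SyntheticConfig, simulate

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20240501

config = SyntheticConfig(seed=SEED)
manifest = simulate(config, OUTDIR)

n_overlap = sum(c == "overlapping" for c in manifest.locus_class.values())
print(f"simulated inputs -> {OUTDIR}")
print(f"  loci: {len(manifest.locus_class)} ({n_overlap} planted on human-specific elements)")
print(f"  variants: {len(manifest.variant_direction)}")
print(f"  associations: {len(manifest.association_class)} "
      f"({len(manifest.planted_host_loci)} planted host loci)")
print(f"  genes: {len(manifest.gene_class)}; "
      f"human-restricted pairs: {len(manifest.human_restricted_pairs)}")
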