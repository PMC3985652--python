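#!/usr/bin/env python
"""Simulate the synthetic study cohort: one toy genome (2 x 5 Mb, 400
genes, 20 LADs) with an H1.2-like and an H1X-like ChIP library plus
matched inputs, written as a plain-text fixture bundle.

The read BEDs are large, so the bundle goes under scratch/; downstream
scripts read it from there. Run from the repository root:

    python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from h1scape.synth import H12_LIKE, H1X_LIKE, generate_genome, write_bundle
from dataclasses import replace

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
outdir = Path("scratch/bundle")

truth = generate_genome(seed=seed)
models = [replace(H12_LIKE, seed=seed + 1), replace(H1X_LIKE, seed=seed + 2)]
write_bundle(truth, models, outdir)

print(f"genome: {len(truth.genome.chrom_names)} chromosomes, "
      f"{truth.genome.total_bp:,} bp")
print(f"genes: {len(truth.genes)} ({int(truth.genes.df['in_lad'].sum())} in LADs), "
      f"LADs: {len(truth.lads)} covering "
      f"{truth.lads.total_bp_in(truth.genome):,} bp")
print(f"libraries: {[m.name for m in models]} at depth {models[0].depth:,}")
print(f"bundle written to {outdir}/")
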