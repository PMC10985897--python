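"""Generate a synthetic multi-cell-type methylome dataset with known truth.

Builds a 300-kb genome, plants 30 CHG-hypermethylated regions in microspore
and 10 sexual-lineage loci, then writes cytosine reports (one per replicate),
a BED annotation, truth tables and a sample manifest — the exact file set the
pipeline consumes.
"""

from pathlib import Path

from dmrkit import TruthProfile, build_genome
from dmrkit.simulate import plant_dmrs, plant_slh_loci, write_dataset

out = Path("scratch/example_dataset")
genome = build_genome(seed=1, chrom_sizes={"chr1": 300_000})
cells = {"meiocyte": 2, "microspore": 2, "sperm": 2, "seedling": 2}

truth = TruthProfile.uniform(cells)
truth = plant_dmrs(genome, truth, n_regions=30, context="CHG", delta=0.4,
                   cell_type="microspore", seed=1)
truth = plant_slh_loci(genome, truth, n_loci=10, seed=1)

manifest = write_dataset(out, genome, truth, cells, coverage_mean=30, seed=1)

n_cyt = sum(len(df) for df in genome.cytosines.values())
print(f"genome: {sum(genome.chrom_sizes.values()):,} bp, {n_cyt:,} cytosines, "
      f"{len(genome.annotation)} annotated features")
print(f"planted: {len(truth.planted_regions)} CHG regions (+0.4 in microspore), "
      f"{len(truth.planted_slh)} sexual-lineage loci")
print(f"wrote {len(manifest.entries)} cytosine reports + manifest to {out}")
# Each report lists chrom, 1-based position, strand, methylated and
# unmethylated read counts, and CG/CHG/CHH context, exactly as a bisulfite
# methylation extractor would emit them.
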