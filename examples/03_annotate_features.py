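"""Feature annotation: where do stranded vs unstranded R-loops fall?

Assigns each called R-loop to promoter-TSS / exon / intron / downstream-TTS
/ pseudogene / intergenic by its midpoint (promoter window -2.5/+0.5 kb of
the TSS, downstream -0.5/+2.5 kb of the gene end, strand-aware) and reports
observed / expected counts, where expected follows the genomic bp share of
each class.
"""

from rloopkit.annotation import FeatureMap, expression_tertiles, gene_rloop_overlap, observed_expected
from rloopkit.pipeline import run_pipeline
from rloopkit.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=7), mark_spec={})
res = run_pipeline(ds.treatments, ds.controls, ds.truth.chrom_sizes)
fmap = FeatureMap(ds.truth.chrom_sizes, ds.truth.genes)

for label, df in (("stranded", res.rlset.stranded), ("unstranded", res.rlset.unstranded)):
    tab = observed_expected(df, ds.truth.genes, ds.truth.chrom_sizes, fmap)
    print(f"\n{label} R-loops (n={len(df)}):")
    print(tab.round(3).to_string(index=False))
# ratio > 1 means the class is over-represented relative to a uniform
# placement over the genome.

tertiles = expression_tertiles(ds.truth.expression)
table = gene_rloop_overlap(res.rlset, ds.truth.genes, ds.truth.chrom_sizes, tertiles=tertiles)
print("\ngenes by R-loop category:",
      table["rloop_category"].value_counts().to_dict())
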