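# mitodiff

Comparative analysis of circular plant mitochondrial genomes, built for
the question behind cytoplasmic male sterility (CMS): *how does the
mitochondrial genome of a sterile line differ from its isonuclear
maintainer, and which of those differences could cause pollen abortion?*
The canonical use case is the wheat K-type pair — the CMS line Ks3
(647,559 bp master circle) versus its maintainer Km3 (452,526 bp) — but
every stage works on any pair of annotated circular genomes.

The pipeline covers the full comparison:

- **Repeat families** — direct (DR) and inverted (IR) repeats ≥ 100 bp on
  a circular genome, with per-family copy coordinates, gap-inclusive
  aligned length, mismatch/indel counts and identity
  `100·(aligned − mismatch − indel)/aligned`;
- **Homology & unique regions** — shared segments between two genomes
  (native seed–chain–extend search, E-value ≤ 0.001), coverage
  statistics, line-specific regions (U1…) with copy grouping and source
  annotation against local reference sets (chloroplast, relatives,
  elements);
- **CDS SNPs** — substitutions between orthologous genes, classified
  synonymous/non-synonymous under the standard genetic code and
  transition/transversion, in the layout of published difference tables;
- **ORF screening** — six-frame ATG…stop ORFs (origin-spanning included),
  uniqueness classes including the chimeric "two discrete segments"
  signature, and CMS-candidate geometry flags (upstream of / overlapping
  known genes — the orf256/cox1 and orf107/atp9 arrangements);
- **Multipartite structure** — subgenomic circle pairs from DR
  recombination (lengths summing to the parent), isomers from IR
  recombination, sequence-level crossover realization, and the reduced
  ("actual") genome size after removing redundant repeat copies;
- **Synteny** — circular gene orders (tRNAs excluded), maximal shared
  clusters allowing reversal, gene copy-number tables;
- **Synthetic data** — a maintainer/CMS-like genome pair generated from
  an explicit edit plan with full ground truth, so every stage is
  verifiable at desk scale.

## Worked example

Generate the reduced-scale synthetic study pair and run the comparison:

```python
from mitodiff import (simulate_pair, find_shared_segments, unique_regions,
                      coverage_stats, find_repeat_families, summarize_snps)
from mitodiff.variants import compare_gene_sets

anc, anc_feats, var, var_feats, ct, truth, plan = simulate_pair(seed=1)
print(anc.length, var.length)            # 50000 65203

segs = find_shared_segments(var, anc)
print(coverage_stats(segs, var, "query"))  # (58785, 90.2)

regions = unique_regions(var, segs)
print(len(regions), sum(r.length for r in regions))  # 8 6394

fams = find_repeat_families(var)
print([(f.id, f.orientation_class, f.aligned_length) for f in fams[:3]])
# [('R1', 'DR', 5000), ('R2', 'IR', 2002), ('R3', 'DR', 602)]

snps = compare_gene_sets(anc, anc_feats, var, var_feats)
print(summarize_snps(snps))
# {'total': 12, 'S': 4, 'N': 8, 'transitions': 6, 'transversions': 6, 'genes': 5}
```

Reading the output: the variant genome is 15.2 kb larger than its
ancestor; 90.2 % of it is covered by homology to the ancestor, and the
8 uncovered runs > 100 bp (6,394 bp) are its line-specific regions —
exactly the planted insertions, as `truth` confirms. The largest repeat
families are the planted 5 kb direct repeat and 2 kb inverted repeat
(sizes may exceed the planted span by a few chance-matching flank bases),
and the 12 planted CDS substitutions are recovered with their
synonymous/non-synonymous and transition/transversion labels.

The same session from the shell:

```bash
mitodiff simulate --seed 1 --out-dir sim
mitodiff compare sim/variant.fasta sim/ancestor.fasta --ct sim/chloroplast.fasta --out-dir out
mitodiff snps sim/ancestor.fasta sim/ancestor.gff3 sim/variant.fasta sim/variant.gff3 --out-dir out
```

Bundled reference tables of the published Ks3/Km3 comparison (repeat
families, SNPs, unique ORFs) are available from `mitodiff.datasets` and
feed the worked-example checks — e.g. `reduced_genome_size` on the repeat
table returns 374,407 bp, bracketing the published ~400 kb estimate of
the non-redundant genome.

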