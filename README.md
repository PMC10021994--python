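# karyolink

Linkage mapping and recombination-landscape analysis for haploid
(homokaryotic) fungal mapping populations.

karyolink takes a VCF of biallelic SNP calls for a set of haploid offspring
plus one sequenced parental homokaryon, an assembly (FASTA or length index)
and optionally a GFF3 gene annotation, and provides:

* **io_formats** — VCF/FASTA/GFF3/BED/TSV readers and writers with parental
  phase resolution (the parent's allele is `P1` everywhere).
* **marker_filtering** — the strict and lenient marker filter cascades:
  call-count/allele-frequency/heterozygosity rules, heterokaryon sample
  detection, binomial segregation-skew test, double-crossover island
  filter, small-linkage-cluster filter.
* **linkage_core** — two-point recombination fractions and LOD scores,
  single-linkage grouping (LOD > 5.5), greedy + 2-opt marker ordering,
  Haldane/Kosambi map functions, a physically anchored "forced order" map
  built by chaining contigs whose distal markers are linked, forward-fill
  imputation, map summaries (cM/Mb, assembly fractions) and the r-bar
  shuffling statistic.
* **recombination_landscape** — per-interval crossover counts tested
  against a marker-distance-weighted multinomial null (10,000 resamples),
  Benjamini-Hochberg correction per tail, ~500 kb interval binning,
  distance–crossover Spearman correlation, genetic-vs-physical profiles.
* **genome_features** — telomere motif (`CACTAA`/`TTAGTG`) runs at contig
  ends, sliding-window GC and gene density (30 kb / 10 kb), gene-free
  AT-rich centromere candidates, intergenic-space extraction and a
  uniform-gene-placement (Dirichlet stick-breaking) spacing null.
* **synthetic_data** — a deterministic meiosis simulator: multi-contig
  assemblies carved from hidden chromosomes, obligate + Poisson
  crossovers, hotspot multipliers, viability-based segregation distortion,
  heterokaryon contaminants, missing/error noise, and ground-truth files,
  so the whole pipeline is testable without any sequencing data.

## CLI

```sh
# synthetic dataset (VCF + FASTA + GFF3 + truth JSON)
karyolink simulate --seed 42 --n-offspring 88 --sequences --n-genes 500 --out data/

# strict filter cascade with a per-rule report
karyolink filter --vcf data/genotypes.vcf --parent parent --mode strict \
    --report report.tsv --out filtered.tsv

# strict or forced-order linkage map
karyolink map --vcf data/genotypes.vcf --parent parent --mode forced \
    --fai data/assembly.fai --out map.tsv --chains-out chains.tsv

# recombination landscape (multinomial resampling test + 500 kb bins)
karyolink landscape --vcf data/genotypes.vcf --parent parent \
    --draws 10000 --seed 17 --out-prefix landscape

# genome-architecture scans
karyolink features --fasta data/assembly.fasta --gff data/genes.gff3 \
    --out-prefix features
```

## Tests

```sh
python -m pytest tests/
```

The suite includes unit tests per module, hypothesis property tests
(idempotent filters, BH against statsmodels, phase-flip invariance) and an
acceptance suite (`tests/test_acceptance.py`) covering published map
summaries, simulator parameter recovery, FDR control and hotspot power of
the resampling test, and exact-arithmetic oracles.

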