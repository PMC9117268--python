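# multiclip

Downstream analysis of PAR-CLIP crosslink data for multivalent RNA-binding
proteins, together with the companion assays that place the binding in
context: membrane/cytosol mRNA localization from fractionation RNA-seq,
crosslinked k-mer and motif-multivalency statistics, ribosome-profiling
P-site metagenes and codon occupancy, tRNA crosslink enrichment with
modification masking, and BioID/pSILAC/RIP proteomics filters. A
synthetic-data generator with planted ground truth makes every stage
verifiable end to end without any deposited dataset.

## Who this is for

Groups analyzing PAR-CLIP (or similar transition-based CLIP) data for an
RNA-binding protein with many tandem domains, where the question is not
just *where* the protein binds but whether binding is **multivalent** —
several short motifs engaged simultaneously within a window — and how that
relates to mRNA localization and translation. The pipeline starts from
transcript-space tables (per-position pileups of coverage and T→C
mismatches, BED-like cluster tables, count matrices); alignment and
cluster calling are upstream and out of scope.

## The statistics at the core

- **Crosslink signal.** At position *i*, the T→C count marks a crosslinked
  uridine; transition specificity TC_i / coverage_i < 0.95 separates
  crosslinks from genomic variants, and sites must be present in both
  replicates. Clusters are reproducible when they overlap reciprocally by
  ≥50%, their T-C peaks are ≤10 nt apart, and mean T-C ≥ 3. Per-gene
  enrichment E = ΣTC / TPM corrects expression bias.
- **Localization.** M = log2(membrane / cytosol) on median-of-ratios
  normalized counts; membrane iff M ≥ 1.5, cytosolic iff M ≤ 0.5, for
  genes with TPM ≥ 10.
- **Multivalency.** For each crosslink site, the multivalency score *m*
  counts occurrences of a high-affinity four-mer group (default: the top
  ten crosslinked four-mers, a CU-rich set) starting within ±40 nt of the
  site, excluding the innermost ±4 nt. Sites are binned into quintiles of
  *m*, and the crosslink signal within the window rises with the bin when
  binding is multivalent.
- **Translation.** P-site = footprint 5′ end + 13 nt. Metagenes are
  scale-then-average (per-transcript normalization to codons 20–40, or to
  the trimmed CDS mean); codon occupancy shifts are footprint-weighted
  frequency differences over the 61 sense codons (Σdelta = 0 by
  construction).

See `docs/methods.md` for the full model descriptions, parameter defaults,
and generator assumptions.

## Worked example

```python
import pandas as pd
import multiclip as mc

# synthetic dataset with planted CU-rich hotspots in membrane-class CDS
tx, truth = mc.simulate_transcriptome(n_genes=200, seed=7)
pileups, clusters = mc.simulate_parclip(tx, truth, seed=7)

kept = mc.filter_reproducible_clusters(clusters[0], clusters[1])
sites = mc.normalize_tc_per_million(mc.filter_sites(pileups[0], pileups[1], tx))
print(f"{len(kept)} reproducible clusters, {len(sites)} reproducible T-C sites")

ranked = mc.count_crosslinked_kmers(sites, tx, k=4)
print(ranked.head(4).to_string(index=False))

group = [k.replace("U", "T") for k in ranked["kmer"].head(10)]
rec, profiles = mc.multivalency_scores(sites, tx, group)
print(rec.groupby("bin")["window_tc"].mean().round(1).to_string())

counts = mc.simulate_fraction_counts(tx, truth, seed=7)
m = mc.membrane_enrichment(counts, ["membrane_1", "membrane_2"],
                           ["cytosol_1", "cytosol_2"])
print(mc.classify_localization(m, pd.Series(truth.tpm())).value_counts().to_string())
```

prints

```
987 reproducible clusters, 27324 reproducible T-C sites
kmer  count  frequency  rank
UCUU   4012   0.036745     1
UUCU   3693   0.033823     2
CUCU   2436   0.022311     3
CUUC   2427   0.022228     4
bin
1    259.0
2    357.0
3    458.0
4    660.5
5    995.3
localization_class
cytosolic    123
membrane      68
undefined      9
```

The four planted motifs occupy the top four crosslinked four-mer ranks;
the mean window crosslink signal rises monotonically across multivalency
quintiles (bin 5 ≈ 4× bin 1) — the signature of multivalent binding; and
the localization classifier recovers the planted class mixture (the few
`undefined` calls are genes whose planted enrichment scatter lands between
the 0.5/1.5 cutoffs).

## Command line

The same stages are available as subcommands of one executable:

```sh
multiclip simulate --seed 5 --out sim/
multiclip crosslink --fasta sim/transcripts.fasta --regions sim/regions.tsv \
    --pileup1 sim/pileup_rep1.tsv --pileup2 sim/pileup_rep2.tsv \
    --clusters1 sim/clusters_rep1.bed --clusters2 sim/clusters_rep2.bed \
    --tpm tpm.tsv --out crosslink/
multiclip multivalency --fasta ... --sites crosslink/sites_reproducible.tsv --out mv/
multiclip ribo --fasta ... --signals sim/signals.tsv --footprints sim/footprints.tsv --out ribo/
multiclip trna --pileups ... --abundance ... --masks ... --out trna.tsv
multiclip proteomics --lfq sim/bioid_lfq.tsv --silac sim/silac_pairs.tsv --out prot/
```

Every subcommand accepts `--config` (INI-style, one section per stage,
unknown keys rejected); the resolved configuration and seed are logged to
stderr.

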