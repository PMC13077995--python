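# ms2drs

Analysis pipeline for Nanopore direct RNA sequencing (DRS) of the MS2
bacteriophage transcriptome, for virologists and transcriptomics analysts
dissecting what a small (+)ssRNA phage actually transcribes inside its host.
A DRS run of MS2-infected *E. coli* mixes several read populations that are
easy to conflate: full-length genomic reads, truncated reads produced by the
technology's 3' bias (DRS sequences RNA 3'→5', so incomplete reads keep the
genomic 3' end), 5'-anchored degradation products, internal subgenomic reads
carrying the *coat* ORF, negative-strand replication intermediates, chimeric
reads from replicase template switching, and modified bases with a high
false-positive call rate. `ms2drs` separates and quantifies all of them.

## What it computes

* **Read classification** — reads spanning ≥ 90% of the *L* = 3,569 nt
  genome are full-length; shorter reads are assigned, in precedence order,
  to 3'-anchored (DRS bias), 5'-anchored (degradation), *coat* / *coat+lys*
  subgenomic (≥ 90% ORF coverage), or other internal classes, with
  per-timepoint proportions and < 800 nt / > 3,000 nt length fractions.
* **Start/end hotspots** — per 5-bp window *w* and strand, the statistic
  `ratio(w) = starts(w) / depth(w)` normalised by the genome-wide median
  ratio; windows with fold ≥ 5 at depth ≥ 50 are hotspot calls, annotated
  with nearby start/stop codons and tested for AG (purine) richness in the
  5' flank by a one-sided exact binomial test with Benjamini–Hochberg FDR.
* **Hybrid reads** — local-alignment segments (k-mer seeding + maximal
  ungapped extension under Smith–Waterman scoring +1/−2, gapped refinement
  −4/−2) are chained per read; reads mapping to ≥ 2 distinct loci are typed
  pos_pos / neg_neg / neg_pos / pos_neg / foldback, and same-strand
  junctions get a signed offset Δ in transcript orientation: Δ > 0 is a
  deletion (template skipped Δ nt), Δ < 0 a duplication, with the
  characteristic 20–60 nt range flagged.
* **Modification dynamics** — per-site stoichiometry = fraction of covering
  reads with call probability > 0.8; sites survive only if
  stoichiometry(test) − stoichiometry(IVT) > 0, where IVT is an unmodified
  in vitro transcribed control; significance by Fisher's exact test with
  BH-FDR per comparison family; temporal labels
  (increase/decrease/no_difference) per consecutive timepoint pair.

A synthetic-data generator (`ms2drs.synthetic`) produces an MS2-like genome
and every one of these read populations with ground-truth labels, so the
whole pipeline is testable end to end without sequencing data.

## Worked example

```python
from ms2drs import (make_genome, simulate_reads, simulate_hybrids,
                    detect_hybrids, classify_reads, class_proportions)
from ms2drs.synthetic import SimConfig

genome = make_genome(seed=1)                      # 3,569 nt, mat/coat/lys/rep
cfg = SimConfig(seed=1, n_reads=2000, timepoint="40min", error_rate=0.02)
reads, seqs, quals, truth = simulate_reads(genome, cfg)
props = class_proportions(classify_reads(reads, genome))
print(props[["read_class", "count", "proportion"]].to_string(index=False))
```

```
          read_class  count  proportion
     coat_subgenomic    286      0.1430
 five_prime_anchored    406      0.2030
         full_length    619      0.3095
      other_internal     97      0.0485
three_prime_anchored    592      0.2960
```

The recovered proportions match the simulated mixture (0.15 / 0.20 / 0.30 /
0.05 / 0.30) to sampling noise. Adding five template-switch chimeras and
detecting them:

```python
hyb, _, _ = simulate_hybrids(genome, [("pos_pos_deletion", 5, (20, 60))],
                             seed=2, error_rate=0.02)
calls = detect_hybrids({**seqs, **hyb}, genome)
for c in calls[:3]:
    print(c.read_id, c.junction_type, c.event, c.delta, c.junction_ref_positions)
print(f"hybrid ratio: {len(calls)}/{len(seqs) + len(hyb)}")
```

```
test_0h_h00000 pos_pos deletion 54 (973, 1027)
test_0h_h00001 pos_pos deletion 59 (2764, 2824)
test_0h_h00002 pos_pos deletion 56 (2963, 3020)
hybrid ratio: 5/2005
```

All five chimeras are recovered (none of the 2,000 plain reads is called),
each as a positive-strand deletion junction whose 1-based ligation
positions and Δ match the simulation.

The same stages are available from the shell:

```bash
ms2drs simulate --outdir run --seed 3 --n-reads 2000 --timepoint 40min
ms2drs classify --genome run/genome.fasta --annotation run/orfs.gff3 \
                --alignments run/reads.sam --outdir run/out
ms2drs hybrids  --genome run/genome.fasta --annotation run/orfs.gff3 \
                --reads run/reads.fastq --outdir run/hyb
ms2drs run-all  --config run_config.json
```

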