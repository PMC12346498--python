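# mitokit

Structural and post-transcriptional analysis of plant organelle genomes:
repeat content, repeat-mediated recombination testing with long reads,
mitochondrial plastid DNA (MTPT) detection, and C-to-U RNA-editing site
calling with SNP subtraction.

## Who this is for

Plant mitochondrial genomes are large, slow-mutating but structurally fluid
molecules: they carry microsatellites, long tandem arrays, and dispersed
repeats whose copies can recombine intramolecularly and reshuffle the
chromosome; they absorb chloroplast DNA fragments (MTPTs); and their
transcripts are heavily edited, mostly cytidine→uridine in coding regions.
`mitokit` is a library (plus a thin `mitokit` CLI) for the post-assembly
questions these genomes raise, with a first-class synthetic-data module that
plants every feature class with recorded truth — so each detector can be
validated offline, end to end, against known answers.

## The methods at the core

- **SSRs** — maximal perfect tandem runs of a primitive 1–6 bp unit with
  MISA-convention copy minima (mono ≥ 10, di ≥ 5, tri ≥ 4, tetra/penta/hexa ≥ 3).
- **Long tandem repeats** — arrays with period 7–500 found on the self-match
  profile at lag *p* and scored `+2·matches − 7·mismatches` against the
  array's majority consensus; reported at score ≥ 50 (a perfect array of
  total length *L* scores 2*L*).
- **Dispersed repeats** — exact maximal non-adjacent pairs ≥ 50 bp, direct
  (F) or palindromic (P), via seed-and-extend with containment suppression;
  multi-copy repeats appear as their pairwise closure.
- **Recombination testing** — each repeat pair plus 500 bp flanks defines
  four conformations: `ref1 = upA·R·downA`, `ref2 = upB·R·downB`, and the
  flank-exchange products `rec1 = upA·R·downB`, `rec2 = upB·R·downA` (copy-B
  context reverse-complemented into copy-A's frame for P pairs). A long read
  is informative when it spans the repeat plus ≥ 100 bp of both flanks at
  ≥ 80% identity; best-hit assignment with near-ties counted ambiguous gives
  the recombination frequency `(rec1+rec2)/(ref1+ref2+rec1+rec2)`.
- **MTPTs** — blastn homology between mitogenome and plastome, hits merged
  on the mitochondrial axis (≥ 30 bp, ≥ 70% identity), annotated with
  contained plastid genes and validated by reads spanning the insertion plus
  both mitochondrial flank anchors.
- **RNA editing** — REDItools-style gene-centric calling on CDS ± 100 bp
  references: a site needs alternative-base frequency ≥ 0.10 at coverage ≥ 5;
  DNA reads are called identically and coinciding sites subtracted; C→T
  sites are classified by codon position and effect (synonymous /
  nonsynonymous / stop gain / start gain).

## Worked example

```python
from mitokit import (GenomeRecord, build_conformations, count_support,
                     find_dispersed_repeats, make_toy_organelles,
                     simulate_long_reads)

mito, plastid, feats, truth = make_toy_organelles(seed=1)
pair = find_dispersed_repeats(mito)[0]          # DRS1: F, 300 bp
conf = build_conformations(mito, pair, flank=500)

mixture = [(GenomeRecord(id="ref1", seq=conf.ref1), 0.35),
           (GenomeRecord(id="ref2", seq=conf.ref2), 0.35),
           (GenomeRecord(id="rec1", seq=conf.rec1), 0.15),
           (GenomeRecord(id="rec2", seq=conf.rec2), 0.15)]
reads = simulate_long_reads(mixture, n=500, mean_len=1200, error_rate=0.05, seed=11)
support = count_support(conf, reads)
print(support.counts, support.recombination_frequency)
```

prints

```
{'ref1': 175, 'ref2': 172, 'rec1': 66, 'rec2': 66} 0.2756...
```

Of 500 simulated reads, 479 were informative; 132 supported a recombinant
conformation, estimating the planted 30% recombinant molecule fraction as
27.6% — within binomial sampling error. With reads drawn from the reference
genome only, both `rec` counts stay at zero, the signature of a repeat pair
that does not mediate recombination. The `examples/` directory holds one
short script per capability (simulation, repeat scans, recombination, MTPT,
RNA editing), each printing what it computes and what the numbers mean.

The same analyses run from the shell:

```bash
mitokit simulate --out data --seed 1
mitokit dispersed --fasta data/mito.fasta --out drs.tsv
mitokit recomb --fasta data/mito.fasta --pairs drs.tsv \
    --reads data/long_reads.fastq --out recomb.tsv
mitokit report --out run1 --seed 1      # full pipeline + report.json
```

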