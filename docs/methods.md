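# Methods

This note documents the models and procedures behind each analysis stage,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates, alphabet, reporting conventions

All external coordinates are 1-based inclusive. Sequences are uppercase over
{A, C, G, T, N}; U normalises to T on input; IUPAC ambiguity codes beyond N
are rejected. Palindromic repeat copies may be *written* with start > end in
report tables to signal orientation, but are stored internally as forward
intervals. Reported frequencies and percentages are rounded half away from
zero to two decimals (the convention of published pileup tables); internal
comparisons always use full precision. Translation uses the standard genetic
code (table 1): plant mitochondria use the universal code, and the canonical
editing-derived stops (CAA→UAA, CGA→UGA) are consistent with it. Circular
topology is supported for interval extraction (wrap-around slices); all
analyses otherwise treat the molecule as linear.

## SSR scanning

SSRs are maximal perfect tandem runs of a primitive 1–6 bp unit whose full
copy count meets the per-unit-size minimum (1→10, 2→5, 3→4, 4/5/6→3 units).
"Below 10, 5, 4, and 3 units" in tool descriptions of these thresholds is
read as "at least", the MISA convention and the standard meaning of a
minimum-repeat-number cutoff. Runs are detected on the lag-*p* self-match
profile; a run is reported once, under its primitive unit (a poly-A run is
mono, never di), with partial trailing copies dropped so that interval
length = unit × copies. When two runs of the same unit size overlap by up to
*p* − 1 bases (phase-shifted reports), the later run is trimmed to start
after the earlier one, left to right — a deterministic tie-break that keeps
same-size records disjoint. Compound SSRs are reported as separate adjacent
records; only perfect repeats are modelled, matching the simple-SSR model of
standard scanners.

## Long tandem repeats

Arrays with unit length ≥ 7 and period ≤ 500 are found per period on the
self-match profile: maximal match runs are chained across substitution gaps
while each extension pays for itself under weights (+2 match, −7 mismatch),
then weak boundary runs are trimmed. Each candidate array is scored against
its per-offset **majority consensus** (+2 per consensus match, −7 per
substitution; alphabetical tie-break within a column) and reported when the
score reaches 50 and the copy number reaches 1.9. A perfect array of total
length L scores 2L. Consensus scoring values an array identically at every
period that describes it, so the collapse of multi-period reports (a
period-10 array also matches itself at lag 20, 30, ...) resolves to the
smallest period deterministically.

The detector models substitutions only: an indel inside an array shifts the
register and truncates the array at that point rather than being bridged.
This is a deliberate departure from Tandem Repeats Finder's stochastic
k-tuple heuristic — the detector is exact and reproducible for perfect and
substitution-degraded arrays, which is what the synthetic truth plants and
what the tests certify; exact concordance with TRF on real genomes is not a
goal.

## Dispersed repeats

Exact maximal repeated pairs ≥ `min_len` (default 50 bp, accepted down to 8)
on the same strand (F) or opposite strands (P), found by seed-and-extend:
every shared k-mer (k = min(21, min_len)) that cannot be extended one base
left seeds a maximal match extended right. Near-exact matching (the
blastn-based behaviour of organelle repeat finders) is approximated by
exactness; planted-truth recovery, not concordance with any published
genome-specific count, is the primary acceptance surface.

Filters, in order: copies that overlap or abut are excluded (tandem, not
dispersed); a pair whose copy is itself a tandem array (primitive period
≤ length/2) and whose whole copy1→copy2 span continues that periodicity is
excluded as an echo of a single array; pairs wholly contained in a longer
kept pair (both copies inside the container's copies, in either assignment)
are suppressed, so a long duplication is one record rather than a cloud of
sub-repeats. Repeats with more than two copies emerge naturally as their
pairwise closure. Ids DRS1, DRS2, ... are assigned in descending length,
ties by first-copy start.

The packaged published repeat table ships with an `audit` function that
flags rows whose coordinates contradict their stated length or orientation
convention; it never guesses corrections. `effective_repeat_types`
classifies a row as palindromic when it is either labeled P or written with
a descending copy interval — the orientation convention — which reconciles
tables whose labels and coordinates disagree.

## Recombination testing

For a pair with copies A and B, four conformations are built from the
repeat R and flanks of `recomb_flank` (500) bases: `ref1 = upA·R·downA`,
`ref2 = upB·R·downB`, `rec1 = upA·R·downB`, `rec2 = upB·R·downA`. For P
pairs, copy B's context is first reverse-complemented into copy A's frame
(so `upB = revcomp(genomic downstream of B)`), making all four read the
repeat in one orientation; `ref2` is then the reverse complement of a
genomic substring, which is equivalent for orientation-free reads. Flanks
truncate at genome ends and the truncation is recorded.

A read supports a conformation when that conformation's *informative
window* — the repeat plus up to `recomb_min_anchor` (100) bases of both
flanks — aligns inside the read (either strand, edlib infix alignment) at
identity ≥ `recomb_min_identity` (0.80). The spanning-window criterion is a
declared substitute for the unstated mapping criterion of read-mapping
pipelines: it is exactly the requirement that a read cross from one flank,
through the whole repeat, into the other flank, which is what discriminates
conformations. Reads are assigned best-hit only; a read whose best window
beats the runner-up by ≤ 0.05 identity is counted ambiguous rather than
assigned, because windows sharing the repeat differ only in their anchors
(≈ 0.15 identity over an informative window for unrelated flanks), so
genuine assignments clear the margin while reads that only partially cover
one anchor — whose relative scores are alignment noise — do not. This
margin is what keeps the false-recombinant rate at zero on reference-only
read sets. Pairs whose smallest window exceeds every read are reported
untestable, not "non-recombining": the recombination frequency
(rec1+rec2)/(all informative) is undefined rather than zero there.

## MTPT detection and validation

Homology search runs the installed NCBI `blastn` binary (`-task blastn`,
tabular output) with the mitogenome as query; the vague "default
parameters" of common practice are replaced by explicit post-filters:
hit length ≥ 30 bp and identity ≥ 0.70. Hits overlapping or abutting on the
mitochondrial axis merge into one fragment (plastid interval and strand
from the highest-scoring constituent, identity length-weighted), because an
insertion is one event even when local alignment fragments it. Gene content
is interval arithmetic on the plastid axis: a gene is complete when fully
inside the hit's plastid interval, partial when properly overlapping;
inverted-repeat membership is checked against caller-supplied IR intervals
(they are an annotation input, not inferred). Direction of transfer is not
decided.

Validation requires a read in which the full insertion aligns (infix, edit
budget 20% of its length) *and* each mitochondrial flank anchor (100 bp)
aligns at ≥ 80% identity immediately beside the insertion's location in the
read. Anchors are checked separately from the core on purpose: a read
drawn from the plastid matches the insertion body perfectly but carries
plastid context, and a whole-window edit budget would let it pass — two
unrelated 100 bp anchors align at ≈ 0.45–0.55 identity, inside a 20% budget
spread over a long window but far outside a per-anchor budget. A hit is
`untested` when no read is long enough to span insertion plus anchors.

## RNA-editing calling

Calling is gene-centric: each gene's reference is its spliced CDS plus
`cds_flank` (100) bp of genomic context on both sides, in mRNA orientation
(minus-strand genes reverse-complemented). Short reads are placed by a
built-in exact/near-exact ungapped mapper (k-mer seeds at several read
offsets, both strands, best placement by mismatch count, capped at 15%
mismatches) suited to the error-free or substitution-only reads the package
simulates; externally aligned SAM is accepted as an alternative source, with
soft-clipped and off-reference bases excluded.

A column becomes a site when coverage ≥ `edit_min_cov` (5) and at least one
alternative base alone reaches `edit_min_freq` (0.10). The reported
frequency is the column's **combined non-reference frequency** — the
convention of published pileup tables, which list one row per column with
all observed substitutions (`AllSubs`) including sub-threshold ones, and
one Frequency value. A site is therefore one record carrying an `alts` list
rather than one record per alternative. Sites with frequency > 0.20 carry a
`focus` flag; the default report keeps the 0.10 threshold and exposes both.
Flank columns get negative (5') or over-length (3') CDS indices and are
excluded from codon classification and summaries. All substitution types
are called; C→T in CDS orientation is flagged C-to-U, and a `--c2u-only`
switch restricts the classified output to those.

SNP subtraction removes RNA sites whose (gene, CDS position) coincides with
any DNA-read variant — matched on position only, not allele, since a
genomic polymorphism at a position disqualifies the site regardless of
which base it shows. Codon effects substitute the site's primary
(highest-count) alternative into its codon: synonymous when the amino acid
is unchanged, stop gain when a sense codon becomes a stop, start gain when
codon 1 becomes ATG, nonsynonymous otherwise; classification is verified in
tests against a mutate-whole-CDS-translate-compare oracle.

## Synthetic data: what it emulates, and what it does not

The generator builds an i.i.d.-background mitogenome (default 60 kb, GC 45%,
mirroring typical plant mitochondrial composition) and plastome (30 kb, GC
37%) and overwrites windows with: ≥ 3 protein-coding genes (random non-stop
codons between ATG and TAA, plus and minus strands), one SSR per unit-size
class, two tandem arrays (13 bp × 4 and 10 bp × 25), one F and one P
dispersed pair (each with a recombinant molecule fraction, default 0),
and two plastid-segment insertions (identity 1.0 and 0.95). Sizes were
chosen so the whole pipeline exercises in seconds; feature counts are one
or two per class because the tests compare *sets of coordinates*, not
abundances.

Three design choices make truth exact rather than approximate. Boundary
guards: after planting, single background bases adjacent to each repeat are
set so the planted repeat is maximal exactly at its recorded coordinates
(otherwise a chance matching neighbour would extend it). Scrubbing: the
assembled genome is rescanned for chance background SSRs, and each is
disrupted by one base change — mirrored into duplicated loci (partner
repeat copy, complemented for P; MTPT plastid source) and chosen to avoid
creating in-frame stops inside genes — so the planted SSR set is the whole
SSR set. Provenance: read names carry source record, interval, and strand,
so support-counting tests can compare assignments against labels without
any external aligner.

Long reads draw log-normal lengths (σ = 0.25) around the requested mean,
uniform starts, random strand, and errors split 50% substitution / 25%
insertion / 25% deletion — the indel-dominated profile of nanopore data —
at a uniform per-base rate up to 0.3. Not emulated: homopolymer-dependent
error bias, quality-score structure (a constant Q is written), chimeric
reads, PCR duplicates, or strand-specific library artefacts (RNA reads are
generated directly in CDS orientation). Short reads are error-free outside
planted sites and tile the reference near-uniformly per depth pass, so
coverage is essentially exact except within a read length of the reference
ends. Passing tests therefore certify the *logic* of every detector under
controlled noise — exact recovery at zero noise, binomially calibrated
frequency recovery under mixtures — not robustness to the full error
structure of real instruments.

All randomness flows from a single integer seed through NumPy generators;
identical seeds give byte-identical FASTA/FASTQ/TSV/JSON outputs, and the
pipeline writes a run manifest (version, seed, parameters, input digests).

## Parameter summary

| Parameter | Default | Meaning |
|---|---|---|
| `ssr_min_units` | 10/5/4/3/3/3 | minimum full copies per SSR unit size 1–6 |
| `ltr_min_unit`, `ltr_max_period` | 7, 500 bp | tandem-array period range |
| `ltr_min_score` (+2/−7/−7) | 50 | consensus alignment score floor |
| `drs_min_len` | 50 bp | dispersed-repeat length floor |
| `recomb_flank` | 500 bp | flank length in conformation construction |
| `recomb_min_anchor` | 100 bp | flank anchor a spanning read must cover |
| `recomb_min_identity` | 0.80 | identity floor for read support |
| `mtpt_flank` | 1000 bp | flank extracted around an MTPT for validation |
| `cds_flank` | 100 bp | genomic context in gene-centric references |
| `edit_min_freq`, `edit_min_cov` | 0.10, 5 | site-calling thresholds |
| `edit_focus_freq` | 0.20 | `focus` flag threshold |

`drs_min_len`, `recomb_min_anchor`, and `recomb_min_identity` are this
package's declared choices where common practice leaves the value implicit;
the rest follow the standard tool conventions named above.

## Known limitations

- Dispersed-repeat detection is exact-match; diverged repeat copies
  (mismatches between copies) are found only up to their exact sub-matches.
- The tandem detector does not bridge indels inside arrays.
- The built-in short-read mapper is ungapped and intended for simulated
  reads; use SAM input for real data aligned with a production mapper.
- The editing caller assumes spliced-CDS references; intron-containing
  references are out of scope.
- Recombination testing treats each pair independently; joint haplotype
  inference across repeats is not attempted.
- MTPT detection requires the `blastn` executable on PATH.
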