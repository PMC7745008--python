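# Methods

This note documents the models, numerical choices, and limitations behind
probecraft's probe-design pipeline.

## Oligo generation and thermodynamics

Targets are scanned with a sliding window (default 30 nt) from the 5′ end.
The two advance rules — accept → advance by one window length, reject →
advance 1 nt — make accepted oligos from one target adjacent and
non-overlapping, and make the whole procedure deterministic: there is no
randomness anywhere in scanning or filtering.

Duplex melting temperatures use the nearest-neighbor model with the
SantaLucia (1998) unified ΔH°/ΔS° parameter set, transcribed into
`thermo.NN_TABLES`. Conditions are fixed at the table's reference state:
1 M Na⁺ (no salt correction is applied — the `na_conc` parameter exists so
a correction could be added, but at 1 M it is the identity) and total
strand concentration C_T = 10⁻⁶ M. The log-term concentration is C_T/4 for
non-self-complementary duplexes and C_T for self-complementary ones, which
also receive the symmetry entropy term (−1.4 cal mol⁻¹ K⁻¹). The gas
constant is 1.987 cal mol⁻¹ K⁻¹. The implementation is validated in the
test suite against an independent nearest-neighbor summation
(Bio.SeqUtils.MeltingTemp with the same published table) to 10⁻⁶ °C on
1,000 random 20–40-mers.

Filter thresholds (defaults; all editable via the parameter table):

| parameter        | default | meaning                                          |
|------------------|---------|--------------------------------------------------|
| `window_length`  | 30 nt   | targeting-region length                          |
| `tm_min`         | 66 °C   | duplex T_m floor; a window at exactly 66 passes  |
| `gc_min`/`gc_max`| 30/90 % | GC bounds, inclusive                             |
| `max_run`        | 5 nt    | homopolymer cap; runs of 6+ rejected             |
| `stem_tm_max`    | 76 °C   | hairpin stem T_m ceiling                         |
| `crosshyb_tm_max`| 72 °C   | probe–probe hybridized-region T_m ceiling        |
| `probe_conc`     | 1e-6 M  | total strand concentration in the T_m log term   |

Filters run cheap-to-expensive (alphabet, GC, homopolymer, T_m, hairpin,
cross-hybridization) and short-circuit; the order is outcome-equivalent to
any other order for the pass/fail decision.

**Hairpin model.** Secondary structure is scored by perfect-stem
enumeration: every substring pair (stem ≥ 4 nt, loop ≥ 3 nt) whose halves
are exact reverse complements, scored by the stem's duplex T_m. This is a
deliberate simplification relative to free-energy folding (no bulges,
mismatched stems, or loop entropy): it is deterministic,
brute-force-checkable, and preserves the threshold semantics ("T_m of the
concatenated stem"). Users who need folding-grade stringency should lower
`stem_tm_max` to compensate, since perfect-stem T_m underestimates the
stability of long imperfect stems.

**Cross-hybridization.** Each candidate is locally aligned
(Smith–Waterman via Bio.Align; match +5, mismatch −4, gap open −8, gap
extend −6) against every accepted oligo and its reverse complement; the
exactly matching aligned columns are concatenated and that sequence's
duplex T_m is compared to `crosshyb_tm_max`. The accepted pool is shared
across all targets of a run and grows as the scan proceeds, so the measure
is monotone in the pool. The scoring values are recorded in `thermo` as
module constants; they are conventional nucleotide local-alignment scores,
chosen because the alignment routine itself is standard while no canonical
scoring exists for this screening step.

## Specificity model

Databases (genome, spliced and unspliced transcriptomes) are indexed by
exact k-mers (default k = 12). A hit is defined on ungapped full-length
placements of the oriented query (forward → plus/plus; reverse complement
→ plus/minus, always reported against the database plus strand): the best
contiguous alignment segment that starts and ends on a match, contains at
most 2 mismatching columns, and contains at least one exact k-mer run,
provided it has ≥ `min_matched` (default 18) matching columns. The exact
k-mer clause is part of the hit definition, not just the search heuristic —
it is what makes seed-and-extend provably complete, and the test suite
exploits this by checking exact agreement with an exhaustive
every-placement oracle. Overlapping hits at one locus are merged to the
best. Gapped similarity is out of scope for the built-in engine; the
BLAST+ backend (`blastn -task blastn-short`, e-value 10, dust off, tabular
output mapped onto the same hit records) covers users who want
NCBI-equivalent behaviour, and the backend contract (identical
retain/reject decisions on fixture data) is tested.

Rule sets per probe type:

* **chromatin** — keep oligos with exactly one genome alignment, both
  orientations combined (the self-locus). With `antisense_only`, oligos
  are re-screened against the unspliced transcriptome: no hits → keep;
  plus/plus hits only → keep the reverse complement (the probe then
  targets the antisense strand and cannot bind nascent RNA); plus/minus
  only → keep; both orientations → reject. With `avoid_exons`, any hit to
  a spliced transcript (either orientation — conservative, protecting
  combined DNA+RNA experiments) rejects the oligo.
* **merfish / smfish** — keep oligos whose plus/plus hits all fall on
  transcripts of the target gene (isoform-tolerant, cross-gene-intolerant).
  Only plus/plus hits matter because the probe is the oligo's reverse
  complement and binds RNA exactly where the oligo matches a transcript
  in plus/plus.

`min_matched` governs how much near-identity elsewhere in the genome is
tolerated (e.g. a 28/30 copy is rejected at the default); it is exposed in
the run configuration.

## MERFISH encoding

The barcode space is the weight-4 shell of the extended Hamming [16,11,4]
code: exactly 140 words of length 16 with four on-bits and minimum
pairwise Hamming distance 4, generated deterministically (messages →
parity bits → overall parity; shell sorted by on-bit positions). Capacity,
weight, and distance are verified exhaustively at test time.

Codeword assignment minimizes a bit-sharing load,
Σ_bits (Σ genes-on-bit expression)², greedily: genes sorted by expression
descending (ties by gene id) each take the unused codeword with the
smallest incremental load (ties by codeword index). The objective and the
greedy scheme are this package's own design — the goal (keep highly
expressed genes off shared bits) admits many formalizations; squared
per-bit load penalizes co-loading a bit with two bright genes by exactly
2·e₁·e₂, and the greedy result is never worse than the input-order
assignment (property-tested) and is compared against the exhaustive
optimum on a small instance in the tests. Probe i of a gene carries the
on-bit triplet that drops on-bit (i mod 4), first element upstream, the
other two downstream — a deterministic rule giving each readout presence
on exactly three of every four consecutive probes.

## Assembly and outputs

Template = forward primer + upstream readout(s) + targeting region +
downstream readout(s) + reverse complement of the reverse primer (both
primers stored 5′→3′). Primary probe = reverse complement of the template
without primers; in `primary` output mode primers are never attached.
Regions are concatenated directly (a configurable spacer exists, default
empty). Chromatin/smFISH targets consume readouts in input order, one per
target, never reused within a run; exhausting the library is an error
instructing the user to extend the readout table.

The shipped readout and primer tables are **synthetic placeholders**:
20-nt sequences generated once (seed 20201216, recorded in
`defaults.DEFAULT_SEED`), constrained to GC 40–60 %, homopolymer ≤ 4, and
no shared 12-mer across the combined pool on either strand. They preserve
the inventory sizes real designs use (50 chromatin readouts, 16 RNA
readouts — one per codebook bit — and three primer pairs, one per probe
type) but are not experimentally validated; replace them via `--readouts`
/ `--primers` for production libraries.

## Synthetic data

The fixture generator samples contig bases independently at a target GC,
plants gene models (genomic span → unspliced transcript; strand-corrected
exon concatenation → spliced transcript) and then copies segments to plant
exact duplications. It emulates exactly the features the pipeline keys on
— uniqueness violations, sense/antisense gene overlap, exon/intron
structure — and none of the features it does not: no repeat families, no
homology short of identity, no splice-isoform complexity beyond exon
subsets, no sequencing artifacts. Passing tests therefore demonstrate
algorithmic correctness of the filters on controllable inputs, not probe
yield on real genomes, where repeat content and paralogy dominate attrition.

## Problem sizes and numerical notes

Test fixtures use 6–20 kb genomes, 300–700-nt targets, and ≤ 141-gene
transcriptomes — large enough that every filter has planted positives and
negatives, small enough that the exhaustive oracles (all-placement
alignment scans, all-pairs Hamming distances, all-assignment enumeration)
run in seconds. Degenerate inputs are defined rather than left to chance:
windows containing N are rejected at the alphabet rule; a target shorter
than the window yields zero oligos (warning, not error); an empty accepted
pool gives the cross-hybridization measure a −∞ sentinel, as does a
structure-free window for the hairpin measure; a requested probe count
exceeding availability returns everything with a warning; ties in probe
subsampling, codeword choice, and hit merging are broken by fixed
deterministic orderings documented at each site.

## Known limitations

* Thermodynamics assume DNA:DNA duplexes at 1 M Na⁺; no formamide, Mg²⁺,
  or RNA:DNA corrections.
* The hairpin screen ignores imperfect stems and loop energetics.
* The built-in specificity engine is ungapped; indels in near-copies can
  split one locus into two sub-threshold hits.
* Chromatin targets are accepted as plus-strand coordinates only.
* Expression-aware codeword assignment is greedy, not optimal; the tests
  bound its gap on toy instances only.
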