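# probecraft

Oligonucleotide probe design for highly multiplexed fluorescence in situ
hybridization (FISH). probecraft designs primary-probe libraries for three
experiment families — **chromatin tracing** (sequential DNA FISH across many
genomic loci), **RNA MERFISH** (multiplexed error-robust FISH with binary
barcodes), and **sequential single-molecule RNA FISH** — and writes
synthesis-ready template-oligo pools or directly orderable primary-probe
sequences. It is aimed at imaging labs that need probe sets with controlled
hybridization thermodynamics and genome/transcriptome-level specificity
without stitching together several tools by hand.

## What it computes

**Oligo generation.** Each target sequence is scanned 5′→3′ with a 30-nt
window (configurable). A window is accepted if it passes, in order: GC
content within [30, 90] %; no homopolymer run longer than 5 nt; melting
temperature T_m ≥ 66 °C; hairpin stem T_m ≤ 76 °C; and cross-hybridization
T_m against all previously accepted oligos ≤ 72 °C. On acceptance the window
advances by a full window length (adjacent, non-overlapping tiling); on
rejection it advances 1 nt.

T_m uses the nearest-neighbor model with the SantaLucia-1998 unified
parameter set at the 1 M Na⁺ reference state and total strand concentration
C_T = 10⁻⁶ M:

    T_m = ΔH° / (ΔS° + R ln(C_T / x)) − 273.15

with ΔH°, ΔS° summed over dinucleotide stacks plus terminal initiation
terms, and x = 4 (x = 1 plus the symmetry entropy term for
self-complementary duplexes).

**Specificity screening.** Oligos are queried against k-mer-indexed sequence
databases (k = 12) with an ungapped seed-and-extend aligner reporting
strand-aware hits (≥ 18 matching columns, ≤ 2 internal mismatches).
Chromatin-tracing oligos must have exactly one genome alignment over both
orientations; optional filters keep only probes targeting the antisense
strand of genes (so probes cannot bind unspliced RNA) and reject oligos
matching spliced transcripts. RNA-FISH oligos are kept only if every
transcript they match (in the orientation the probe would bind) belongs to
the target gene. NCBI BLAST+ (`blastn -task blastn-short`) is available as
a drop-in backend.

**MERFISH encoding.** Barcodes are the 140 weight-4 codewords of the
extended Hamming [16,11,4] code (16 bits, minimum pairwise Hamming distance
4). Codewords are assigned to genes greedily in descending bulk-expression
order, minimizing the bit-sharing load Σ_b (Σ_{genes on bit b} FPKM)², so
highly expressed genes avoid sharing readout bits. Each probe of a gene
carries three of its four readout sequences (one upstream of the targeting
region, two downstream), cycling through the leave-one-out triplets.

**Assembly.** Template oligos are
`forward primer + upstream readout(s) + targeting region + downstream
readout(s) + revcomp(reverse primer)`; primary probes are the reverse
complement of the template without primers. The shipped readout and primer
tables are synthetic placeholders (orthogonality-screened, editable CSV) —
replace them with your lab's validated sequences for real experiments.

## Worked example

Design chromatin-tracing probes on a bundled synthetic mini-genome (two
6-kb contigs; a 150-nt segment of the second target is duplicated onto the
other contig):

```python
from probecraft.fixtures import FixtureSpec, PlantedDuplication, generate_fixture
import pandas as pd

fx = generate_fixture(FixtureSpec(
    seed=11, n_contigs=2, contig_length=6000, gc_target=55.0,
    planted_duplications=(PlantedDuplication("ctg1", 1550, 1700, "ctg2", 4000),)))
fx.write("demo_fx")
pd.DataFrame([("ctg1", 501, 800, "regA"), ("ctg1", 1401, 1800, "regDup")],
             columns=["contig", "start", "end", "label"]
             ).to_csv("demo_fx/targets.csv", index=False)
```

```
$ probecraft design --probe-type chromatin \
      --genome demo_fx/genome.fasta --targets demo_fx/targets.csv --out demo_out
...
wrote 16 probes to demo_out

$ cat demo_out/run_report.txt
target  scan  unique  selected
  regA     9       9         9
regDup    11       7         7
total probes written: 16
```

Reading the report: the 300-nt target `regA` yields 9 physically qualified
oligos, all genome-unique. `regDup` yields 11, but the 4 oligos falling in
the planted duplicated segment align twice in the genome and are removed by
the uniqueness filter, leaving 7. The 16 probes are written as
`probes.fasta` / `probes.csv` / `probes.xlsx`; each template begins with the
chromatin forward primer, carries target-specific readout `DR001`/`DR002`
upstream and downstream of the 30-nt targeting region, and ends with the
reverse complement of the reverse primer:

```
>regA|0|chromatin|DR001,DR001
ATCACGGCGGCTGGATATAGAGGTTCCAGATGTGTCGCAGCCACTTGTTCTCAGGGGAGTGTGTATCTCGAGGTTCCAGA
TGTGTCGCAGCTTTAATGAGGGGAGCGATC
```

MERFISH designs additionally write `codebook.csv`/`codebook.xlsx` mapping
each gene to its 16-bit codeword and readout identities.

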