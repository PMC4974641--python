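# abpipe

Annotation and germline-usage profiling of antibody (immunoglobulin)
repertoire amplicons, with a synthetic-data generator that makes the
whole pipeline verifiable against known ground truth.

## The problem

Bulk antibody repertoire sequencing reads a PCR amplicon spanning the
rearranged V(D)J region of each B-cell receptor. Turning those reads
into biology requires, per read: which germline V, D and J segments
were used; where the CDR3 (the hypervariable V–(D)–J junction) lies;
and whether the read is a full-length, non-chimeric molecule. On
homopolymer-prone platforms it also requires undoing short indel
errors that would otherwise shift the reading frame. With per-read
annotations in hand, a repertoire is summarised by its germline gene
usage frequencies, and two groups of animals (e.g. transgenic vs
wild type) are compared per gene as fold changes

  FC(g) = f_TG(g) / f_WT(g),

flagging genes above an arbitrary display threshold (default 3).

`abpipe` implements that pipeline for mouse heavy (IGH) and light
(IGK/IGL) chain 5′-RACE amplicons:

1. read indexing;
2. V/(D)/J assignment by exhaustive affine-gap Smith–Waterman
   (match +2, mismatch −2, gap −5/−2) over a germline FASTA library,
   both strands, with a Karlin–Altschul E-value filter
   (reads with E > 10⁻³ for the V assignment are removed);
3. template-based error correction: indels of **less than three
   nucleotides** in the V segment are reverted toward the assigned
   germline; longer indels are kept and flagged;
4. nucleotide- and amino-acid-level identity to the germline template
   by end-gap-free global alignment;
5. CDR3 and V(D)J boundary determination from the conserved anchors
   (V 2nd-CYS → J J-TRP/J-PHE, IMGT junction convention);

then a full-length filter (a read is removed if its V alignment is
< 220 bp — the signature of PCR-swapped segments), per-gene usage
profiling, and between-group fold-change comparison.

Because public germline databases and the original sequencing data are
deliberately not dependencies, the package ships a simulator
(`abpipe.simulate`) that generates 5′-RACE-like reads — segment draws
with configurable usage skews, junctional trimming and N insertions,
somatic hypermutation, substitution errors and homopolymer-boosted
short indels — together with a per-read truth record from which every
emitted read can be reconstructed exactly. All recovery claims in the
test suite are measured against that truth. See `docs/methods.md` for
the model details and design choices.

## Worked example

Simulate a wild-type sample (uniform V usage) and a "transgenic"
sample with three V genes up-weighted to a 4-fold usage change, then
annotate both and compare usage:

```
abpipe simulate --n-reads 2000 --seed 7 --out-prefix demo_wt
abpipe simulate --n-reads 2000 --seed 8 \
       --upweight-genes IGHV2-1,IGHV4-2,IGHV5-1 --usage-fold 4 \
       --out-prefix demo_tg
abpipe run-all --library-seed 1 \
       --reads-num demo_tg.fastq --reads-den demo_wt.fastq \
       --out-prefix demo
```

The run logs per-stage read accounting to stderr —

```
[abpipe] input: 2000 reads
[abpipe] unalignable: 0 reads
[abpipe] removed_evalue: 0 reads
[abpipe] assigned: 2000 reads
[abpipe] indel_corrected: 666 reads
[abpipe] removed_swapped_segment: 0 reads
[abpipe] full_length: 2000 reads
wrote demo.comparison.tsv; flagged: IGHV2-1, IGHV4-2, IGHV5-1
```

— meaning all 2000 reads aligned confidently (none failed the E-value
or full-length filters on this clean simulation) and 666 carried at
least one corrected V indel. The comparison table holds one row per
gene:

```
gene     freq_num  freq_den  fold_change  flagged
IGHV1-1  0.0255    0.046     0.557        False
IGHV2-1  0.209     0.049     4.249        True
...
```

The three up-weighted genes — and only they — exceed the fold-3 line
(`IGHV2-1` at 4.25 here: 20.9% of the transgenic repertoire vs 4.9%
of wild type). `demo.num.rearrangements.tsv` carries the per-read
annotations (AIRR-style columns: `sequence_id, v_call, d_call, j_call,
junction, junction_aa, productive, v_alignment_length, v_evalue,
filter_flags`), including reads removed by each filter with their
status, for audit.

The same analysis is available as library calls
(`abpipe.simulate_repertoire`, `abpipe.run_pipeline`,
`abpipe.compute_usage`, `abpipe.compare_groups`) — the CLI is a thin
wrapper. Real germline FASTAs are supplied with
`--v-fasta/--d-fasta/--j-fasta` (header dialect
`>segment_id[|family[|anchor_offset]]`; anchors are located
automatically when absent).

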