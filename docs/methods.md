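# Methods

## The annotation pipeline

`abpipe` annotates immunoglobulin amplicon reads (heavy chain IGH, or
light chains IGK/IGL) against a germline segment library in five
stages, then profiles germline gene usage.

1. **Indexing.** Reads are relabelled `READ000001…` in input order;
   the original headers are retained. Sequences are uppercased.
2. **Gene assignment.** Each read is aligned against every V segment
   on both strands by affine-gap Smith–Waterman (match +2, mismatch
   −2, gap open −5, gap extend −2; a gap of length *L* costs
   −5 −2(*L*−1); `N` mismatches everything). The best-scoring segment
   is called, ties going to the lexicographically smallest segment id,
   then the forward strand. The read is then oriented to germline
   sense, J is searched 3′ of the V alignment, and D (IGH only) in the
   V–J window; D calls covering fewer than 5 nt are withheld
   (`d_ambiguous`) because 10–15 nt D segments align spuriously.
   Significance of the V call is a Karlin–Altschul E-value
   E = *K·m·n·*exp(−λ*S*) with *m* the read length and *n* the total V
   library length; reads with E > 10⁻³ are removed (strictly greater:
   a read at exactly 10⁻³ is retained).
3. **Template-based indel correction.** Indel runs in the V edit path
   are corrected toward the assigned germline: insertions excised,
   deletions refilled with germline bases, applied 3′→5′ so positions
   stay valid. Only events **shorter than three nucleotides** are
   corrected; longer events are recorded and left in place (a
   codon-multiple indel can be genuine), and a read whose uncorrected
   indel lengths are not a multiple of three is flagged
   `frameshift_suspect`. Substitutions are never altered. After
   correction the V alignment is recomputed against the assigned
   segment (banded around the previous diagonal); identity can only
   increase.
4. **Template comparison.** The corrected V region is compared with
   its germline template by end-gap-free global alignment at the
   nucleotide level and, after translation in the germline frame, at
   the amino-acid level. Identity is matches over aligned columns,
   internal gap columns counting as non-matches.
5. **CDR3 and boundaries.** The V segment's 2nd-CYS codon and the J
   segment's J-TRP/J-PHE codon are projected through the edit paths
   onto read coordinates. The *junction* runs from the first Cys base
   through the last Trp/Phe base (anchors included); the *CDR3*
   excludes both anchor codons (IMGT convention). Junctions whose
   length is not a codon multiple are flagged `junction_out_of_frame`
   and retained; a read is `productive` when its junction is in frame
   and the translated variable region is stop-free. Productivity is
   reported, never filtered on. The variable region runs from the
   read image of germline V position 0 (or the first aligned V base,
   flagged `v_5prime_truncated`) to the last aligned J base.

After annotation a **swapped-segment filter** removes reads whose V
alignment spans fewer than 220 bp of the read — PCR-jumping chimeras
align only partially to any single template — with 220 itself
retained. Surviving reads are tallied per V gene (or family), each
read counting once (an optional mode collapses identical nucleotide
sequences first). Two samples are compared per gene as
fold_change = (f₁+p)/(f₂+p), with pseudocount *p* defaulting to half a
count in the smaller sample so genes absent from one group stay
finite; genes above a fold threshold (default 3) are flagged. The
threshold is a display convention; no p-values are attached.
Replicate groups can be combined either by averaging per-replicate
frequencies or by pooling counts before the ratio; both are exposed
because group summaries of this kind are computed both ways in
practice.

### CDR3 anchors

Anchor conventions follow the IMGT conserved residues. On a V segment
the anchor is the 3′-most in-frame Cys codon (TGT/TGC) within the
final 45 nt; on a J segment, the 5′-most in-frame Trp (TGG) or Phe
(TTT/TTC) codon followed by `GG` at the next codon (the [WF]G.G
motif), falling back to the first in-frame Trp/Phe when the motif is
absent. J reading frames are inferred from the motif when not given.
All coordinates in the package are 0-based half-open; conversion
happens only at output boundaries.

### Alignment engine and its shortcuts

The Smith–Waterman and end-gap-free global (overlap) aligners are
numba-compiled Gotoh three-state kernels; `N` is a dedicated code that
mismatches every base including itself. The reference behaviour of
segment assignment is the exhaustive search over all segments and both
strands. The pipeline's default fast path adds two heuristics, both
off when `align_segment` is called without an index:

* a k-mer prescreen (k = 12) ranking (segment, strand) candidates by
  shared-k-mer count — only the top 3 candidates are aligned;
* a diagonal band around the seed diagonals (±24 nt) for those
  alignments, exact whenever the optimal path stays inside the band.

On simulated data the fast path reproduces the exhaustive call
(checked in the tests); it exists because profiling two 5,000-read
samples across many replicates is otherwise dominated by dynamic
programming over segments that share no seeds with the read.

### E-value calibration

The filter threshold E > 10⁻³ needs an E-value definition; the
package uses the Karlin–Altschul form with (K, λ) fitted by
simulation: 500 random 500-nt reads aligned (both strands) against a
fixed library of fifty random 300-nt segments, per-read maximum scores
fitted to a Gumbel distribution, λ = 1/scale and
K = exp(loc/scale)/(m·n). The shipped constants for the default
scheme are K = 0.10518, λ = 0.44600; the both-strand search is
absorbed into K. `calibrate_evalue_params` refits for any other
scoring scheme. True rearrangements score thousands of bits above the
null, so the filter's practical role is to reject unalignable
artefacts; random reads reach E ≤ 10⁻³ at about the nominal 10⁻³
rate.

### The flank-support rule (a deliberate tightening)

A local V alignment can chance-extend a few positions beyond the true
V boundary into untemplated junction nucleotides (or the adapter),
bridging with a 1–2 nt gap: three matches repay a gap-open. Treating
such a gap as a platform error and "correcting" it rewrites genuine
junctional sequence. An indel event is therefore corrected only when
supported by at least `MIN_FLANK_SUPPORT = 6` aligned germline columns
on each side. Measured on simulation, removing the rule corrupts the
CDR3 of ~0.8% of reads; with it, correction strictly improves CDR3
recovery. The cost is that genuine indels within ~6 columns of the
alignment ends are left uncorrected (~4% of injected indels).

## The simulator

`simulate` emulates the structure of 5′-RACE antibody amplicons
sequenced on an indel-prone semiconductor platform, with enough
fidelity to validate every pipeline stage against known truth:

* a rearrangement is V (3′-trimmed) + N1 + D (5′/3′-trimmed) + N2 + J
  (5′-trimmed) for IGH, without D/N2 for light chains; trims are
  uniform on [0, 6] nt and untemplated insertions uniform on [0, 10]
  nt per junction;
* somatic hypermutation is uniform substitution at 0.005/base over the
  V(D)J region (the repertoires modelled come from in-vitro expanded
  B cells with limited mutation; no hotspot motifs);
* sequencing noise is substitution at 0.003/base and indels at
  0.001/base, the indel rate multiplied by 5 inside homopolymer runs
  ≥ 3 nt; indel lengths are 1–2 by default (3:1 short-biased) and
  configurable up to longer lengths to exercise the uncorrectable
  regime;
* fixed 90 nt and 110 nt flanking stubs stand in for the RACE adapter
  (plus UTR/leader) and the constant-region primer stretch, putting
  default amplicons at ~550 nt (≥95% within 400–700 nt).

Every read carries a `TrueAnnotation` from which it can be rebuilt
base-for-base (segments + trims + inserts + mutations + edits +
stubs); this reconstruction identity is asserted in the tests.

The synthetic germline library (`make_synthetic_library`) is a
stand-in reference, not real alleles: 20 V segments of 293 nt in 5
families (~5% within-family divergence), 5 D segments of 10–14 nt, 3
J segments of 45 nt. V segments carry their Cys anchor 11 nt from the
3′ end and J segments their Trp anchor at offset 6, deliberately
compact junctions (mean CDR3 ≈ 22 nt) so that exact-recovery metrics
measure the pipeline rather than raw per-base error accumulation over
a long junction. What passing tests show is therefore recovery of
*this* structure at *these* noise rates; real repertoires add longer
junctions, allele-level V diversity, biased junctional profiles and
hotspot-clustered mutation, none of which the simulator models.

## Study conditions used by the tests and the reproduction script

* Recovery metrics: 2,000 heavy-chain reads at the default noise
  rates. Measured there: V-call accuracy ~100% (≥99% on noise-free
  reads), exact CDR3 nucleotide recovery ≈ 90%, and ≈ 93% of injected
  1–2 nt V indels exactly reverted with injected ≥3 nt indels never
  modified. "Exactly reverted" is judged per indel on the local
  sequence around its site; isolated ≥3 nt indels only, since two
  opposing injected indels at one locus present to any aligner as
  their net difference.
* Usage contrast: a wild-type sample with uniform V usage versus a
  "transgenic" sample in which three designated V genes are up-weighted
  to a true frequency fold change of 4 (weight w = F(G−k)/(G−Fk) for
  G genes, k targets, fold F), 5,000 reads per sample. At this depth a
  fold-4 skew sits ≈ 3.5 standard errors above the fold-3 flagging
  line, so all three genes are flagged with at most one false flag in
  ≥ 95% of replicates.

## Numerical and degenerate-input choices

* Ties in segment assignment: smallest segment id, forward strand
  first — determinism over biology, as any single-best-call rule must
  be.
* DP tie-breaks: diagonal over deletion over insertion; the first
  maximal cell in row-major order ends a local traceback.
* Reads shorter than 30 nt are `unalignable`; empty J search regions
  leave `j_unassigned` and CDR3 undetermined (`cdr3_unresolved`),
  always retaining the read.
* Anchor projection through a deleted germline base maps to the
  deletion point in the read.
* Germline libraries reject ambiguity codes outright; references
  should be clean, and failing loudly beats silent resolution.
* The correction realignment is banded around the prior diagonal
  widened by the total corrected/skipped indel length, and keeps the
  old alignment in the (rare) event the banded score is worse.

## Known limitations

* Identity of the best-scoring V gene is the only call made; no
  attempt at allele-level distinction or multi-call ambiguity sets.
* The E-value calibration assumes uniform base composition; strongly
  biased reads shift the null distribution.
* The swapped-segment filter's 220 bp cutoff presumes near-full-length
  V amplicons; fragmented libraries would need it lowered.
* `compare_groups` attaches no uncertainty to fold changes; with few
  reads per gene the pseudocount dominates and fold changes shrink
  toward 1.
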