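# Methods

This note documents the models and procedures implemented in `plastocomp`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Genomes and coordinates

All analyses operate on an `AnnotatedGenome`: a circular nucleotide
sequence plus gene features (protein / rRNA / tRNA, one of nine functional
categories).  Coordinates are 0-based half-open; GenBank's 1-based
inclusive coordinates are converted only at the parsing boundary.  A
feature spanning the origin is stored once, with a wrap flag, and every
consumer resolves the wrap through the same two helpers
(`feature_sequence`, `feature_length`) — one wrap rule, one place.
Translation uses table 11 (bacterial/plastid) throughout, which matters for
NG86 site classification.

Cross-genome gene identity is the normalized gene name.  Normalization
case-folds plain symbols (`ATPI` → `atpI`), maps verbose rRNA labels
through a curated synonym table (`16S ribosomal RNA` → `rrs`; the
bacterial-style rrs/rrl/rrf convention was an open choice and is
configurable), and renders tRNAs as one-letter amino acid plus anticodon in
the RNA alphabet (`tRNA-Thr(ggt)` → `trnT(GGU)`), so isoacceptors are
distinct genes.  Unrecognized labels pass through unchanged rather than
being mangled.

## Compactness statistics

The non-coding percentage is 100 × (circle positions covered by no
annotated gene) / genome size, with coverage taken as the **union** of all
features — overlapping annotations count once.  The mean intergenic
distance is total uncovered length divided by the number of maximal
uncovered gaps.  This is the plain, reproducible definition; published
tables sometimes report a different number for the same record (their gap
convention is not stated), so this metric should be compared across
genomes *within* this package, not against externally published means.
Genome rotation and reflection change none of these statistics (tested).

Inverted-repeat detection seeds on exact 25-mers shared between the
sequence and its reverse complement and extends them without gaps,
reporting the longest pair of non-overlapping arms at or above `min_len`
(default 1,000 bp, the scale of canonical plastid IRs).  Chance exact
repeats of that length are vanishingly unlikely in a 50–200 kb genome, so
no significance model is attached.  The scan is linear in the sequence; an
IR spanning the origin would be reported with truncated arms.

## Gene content and identity

Shared/lost accounting is set algebra on distinct normalized names;
duplicate copies (e.g. genes inside an inverted repeat) collapse to one
name for the sets but are reported separately, so a "counted twice"
annotation convention does not distort the arithmetic.  Identity profiles
use an implemented global pairwise alignment with match +1, mismatch −1,
gap open −2, gap extend −1 (the dynamic program is Biopython's
`PairwiseAligner`; the scoring is fixed, versioned configuration — only the
mismatch penalty is externally dictated, the gap costs are this package's
declared choice).  Identity is matching columns over all alignment columns,
reported globally, in 100-bp windows, and for the 50 bp upstream of the
start codon (the 5′UTR proxy).

## Synteny on signed circular permutations

The shared genes of a pair (protein + rRNA by default; tRNAs includable by
flag, following the field's gene-order convention) form signed circular
permutations ordered by position and signed by strand.  A **conserved
adjacency** is an unordered gene pair adjacent on both circles; the
**breakpoint distance** is n_shared − conserved adjacencies; collinear
blocks are maximal chains of conserved adjacencies, so block count equals
breakpoint count whenever the circles differ.  Orientation-compatible
adjacencies (the pair occurs with the same signs as read, or with both
signs flipped in reverse order) are reported in a separate field.

The pair-adjacency rule was chosen deliberately: under it the expected
adjacency fraction for a uniformly random signed circular permutation of
*n* genes is exactly 2/(n−1) (each gene has two neighbours among the n−1
others; orientation plays no role), which the Monte-Carlo null test
verifies.  Requiring orientation compatibility would halve or quarter the
null without changing the ranking of real comparisons, and a breakpoint in
the orientation-sensitive sense is already visible in the separate oriented
count.  All statistics are invariant under rotation and reflection of
either genome; `canonicalize` (rotate to an anchor gene, optionally
reflect) exists purely for presentation and provably does not change any
result.

## Deletion breakpoints

Walking the reference circle (all gene types — lost tRNAs participate in
deletion runs), maximal runs of genes absent from the reduced genome become
breakpoint regions, labelled BP1… in reference order.  Adjacent runs
separated only by missing genes merge by construction, since a flank must
be a retained gene.  The junction is the intergenic span between the two
flanks in the reduced genome (checked in both reading directions; if the
flanks are no longer adjacent the region is marked not-clean and the
intergenic region downstream of the left flank is reported).  Junction
windows shorter than `W` = 100 bp are extended symmetrically into the
flanks; 100 bp matches the window granularity used for identity profiles
and is configurable.  tRNA adjacency means *either* flank is a tRNA — the
weakest reading of "adjacent to a tRNA gene".  Junction similarity is
all-vs-all global-alignment identity of junction windows, flagging pairs
above 70% identity over ≥ 30 columns.

The reported `deleted_span_bp` is the reference distance between the
flanks (always ≥ the summed lengths of the missing genes); it is labelled
explicitly because a "deletion size" could also plausibly mean the junction
gap.

## NG86 Ks/Ka

Codon alignment is protein-guided: translate both coding sequences
(terminal stop trimmed; internal stop rejects the gene; a length not
divisible by 3 is trimmed from the 3′ end with a warning), align the
proteins globally (BLOSUM62, gap open −11 / extend −1), and back-translate,
so gaps occur only in whole-codon units.

The estimator is the Nei–Gojobori counting method:

* **Sites.**  Each codon position contributes the fraction of its non-stop
  single-nucleotide neighbours that are synonymous; the two fractions at a
  position sum to one, so S + N = 3 × codons exactly.  S is averaged over
  the two sequences.
* **Differences.**  For codons differing at k positions, all k! single-step
  pathways are enumerated; pathways through stop codons are excluded (if
  every pathway is blocked, all are used with stop steps counted
  non-synonymous — a rare fallback); synonymous/non-synonymous step counts
  are averaged with equal weights.
* **Correction.**  p_S = S_d/S and p_N = N_d/N are corrected with
  Jukes–Cantor, d = −(3/4) ln(1 − (4/3) p), undefined at p ≥ 3/4.

A gene is flagged *saturated* when the correction is undefined or Ks ≥ 1.
The mean Ks excludes only genes with an undefined correction: a defined
Ks ≥ 1 is noisy but is still an estimate, and dropping the high tail would
bias the average downward.  The default average is the unweighted per-gene
mean; site-weighted averaging is available.  A transition/transversion- and
codon-usage-aware counting estimator (YN00-style) would typically give
slightly larger Ks on biased sequences; NG86 was implemented because it is
fully specifiable and testable against exhaustive enumeration (the test
suite carries an independent brute-force oracle and checks all 61 × 61
sense-codon pairs exactly).

## Generation-time clock

G = K̄s / μ generations, times an assumed generation time in years.
Defaults: μ = 3.23 × 10⁻¹⁰ substitutions per site per generation (a
unicellular green-algal per-generation rate; plastid and nuclear rates are
taken as comparable, and μ is an explicit parameter), generation times
0.00274 y (24 h, heterotroph) and 0.008219 y (72 h, autotroph), giving a
low/high window.  Whether the distance should be halved (two lineages each
accumulating half the divergence) is a biological-interpretation question;
the default follows the G = K̄s/μ convention and `per_lineage=True` halves
it, so the choice is visible rather than buried.

## The simulator

`generate_ancestor` assembles a circular gene–spacer alternation: random
stop-free codon sequences for proteins (codon frequencies AT-biased at
0.65), random RNA genes (tRNA 72–90 bp; rRNA 1490/2890/120 bp), spacers of
20–400 bp at AT fraction 0.85 — numbers chosen to mimic a compact AT-rich
plastome.  Photosynthesis genes can be laid out in a fixed number of
well-separated clusters, the way plastid operons cluster in real maps, and
those clusters become plantable deletion runs.

`evolve` drives each protein gene to a target divergence by proposing
random single-nucleotide codon changes (start codon fixed, stop-creating
changes rejected) and accepting a proposal only if it moves the realized
NG86-counted distance to the ancestor strictly closer to the target —
non-synonymous proposals toward Ka first, then synonymous toward Ks.  This
counting-driven design gives tight control at small gene counts, which
parameter-recovery tests need more than they need a continuous-time model;
per-gene realized Ks lands within 5% of the target for genes ≥ 300 codons.
The recorded truth is the realized NG86 divergence recomputed from the true
codon correspondence — not the target — so estimator tests measure the
estimator, not the proposal loop.  RNA genes and spacers evolve by
independent per-site substitution at per-site distances of 0.1 × and
1.5 × the protein Ks target respectively: RNA genes are set strongly
conserved (a protein gene at Ks 0.8 / Ka 0.05 has an effective nucleotide
distance near 0.17, so the RNA multiplier must sit well below ~0.2 for the
"RNA most conserved, spacers least" ordering to hold by construction).
Deletions remove a gene run plus its internal and flanking spacers and fuse
the flanks with a fresh junction spacer of 100–200 bp drawn at AT 0.9,
matching the designed expectation that junction AT aggregates above 85%.
Inversions reverse-complement whole gene spans.  All randomness comes from
integer-seeded numpy generators; a seed reproduces the pair bit-exactly.

What the simulator does **not** emulate: indels inside genes (the true
codon correspondence is the identity, so codon-alignment recovery is only
exercised by explicitly constructed indel cases), rate heterogeneity among
sites and genes, transition/transversion bias, strand-asymmetric
composition, recombination, and compositional stationarity — under the
uniform substitution model a long-evolved descendant drifts toward 50% GC.
Passing the recovery tests therefore shows the estimators are correct on
data satisfying their own model assumptions; it does not show robustness to
alignment error or compositional bias in real genomes.

## Problem sizes and determinism

The test suite and the acceptance script run on study-scale fixtures:
~46-gene genomes (~45 kb) for the end-to-end pipeline, 30-gene replicates
of 300–500-codon genes for parameter recovery (50 seeds × three divergence
levels in the suite; 20 seeds in the acceptance script), 1,000 random
50-gene permutations for the synteny null, and fixtures with 5–17 planted
deletion runs for breakpoint recovery.  These sizes were chosen so the
whole suite completes in about a minute while keeping Monte-Carlo standard
errors far below the tested tolerances.  Pipeline outputs are byte-stable:
TSV floats at four significant digits, JSON with sorted keys, gene lists
sorted.
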