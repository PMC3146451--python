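# Methods

This note records the models, conventions and design choices behind
`islandmob`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and what
the synthetic benchmarks do and do not demonstrate.

## Coordinates and alphabets

All internal coordinates are 0-based half-open; every user-facing report is
1-based inclusive, and the two conversions are exact inverses. Genome
sequences are restricted to `A C G T N`. `N` (metagenome gap filler) is
tolerated in input but excluded from every identity, consensus and distance
denominator, so assembly gaps cannot inflate disagreement; in the repeat
scan an `N` simply never matches.

## Island scanning

*ssrA* location prefers an annotated tmRNA feature; without one, a
reference gene is placed by local alignment (match +1 / mismatch −1, gap
open −2 / extend −1) on both strands and accepted at ≥ 80% identity over
the reference. All downstream logic runs on the strand that puts *ssrA*
forward (`normalize_orientation`), which makes the scanner exactly
strand-symmetric (a property the tests check by reverse-complementing whole
genomes).

Direct repeats are substitution-only (Hamming) matches of the 3'-terminal
tag: the observed degeneracy of real repeats is substitution-type, and an
indel-tolerant matcher would blur boundary coordinates. Defaults: tag 20 bp,
window 100 kbp downstream, ≤ 3 mismatches, all exposed as parameters. Hits
closer than one tag length are merged keeping the lower-mismatch (then
leftmost) copy, since overlapping repeats are biologically implausible.
Islands tile the interval from the *ssrA* 3' end to the last repeat end;
genes belong to the island containing their midpoint.

Integration-module detection is alignment-based, not annotation-based: each
reverse-strand CDS near attL is translated and locally aligned (BLOSUM62,
gap −11/−1) against packaged reference proteins for the six roles (dsiB,
dsiA, recF-like, parB-like, mom-like, rnap-domain). A module is called when
≥ 5 roles match in canonical attL-proximal order at ≥ 25% identity over
≥ 50% reference coverage, candidate lengths within ±20% of the reference,
and the attL-adjacent gene is the dsiB integrase (start within 500 bp of
attL — "adjacent" needed an operational definition and 500 bp covers the
observed layouts). The identity threshold is permissive by design: the
integrase family's remote homologs sit near 22% identity, and the order
constraint supplies the specificity. Unannotated genomes fall back to a
six-frame ORF caller (ATG/GTG/TTG starts, table-11 stops, ≥ 150 nt). Two
consequences of the fallback are deliberate: a gene whose start codon was
lost to divergence is recovered slightly shorter (first downstream start),
and a gene interrupted by the embedded tRNA-like locus may drop out — both
are absorbed by the ±20% length tolerance and the 5-of-6 rule.

The 76 bp tRNA-like locus is sought by best Hamming placement (≤ 15
mismatches) within the first 300 bp of the fifth module gene in reading
orientation, and flagged canonical when it starts within the gene's first
150 bp and lies 4400 ± 1500 bp from attL.

## Attachment-site analysis

Each boundary (the *ssrA* 3' end, or a repeat end) contributes one gapless
84-column window split 34 upstream + 20 repeat + 30 downstream. The
consensus is majority-rule: a column shows its modal base iff its frequency
among countable rows is ≥ 75%. The att motif is computed from
direct-repeat rows only, over the 15 columns immediately 5' of the repeat:
each column's minimal IUPAC code covering all bases above a 10% inclusion
frequency (10% reproduces two-base codes on realistic row counts and
suppresses rare third alleles).

Insertion-point inference compares repeat rows against *ssrA* rows
column-wise. The repeat span is the longest *ssrA* 3'-suffix whose mean
cross-group per-column identity is ≥ 0.9, with extension stopped at the
first column of outright disagreement (cross-group identity < 0.5). The
two-part rule is deliberate: a pure mean criterion overshoots the repeat by
a column or two because twenty high-identity columns dilute one
chance-level motif column, while a strict per-column criterion is brittle
to sampling noise in small row sets. The last *ssrA* base before the
insertion is `ssrA length − span`; with the packaged 353 nt gene and 20 bp
tag this is position 333, i.e. insertion between 333 and 334. The
"diagnostic column" reported alongside is the attL-proximal column where
both groups are internally conserved (≥ 75% modal frequency) yet disagree.

## Segmentation

Percent identity is **mean pairwise identity**: over all row pairs and
columns, the fraction of comparisons with equal bases, where any comparison
involving a gap or `N` is excluded from that pair's denominator. (The
plausible alternative — consensus identity — is not used; pairwise is the
standard interpretation and the one under which a large deletion private to
two rows does not crater a regional mean.) The two-segment changepoint
minimizes the within-segment sum of squared deviations of per-column
identity values, ties broken leftmost, each segment at least one window
(14 columns) long; a constant profile returns an explicit "no changepoint"
result. Region means are recomputed per-column over the final segments.

## Selection (NG86)

Site counting uses the stop-exclusion convention: one-step changes to stop
codons are removed from both numerator and denominator at each codon
position, after which s + n = 3 exactly per codon (Σ(s+n) = 183 over the
61 sense codons of table 11). Pairwise differences are averaged over the
minimal substitution pathways between two codons, excluding pathways that
pass through a stop (if every pathway is blocked — possible only for a few
two/three-step pairs — all pathways are used, with stop-passing steps
counted nonsynonymous). Proportions are Jukes–Cantor corrected; p ≥ 3/4 is
a hard error rather than a silent NaN. Ratios are reported with explicit
statuses: `undefined_0_over_0` for identical regions and
`infinite_Ks_zero` when all differences are nonsynonymous. Codons
containing gaps or ambiguity codes are skipped entirely (sites and
differences), which preserves the additivity of counts over region
partitions. Variant columns count per-column (a 3-column gap run is 3
variant positions), with gap-as-state and `N`-as-missing.

## Mutation spectrum

Difference columns of a two-row alignment are merged into events at
distance 1 (any intervening matching column separates events). Pure
substitution runs of length 1 are transitions/transversions; length ≥ 2 are
multi-nucleotide polymorphisms (mnp), counted once and contributing to
neither single-base class — the natural reading of a four-category
spectrum summing to 99%. Mixed substitution+gap runs classify by majority
type, ties to indel. Effects within a CDS: indels with length ≢ 0 (mod 3)
are frameshifts; in-frame indels fold into nonsynonymous; substitutions are
translated in context (table 11, both strands) and classified synonymous /
nonsynonymous / truncation (new stop). Events spanning a CDS boundary are
flagged rather than classified.

## Dating

Branch lengths are expected substitutions per site; a "branch length per
year" is treated as a per-year substitution rate. Years are 365.25 days
(the choice matters at < 0.1%). The neighbor-joining helper (negative
branches clamped to zero) exists so the dating formulas can be exercised
end-to-end without an external tree; it reproduces additive distances
exactly. The MRCA branch length of a clade supports both `root_height`
(max MRCA-to-tip path) and `mean_tip_path`; for trees of unknown rooting,
`clock_root_height` uses half the maximal patristic distance, the midpoint
root height. Age tables keep raw years in machine output; significant-
figure rounding (e.g. 3×10⁻⁵/16 yr → 2×10⁻⁶/yr at 1 figure) is applied
only where requested. Per-generation rate models require a user-supplied μ
(the package ships no default mutation rate).

## Synthetic data: what it emulates, and what it does not

All generators are deterministic per seed (`numpy.random.default_rng`).

The island-genome generator plants: a 353 nt synthetic tmRNA gene (packaged
fixture; synthetic, not the real gene, but with the canonical 20 bp tag and
a fixed disagreement base at position 333); tandem islands each terminated
by the tag carrying a requested number of substitutions, preceded by a
realization of the degenerate attachment motif `TTCAGRSMGMRKCCA`; a
six-gene reverse-strand module back-translated (uniform synonymous codons)
from packaged synthetic reference proteins of the canonical lengths
(540/200/150/210/270/700 aa) after seeded amino-acid divergence; the 76 bp
tRNA-like consensus embedded in the fifth gene ~4.3 kbp from attL; a
forward rubredoxin-like gene; and a cargo gene (129 bp leader + 1431 bp
body) with independent leader/body substitution regimes. Background
sequence is i.i.d. at the requested GC and then *scrubbed*: any accidental
window within 4 mismatches of the tag outside planted intervals is
destroyed, so planted boundaries are provably the only callable ones —
recovery tests measure the scanner, not background luck.

Cargo alignments treat body variation as shared single-allele events (at
most one variant column per codon, derived allele in a random proper subset
of rows, chosen nonsynonymous and non-stop when requested), which
guarantees S_d = 0 in every pairwise body comparison — the signature the
selection analysis is meant to detect. Two-regime alignments assign each
column an exact identity level (k ∈ {0..3} deviant rows with distinct
bases gives pairwise identity C(n−k,2)/C(n,2)) and mix levels by largest
remainder, so realized region means equal the planted 75.0%/99.4% up to
rounding and changepoint recovery is limited by the estimator, not by
generator variance. Strain pairs plant an exact largest-remainder kind
composition (default 39/28/28/4% with the 1% remainder as mnp events),
events ≥ 6 bp apart over a CDS tiling. Tree simulation is plain JC69.

What passing these tests does **not** show: performance on real
(meta)genomes with repetitive background, annotation errors, indel-bearing
repeats, recombination between islands, or alignment uncertainty — the
generators produce gapless alignments and clean annotations. Genome-scale
census numbers (island counts across strain collections) and rate models
whose parameters are only available in external supplements are likewise
outside what the synthetic benchmarks can establish.

## Problem sizes used by the benchmark script

`scripts/acceptance.py` uses 35 kb two-island genomes (50 seeds, plus 50
island-free genomes for the false-positive check), ten 45 kb genomes for
the pooled flank analysis (30 boundary rows), an 8 × 2000 two-regime
alignment, an 8 × 1560 cargo alignment (~15 body variants), one 20 kb /
192-event strain pair, and fifty 6-taxon clock trees with 10 kb simulated
alignments — sizes chosen so the whole script completes in seconds while
keeping every statistical check comfortably powered.
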