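# Methods

This note documents the models, conventions and numerical choices behind
`plastigs`, and what the synthetic validation does and does not show.

## Coordinates and the genome model

All coordinates are 0-based, half-open, on the forward strand; GenBank's
1-based inclusive convention is converted at the boundary. Genomes are
circular: an interval may wrap the origin (`start > end`), and origin-
spanning GenBank `join` locations become multi-part annotations. After
partition detection, genomes are rotated ("canonicalized") so the LSC starts
at position 0 and the order is LSC → IRb → SSC → IRa; no strand flip is
applied, because SSC orientation is a biological observation the junction
analysis reports rather than an error to normalize away.

## Quadripartite partition detection

The IR pair is found by seed-and-extend: exact 25-mers shared between the
sequence and its reverse complement seed candidate inverted pairs, grouped
by the anti-diagonal (which is invariant under coupled extension). Extension
is exact-match greedy; a mismatch is bridged only when followed by 20 exact
matches and only while overall identity stays ≥ `min_identity`. This
deliberately conservative bridging stops extension at the sharp IR/SC
boundaries instead of creeping through random flanking sequence, which a
naive "mismatch budget" rule would do (at 99% identity a 20 kb IR would
tolerate ~200 flanking mismatches). Defaults: `min_ir` 1000 bp,
`min_identity` 0.99; real plastome IRs are ≥ 10 kb at near-identity, so both
are safe margins. Ns count as mismatches. The scan is over the linearized
sequence with one half-rotation retry, which covers records deposited with
the IR across the origin. The longer single-copy segment is labelled LSC.
Files carrying explicit IR `repeat_region` annotations can be trusted
instead via a flag.

## Spacers and homology groups

The gene footprint is the full extent of gene-level features (exons plus
introns; tRNA and rRNA count as genes). Spacers are the maximal uncovered
intervals of the circle; zero-length gaps between abutting or overlapping
genes are dropped rather than recorded as length 0, so they cannot dilute
group means. Spacer region (LSC/IRb/SSC/IRa) is assigned by midpoint.
Homology across species is by the *unordered* flanking-gene pair: inversions
reorder flanks but do not split groups. tRNA anticodon suffixes are retained
(trnD-GUC ≠ trnD-GAC). A species in which the two flank genes are not
adjacent — because a flank was lost and the spacer fused with its neighbour,
or because of rearrangement — is absent from the group, mirroring the "-"
convention of cross-species spacer tables. The two mirrored IR copies of a
spacer are kept as records but count once in per-species totals and groups
(`dedup_ir`, default on, following the one-copy reporting convention; the
generator's length identity uses both copies, see below).

## The overlong rule

Within a group with n present copies, a copy is overlong iff its length
strictly exceeds the plain arithmetic mean of the n lengths, focal copy
included. Leave-one-out means are *not* used. Groups with fewer than two
present copies are skipped with a warning. The rule is scale-equivariant and
deliberately simple; applied to the packaged published matrix it reproduces
the reference calls except for two psbE-petL cells that the publication did
not typeset as overlong although they exceed the column mean (2,566 and 873
vs a mean of 842.1). The package reports such disagreements
(`compare_with_published_bold`) instead of reconciling them silently.

## Repeat scanners

*Microsatellites.* A maximal run at period u is the largest interval on
which the sequence equals itself shifted by u; the reported hit covers whole
copies only, anchored at the run start. Minimum copies 10/5/4/3/3/3 for
motif lengths 1–6. A run is reported only at the smallest period that
explains it (the minimal period of the run substring must equal the scan
period), so a poly-A run is never also a degenerate "AA" hit. Adjacent SSRs
stay separate hits (no compound merging; compounding changes grouping, not
totals). The canonical motif (lexicographic minimum over rotations and their
reverse complements) supports A/T- vs C/G-class summaries.

*Tandem arrays.* The same run logic for periods 7–500 bp, requiring ≥ 2 full
copies and ≥ 24 bp total; copy number may be fractional. This is an
exact-copy simplification of the fuzzy-alignment tandem finders used in
survey practice; it affects replication on real accessions (where arrays
drift) but not the synthetic closed loop, whose planted arrays are exact.

*Dispersed repeats.* Maximal pairs of length ≥ 30 within Hamming distance 3,
in four orientation classes: forward, palindromic (reverse complement),
reverse, complement. "Maximal" is the strong sense: extending either end
would introduce a fourth mismatch or leave the sequence, so flanking
mismatches are absorbed up to the budget. Detection is seed-and-extend with
exact seeds of width ⌈(min_len − k)/(k + 1)⌉ = 7; by pigeonhole every
qualifying pair contains such a seed, so seeding loses nothing (hence the
hard floor `min_len ≥ 8`). N matches nothing, including another N, and seeds
containing N are skipped (a valid window's guaranteed exact segment is
N-free). In genome scans the detected IR pair (padded 100 bp) is masked:
otherwise the IR dominates every genome as one giant palindromic hit, which
the size distributions of published repeat surveys clearly do not count.

All three scanners are validated against brute-force oracles (direct
per-period scans; full diagonal enumeration for pairs) with exact set
equality on hundreds of seeded random sequences.

## Statistics

`mann_whitney_u` assigns midranks to the pooled data. For n1+n2 ≤ 16
(configurable) the exact two-sided p doubles the smaller tail of the full
labelling enumeration — a conditional-on-data exact test, which handles ties
naturally. Larger samples use the normal approximation with tie correction
and continuity correction; for groups of ≥ 5 each this is within 0.02 of the
exact p. All contrasts are two-sided; no multiple-testing adjustment is
applied (raw p-values are reported). `pearson_r` uses the product-moment
formula with a two-sided t-test on n − 2 degrees of freedom; |r| = 1 reports
p = 0.

The GC contrast between overlong and non-overlong copies is restricted to
groups containing both classes (a within-spacer comparison); the repeat
contrasts use all classified cells. Both restrictions are switchable.
Repeat-vs-length correlations are computed over overlong copies, relating
spacer length to the summed repeat base pairs inside the spacer
(midpoint-assigned).

## Nucleotide diversity

π is the mean pairwise per-site difference. Default gap handling is complete
deletion (every column containing a gap or N is dropped first), matching the
common default of the desktop tools used for published π tables;
pairwise deletion is available because the convention is often unstated.
Reproducing published π ranges additionally requires the external
alignments, so π is exercised on constructed alignments only.

## Synthetic cohort: what it emulates, and the separation guarantee

The generator builds circular quadripartite genomes from a fixed template of
38 real plastid gene symbols (28 LSC, 6 IR ×2, 4 SSC; ~26 kb of coding
skeleton) with spacers between them. Study conditions (defaults): 20
species; baseline spacers 100–1,000 bp; 15% of eligible (species, spacer)
cells expanded by 2–8 kb; expansion GC 0.55 over a 0.40 background; repeat
injection inside expansions at 0.4 tandem arrays, 0.3 dispersed block pairs
and 0.5 SSRs per kb; the two loss-prone tRNAs (trnT-UGU, trnR-UCG) each lost
with probability 0.1 per species; SSC inverted with probability 0.1. One
integer seed drives everything; the same seed yields byte-identical GenBank
output.

Two deliberate design choices make closed-loop recovery exact rather than
merely likely:

1. **Shared baselines.** Gene lengths, gene sequences and baseline spacer
   lengths are drawn once per cohort and shared by all species, so every
   inter-species length difference is an injected expansion. With
   independent per-species baselines the strict-mean rule cannot have
   perfect precision (a 1,000 bp baseline exceeds a mean shifted by one
   distant expansion), so "perfect recovery" would be unattainable by any
   classifier following the stated rule. A `baseline_jitter` knob (default
   0) relaxes this for power studies.
2. **Within-spacer delta separation.** For each spacer, the expansion deltas
   across species are redrawn (within 2–8 kb) until the smallest exceeds the
   spacer's mean expansion load over the species carrying it; a cell is then
   overlong iff it was expanded, exactly. Without this, a spacer expanded in
   many species can pull its mean above its smallest expansion.

The generator also forces the first SSC base to break inverted-repeat
extension, so the detected partition equals the injected one to the base.
Boundary spacers (the four cells straddling region junctions) and
loss-fused spacers never receive expansions; expansions in IR spacers are
mirrored in both copies. Gene loss deletes the gene and fuses its flanking
spacers, producing the missing-cell semantics of the homology groups.

Per species the identity `genome length = gene total + Σ (spacer length ×
copies)` holds exactly, so the correlation between genome size and total
spacer length counting both IR copies is 1 up to the (tiny) variance of tRNA
losses; the one-copy convention reports a slightly lower r. The cohort-level
validation (20 seeds) checks sensitivity = precision = 1.0, r > 0.99, and a
GC contrast p < 0.001.

**What passing does not show.** The synthetic cohort has iid background
sequence, no phylogenetic signal, no substitution model, exact repeat
copies, sharp expansion boundaries, and expansions that are the sole source
of size variance. Real plastomes violate all of these; in particular the
published size correlation (r ≈ 0.8) is weaker than the synthetic one
precisely because real genomes vary for reasons other than spacers, and real
SSR totals depend on upstream tool conventions (the replication driver
flags this). The closed loop validates the machinery, not the biology.

## Problem sizes and runtime choices

Synthetic genomes run 60–110 kb (a deliberately reduced coding skeleton with
realistic spacer statistics); the default cohort of 20 takes a few minutes
through the full pipeline, dominated by the dispersed-pair scan. Oracle
equivalence is asserted on sequences up to 2 kb, where exhaustive
enumeration is exact and fast. Tandem-scan oracle sweeps cap the period at
64 bp (a scan parameter applied to both implementation and oracle); the full
500 bp ceiling is exercised in the genome-scale scans.

## Known limitations

* The tandem finder is exact-copy; diverged arrays found by fuzzy tools are
  reported fragmented or not at all.
* Overlapping maximal dispersed windows that share a seed region are all
  reported (as in REPuter-style maximal-pair semantics); consumers wanting
  one hit per locus should cluster by overlap.
* Junction calls at crowded boundaries list all tied nearest genes; which
  single gene a published figure chose to draw is not always recoverable.
* `detect_quadripartite` assumes a single dominant IR pair; plastomes with
  IR loss raise `NoInvertedRepeatError` and are reported as
  non-quadripartite rather than partitioned differently.
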