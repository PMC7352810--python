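# Methods

## Problem and model

A human melanoma xenograft growing in a mouse releases miRNAs — free in
plasma and packaged in small extracellular vesicles (sEVs) — into a
circulation that already carries the host's own miRNAs. Mature miRNAs are
19–24 nt and frequently identical between the species, so attribution is a
property of the *sequence*, not of the read: the name universe is split
into human-specific, mouse-specific and conserved miRNAs, and only the
first group is an unambiguous tumor readout. The conserved group is
analyzed separately under the assumption that a conserved miRNA whose
plasma level rises above the tumor-free control as the tumor grows is
likely tumor-released.

## Conserved pairing

Two mature sequences from different species are paired when the shorter is
an exact contiguous substring of the equal-or-longer other (identity
included). This is the deterministic reduction of "perfect full-length
alignment against an equal-or-longer target": implemented as substring
search rather than a heuristic local aligner, it has no seed-size or
word-length artifacts and needs no external binary. One-to-many pairing is
allowed; a name is conserved if it participates in ≥ 1 pair. Sequences
containing ambiguity codes never pair (zero-mismatch semantics cannot
match an N). Pairs are reported and counted under the human-style name.

## Read classification

Reads are matched by read-in-mature containment: size-selected,
adapter-trimmed small-RNA reads are at most mature length, so a perfect
alignment of the read against the reference is exactly substring
containment. A substring index (every ≥ `min_len` window of every mature
sequence → names) resolves each distinct read sequence in one lookup;
duplicate reads are matched once and weighted. `min_len` defaults to 16 nt
— shorter perfect matches are too unspecific to assign. Category
resolution is deterministic and order-free; rather than keeping a single
arbitrary best hit, all matched names within the resolved category are
counted, and conserved tallies merge the two species under the human
name. Per read exactly one of {unassigned, ambiguous_cross, one-category
increment} occurs. FASTQ qualities are ignored.

## Normalization and time-course statistics

miR-451 is removed from the count tables *before* CPM scaling, so this
erythrocyte (hemolysis) contaminant does not inflate library sizes; the
pipeline refuses the opposite order. Library size is the within-category
column total, since the three categories are analyzed as separate
datasets; a flag allows joint normalization but is off by default. CPM
columns sum to 10⁶ (relative tolerance 1e-6); zero-count columns become
all-zero with a warning. Replicates are averaged on the CPM scale.

Accumulation over time is tested per timepoint against control with an
unpaired one-tailed (greater) two-sample pooled-variance t-test on a
per-sample summary statistic. The summary defaults to the number of
detected (CPM > 0) miRNAs — the count of distinct species present is
robust at the very small replicate number (n = 2 per condition) — with
per-sample total CPM as the alternative selector. A fully degenerate
comparison (both groups constant and equal) returns p = 0.5 (t = 0
convention). The conserved growth-trend filter keeps a miRNA when its
day-23 mean CPM strictly exceeds the control mean; an optional
fold-change floor exists and defaults to 1 (plain strict increase), with
no multiplicity correction, matching the screen's exploratory role.

## Abundance profiles

Percentages are `100·xᵢ/Σx` on replicate-mean CPM; rank ties break
lexicographically by name. The abundant set is strictly `> 2%` — the
boundary value is excluded, resolving the ambiguity between "greater than
2%" and "below 2% not relevant" phrasings in favor of the strict reading.
Clustering uses 1 − Pearson correlation of log₂(CPM+1) sample columns with
average linkage — the common transcriptomics default; all three choices
are parameters. Constant columns get correlation 0 with a warning rather
than NaN. Compartment correlation is Pearson on log₂(CPM+1) over the union
of names with absent miRNAs as 0; disjoint-support compartments therefore
anticorrelate weakly rather than erroring.

## External validation

The clinical evidence is a matrix of log₂ quantile-normalized EV probe
intensities with healthy / primary / metastatic labels. "Expressed in a
group" means intensity strictly > 5 in at least ⌈fraction·n⌉ of that
group's samples (fraction 0.5); the filter is evaluated within the group
under test (metastatic for the headline overlap). Name canonicalization
strips the species prefix and case-folds but keeps the arm suffix, so
`hsa-miR-21-5p` meets the array label `miR-21-5p`. Group comparison is a
per-miRNA Welch t-test on log₂ intensities with Benjamini–Hochberg
adjustment; Welch replaces a moderated (empirical-Bayes) statistic — with
thousands of probes and no shared-variance shrinkage requirement the
unequal-variance t is the transparent choice, and the statistic is
pluggable. The progression screen is ordinal: strictly increasing group
medians along healthy → primary → metastatic, with no significance
requirement (a 2-sample primary group cannot reach significance). Being
ordinal, it admits chance passes: three near-independent group medians
land in increasing order with probability ≈ 1/6 per null miRNA, which is
the screen's expected false-positive rate and the reason it is a screen,
not a test.

## Synthetic data

The simulator plants: identical pairs (shared sequence), containment
pairs (mouse = human plus 1–3 flanking nt), and species-unique sequences,
all mutually substring-free apart from the planted pairs, so each read has
a unique assignment and classification is checkable read-for-read.
Defaults mirror the study design: two replicates at control/day 7/14/23
for total plasma, sEVs at day 23; library 10⁵ reads; per-miRNA abundances
log-normal (σ = 1.5) — reproducing the long-tailed rank-abundance shape —
drawn once per (compartment, pool) so replicates correlate while
compartments differ; tumor-read fractions 0 / 0.02 / 0.06 / 0.12, placing
the late human-specific signal near the ~10% observed in the xenograft.
Database sizes default to 60 human-specific, 80 mouse-specific and 65
conserved entries — of the same order as the detected (not annotated)
miRNA universe in such libraries, kept small enough that the full suite
runs in seconds. Reads are error-free by default (a zero-mismatch filter
discards errored reads anyway); an optional per-base substitution rate
exists to verify that errored reads land in `unassigned`. The clinical
simulator draws N(7, 1) log₂ intensities with +shift per group step for
designated trend miRNAs over groups of 8/2/8.

What the simulator does **not** emulate: sequencing error profiles,
isomiRs/non-templated additions, adapter read-through, probe chemistry and
cross-hybridization, or biological covariance between miRNAs. Passing
tests therefore demonstrate the correctness of the computations and the
recoverability of planted signal under the stated noise model — not
performance on real libraries, where mismatched reads are discarded by
the zero-mismatch rule and isomiRs shift counts between arms.

## Numerical choices and degenerate inputs

- CPM conservation asserted at 1e-6 relative tolerance.
- All-zero abundance vectors are a hard error; zero-library CPM columns
  are all-zero with a warning.
- Degenerate t-tests: equal-and-constant groups give p = 0.5 (one-tailed
  accumulation) or p = 1 (two-sided group comparison).
- Rank ties break by name; clustering sorts columns by sample id before
  linkage so dendrogram tie-handling is deterministic.
- All randomness flows through explicit integer seeds (Python `random`
  for sequence generation, NumPy `default_rng` for read draws and
  intensities); identical seeds give byte-identical outputs.

## Problem sizes used in the checks

The verification suite runs the conserved-pairing oracle comparison on 50
random database pairs of up to 200+200 entries, classification recovery
on a 10⁵-read library, the monotonicity grid on 5×10⁴-read libraries, BH
agreement on 1000 random p-vectors, and null calibration on 1000-miRNA
matrices — sizes chosen to exercise the asymptotic behavior while keeping
a full run in well under a minute.

## Known limitations

- Reads longer than their source mature sequence (untrimmed adapters) are
  unassigned rather than soft-clipped.
- Orthology is two-species and exact; near-conserved miRNAs (1 mismatch)
  are treated as species-distinguishable, which is precisely what the
  deconvolution requires but is not an evolutionary statement.
- The expressed/overlap stage assumes the external matrix is already
  quantile-normalized and probe-annotated; no re-annotation across miRNA
  registry versions is attempted.
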