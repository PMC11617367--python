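# Methods

This note documents the models and procedures `dualprot` implements,
the parameters that matter, the design choices that were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## De Bruijn contig assembly

De novo reads carry a per-residue confidence in [0, 1]. Each read is
decomposed into k-mers (default k = 8); a k-mer is an edge between its
prefix and suffix (k−1)-mers with weight equal to the sum, over
supporting read windows, of the window's mean per-residue confidence,
and count equal to the number of supporting windows. Contig extraction
is greedy: seed at the heaviest unused edge, extend both directions
along the heaviest unused edge, break ties lexicographically by k-mer,
never reuse an edge. This makes assembly deterministic (independent of
read order), guarantees termination on cycles (a repeated k-mer stops
extension), and yields the exact source peptide for error-free tiled
reads of any sequence with no repeated k-mer — the reconstruction
property the test suite enforces. Contigs shorter than `min_contig_len`
(default 10 aa, the reporting threshold for contigs) are dropped. A
contig's `support_reads` is the maximum per-edge read count along its
path (peak depth) and `mean_confidence` is the weight/count ratio over
the path. Assembly is per sample: occurrence counts of a contig across
samples are a downstream quantity, so pooling reads across samples
would destroy the information the cohort comparison needs.

## Alignment and identity gates

Contig-to-reference mapping uses exact affine-gap Smith–Waterman
(match +2, mismatch −1, first gapped column −3, each further −1; the
scoring values are package defaults, the published quantities are the
identity gates, not scores). No heuristic seeding is used — databases
here are desk-scale and exactness keeps the 75%/95% thresholds
meaningful; an exact-substring fast path short-circuits the common
case. Ile and Leu are isobaric and indistinguishable to de novo
sequencing, so matching, clustering and proteotypic counting treat them
as equivalent by default (`il_equivalent`).

Mapping identity = 100·matches/aligned columns (gap columns included).
A hit must cover ≥ 50% of the contig. Classification: *canonical* when
the entire contig aligns with every residue matched (an exact substring
up to I/L — a clipped 100%-identity window of a variant does not
qualify); *noncanonical variant* when the best identity is in
[75%, 100%); *unmatched* below the gate. Among co-optimal alignments
the one with the smallest target end (then fewest gaps via a
diagonal-preferring traceback) is returned; this is a deterministic
tie-break, chosen because a unique canonical answer matters more than
which co-optimum is reported.

Clustering identity deliberately uses a different denominator:
100·matches/min(len a, len b). With the alignment-column denominator a
tryptic peptide nested in a longer contig, or a missed-cleavage
extension, could never reach 95%; with the min-length denominator they
cluster together, which is the point of uniting "sequences of different
lengths". Greedy centroid clustering visits sequences longest-first
(ties: sequence, then id) and joins the first centroid at
≥ `cluster_identity_min`; the centroid is therefore always the longest
member, and the output is a deterministic partition.

## Evidence merging and cohort summaries

Per protein, residue coverage is kept separately for the library
channel (exact peptide occurrences, all occurrences counted), canonical
contigs (alignment footprints), and noncanonical contigs (matched
columns only — a mismatched residue is evidence of a variant, not of
the reference residue). Sample counts (Sz = cases, Cnt = controls)
count distinct samples with any supporting identification from either
strategy. Abundance tiers follow the plasma convention: high
> 1 μg/mL, mid 10 ng/mL–1 μg/mL inclusive of both bounds, low below,
`unknown` when no concentration is annotated; concentrations are stored
in SI (g/L). Group-specific selection keeps proteins with
Sz ≥ 9, Cnt ≤ 5 and at least one proteotypic peptide (a peptide
occurring in exactly one database protein, I/L-equivalent); the
thresholds are configuration, reverse-engineered from the extreme rows
of the reference selection, not constants of nature. The ≥ 10-sample
detection filter is applied to the pooled cohort by default; a
`--per-group` flag applies the stricter per-group reading (the pooled
reading is the default because the reference selection contains
proteins with control counts as low as 0). Reported percentages are
rounded half-up to integers, which reproduces every checked reference
coverage cell (93, 32, 80, …).

## Peptide physicochemistry

Aliphatic index: Ikai's mole-percent formula with coefficients 2.9
(Val) and 3.9 (Ile + Leu), reported rounded half-up. Masses are average
(not monoisotopic) residue masses plus one water, via pyteomics; the
reference table's kDa values reproduce under average masses only.
Eight of the ten reference contig rows reproduce the printed aliphatic
index exactly under this formula; two rows (printed 123 and 43) do not
reproduce under any standard coefficient set and are excluded from
assertions rather than chased with ad hoc corrections.

## Structural phosphosite characterization

SASA uses the Shrake–Rupley construction: each heavy atom's van der
Waals sphere (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å) inflated by the
probe radius (1.4 Å water) is sampled with a deterministic
golden-section Fibonacci point set (default 960 points/atom, a
resolution at which totals agree with an independent implementation to
< 0.1% on test fixtures); per-atom SASA is the exposed fraction times
4π(r+probe)². Hydrogens are ignored entirely, consistent with X-ray and
predicted models lacking them.

The phosphorylated proteoform is built with minimal explicit geometry:
P is placed 1.6 Å beyond the side-chain hydroxyl oxygen along the C–O
bond, three terminal oxygens at tetrahedral geometry (P–O 1.5 Å,
O–P–O 109.47°, hence terminal O–O ≈ 2.45 Å); no other atom moves and no
minimization is performed. This is a reproducible methodological
stand-in for whatever modeling produced any particular published
K_SASA value — the package's claim is the *property* (K_SASA ≤ 1 at
solvent-exposed sites, i.e. phosphorylation adds exposed area), which
holds on every exposed-site fixture, not any specific published ratio,
which would depend on the exact source structures and an unpublished
phospho-modeling protocol.

Secondary structure at a site is a 3-way torsion-window label — helix
for φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); strand for φ ∈ (−180°, −90°),
ψ ∈ (90°, 180°); each required at the site and both neighbors — with
"n/d" when backbone context is incomplete. This is intentionally not
DSSP: the report needs only a coarse label, and a window rule is exact
on the ideal-geometry fixtures the builder produces. Per-residue model
confidence (e.g. AlphaFold pLDDT) is read from the B-factor column and
summarized as mean ± population sd over the peptide.

The `builder` module constructs synthetic peptide scaffolds (backbone
plus Cβ and Ser/Thr hydroxyls) from uniform φ/ψ via natural-extension
internal coordinates; these are test fixtures with controlled geometry,
not predicted structures.

## Synthetic cohorts and what the tests show

The generator's defaults are the study conditions: 48 case / 50 control
samples; protein lengths log-uniform on [50, 3000] aa with i.i.d.
residues at Swiss-Prot background frequencies; tier fractions
(0.23, 0.20, 0.57) following the approximate high/mid/low proportions
of a deep plasma profile; per-sample detection probabilities
(0.9, 0.5, 0.15) by tier (abundance drives detectability in DDA);
within a detected protein each tryptic peptide (cleave after K/R except
before P, ≤ 2 missed cleavages, ≥ 6 aa) is emitted with probability
0.6. De novo reads tile 2 disjoint segments of 25–50 aa per protein in
20-aa windows at step 5, with per-residue confidences ~ Beta(8, 2),
substitutions at rate 0.01 (I↔L preferred — the dominant de novo
confusion) and adjacent transpositions at 0.005. Planted case-specific
proteins are detected at the tier probability in cases and never in
controls (the group effect is presence/absence, matching a
detection-count analysis, not quantitation). Planted noncanonical
variants replace one segment with a substituted version whose identity
to the source is inside [75%, 100%) (edits kept ≥ 2 residues from the
segment ends so local alignment cannot clip them away, and never
I↔L); these proteins bypass the library channel entirely
(`library_miss_rate` = 1), which is what makes variant proteoforms a de
novo-only discovery.

What passing tests show: the pipeline recovers planted truth exactly
under noise-free conditions and degrades gracefully under 20% detection
dropout; identity gates classify planted variants correctly; assembly
is exact on unique-k-mer segments. What they do not show: behavior on
real spectra (no spectrum simulation, no retention time or charge, no
homologous protein families, no shared peptides between paralogs —
i.i.d. random sequences make almost every peptide proteotypic, which is
optimistic), nor reproduction of dataset-level counts from the
reference cohort, which would require the original raw data and the
upstream search engines.

## Numerical conventions

All internal coordinates are 0-based half-open; 1-based inclusive
numbering appears only at I/O boundaries (PTM sites, peptide ranges,
reported positions). All reported rounding is half-up (never banker's).
Residues outside the 20-letter alphabet (including B/Z/X/U/O) are
rejected at parse time because the mass and aliphatic-index formulas
are undefined for them. Every stochastic component takes an explicit
seed; identical seeds give byte-identical outputs, and a run manifest
(config snapshot, input digests, version, seed) accompanies every
pipeline run.

## Problem sizes used in tests

Unit and property suites run on toy fixtures and small cohorts; the
end-to-end recovery checks use a 10/10-sample, 20-protein cohort with 3
planted variants, and the group-specific recovery check uses the full
48/50 cohort with 30 proteins and 5 planted case-specific proteins —
sizes chosen so the exact (unseeded) alignment stage stays desk-scale
while every planted effect remains individually checkable.
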