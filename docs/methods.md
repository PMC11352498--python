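# Methods

mirforge reimplements, at desk scale and with a fully synthetic benchmark,
the analysis chain used in plant small-RNA sequencing studies of stress
response: read cleanup, miRBase-style known/novel miRNA classification,
hairpin-criteria filtering of genome-derived candidates, ANOVA differential
expression, and 2^-ddCt qPCR quantification. This note records the models,
the defaults and why, and what the synthetic benchmark does and does not
establish.

## Read cleanup (`mirforge.preprocess`)

Reads are trimmed by 3'-anchored adapter search: the leftmost position where
the adapter (or an adapter prefix running off the read end) matches with at
most `max_adapter_mismatch` substitutions (default 1, no indels). Two guards
keep the rule total and sane at degenerate overlaps: a match must span at
least `min_overlap` bases (default 3) and may never consist mostly of
mismatches (mismatches < matched length). A read with no hit is returned
unchanged, so cleaning already-clean input is a no-op.

Inserts are then filtered by length (18–25 nt inclusive), low complexity
(dropped when one base exceeds 0.8 of the length, or any mono/dinucleotide
repeat pattern covers ≥ 0.9 — conventional defaults, configurable), and
contaminant membership (exact substring of an rRNA/tRNA/snRNA/snoRNA
reference, sense strand only; repeats match either strand). When a tag
matches several families the label follows a fixed precedence
rRNA > tRNA > snRNA > snoRNA > repeat, for reproducibility. Every read lands
in exactly one disposition bucket and the per-sample ledger is checked for
conservation on every run; `valid_reads` (the retained total) is the number
a sequencing report would quote as valid data.

## Classification (`mirforge.annotate`)

Retained tags are assigned by first-match precedence: (1) annotated mature
arm of a same-species precursor → known; (2) opposite arm of a same-species
precursor → novel 5p/3p arm product; (3) mature arm of another species'
precursor whose hairpin also occurs in the study genome → known (cross-
species); (4) genome locus whose flanking window folds into a
criteria-passing hairpin → candidate; else unannotated. Alignment is
ungapped with at most one internal mismatch; positions inside the outer
`max_end_variation` bases (default 3 per end, symmetric) are treated as end
variation and excluded from the mismatch count, since no published bound
exists for either choice. Searches use pigeonhole seeding (two exact halves
of the central region) and re-score candidates exactly, which at ≤ 25 nt is
equivalent in sensitivity to a BLAST of the full tag; multi-locus tags are
counted once at the highest-precedence hit with secondary hits logged.

End shifts are reported as signed outward extension: `_L+n` means the 5'
end extends n nt beyond the annotated mature, `_L-n` that it is trimmed;
`_R±n` likewise for the 3' end. Opposite-arm products take the precursor
name plus `-p5`/`-p3`; genome candidates are `PC-<arm>-<serial>_<count>`
with a run-deterministic serial (tags processed by descending abundance)
and the tag's total read count. Name collisions — typically a
sequencing-error copy of a tag that maps to the same product — are broken
with a `_v2`, `_v3`… suffix so names are unique within a run while the
count matrix pools `_v` variants with their canonical entry.
`parse_mirna_name` inverts every generated form.

## Hairpin folding and criteria (`mirforge.hairpin`)

Folding is an energy-weighted Nussinov dynamic program: the optimal
pseudoknot-free structure under per-pair energies G:C −3.0, A:U −2.0,
G:U −1.0 kcal/mol with a minimum hairpin loop of 3 nt; no stacking or
dangle terms. The traceback prefers pairing the left end with the smallest
admissible partner, making results deterministic. This pseudo-energy is
monotone with thermodynamic stability and is validated against exhaustive
enumeration of all nested structures for sequences up to 30 nt; Vienna
RNAfold output can be substituted through the Vienna reader and is scored
by the same criteria, including the −15 kcal/mol cutoff, whichever energy
source is used.

A candidate locus is evaluated on the ±120 nt flanking window. Because a
260-nt optimal fold essentially always carries side helices, the criteria
are applied to the stem-loop containing the mature sequence: every maximal
helix chain (a terminal loop walked outward until a multibranch junction,
the exterior loop, or an internal loop larger than 12 nt) is a candidate
and the chain pairing the most mature positions wins; discarded pairs
simply leave their positions unpaired. Decomposition of the chain gives
stem pairs, the terminal loop, and bulges recorded as (5'-arm nt,
3'-arm nt); positions across stem, loop, bulges and exterior always sum to
the sequence length.

The eleven criteria (all bounds inclusive): largest stem bulge ≤ 12 nt;
stem ≥ 16 bp; energy ≤ −15 kcal/mol; hairpin length (outermost-pair span,
bulges included) ≥ 50 nt; terminal loop ≤ 200 nt; largest mature-region
bulge ≤ 4 nt; largest mature-bulge asymmetry ≤ 2 nt; ≤ 2 asymmetric
mature bulges; ≤ 4 unpaired mature bases; ≥ 12 mature base pairs; ≥ 80% of
mature bases paired. "Biased" bulges have no published formal definition;
they are interpreted as bulge asymmetry (5'-arm minus 3'-arm unpaired
count), and the verdict records that interpretation explicitly. A bulge
belongs to the mature region when any of its unpaired positions falls
inside the mature interval. The terminal-loop reading of the ≤ 200
criterion is likewise a documented choice. Tightening any single threshold
can only shrink the passing set (verified property).

## Differential expression and qPCR (`mirforge.diffexpr`)

Counts are normalised to counts-per-million over retained miRNAs (the
normalisation used upstream of the published ANOVA is unnamed; CPM is the
standard small-RNA choice and is monotone). Testing is a one-way
fixed-effects ANOVA on log2(CPM + 1); for two groups this is exactly the
pooled-variance t-test (F = t², verified to 1e-10). Zero-variance rows
return p = 1 rather than erroring mid-pipeline. A miRNA is called in a
contrast "treatment vs control" when raw p ≤ 0.05 AND the fold change,
(mean CPM_t + 1)/(mean CPM_c + 1), is ≥ 2 in either direction; the same
gate at p ≤ 0.01 is reported alongside, as are Benjamini–Hochberg q-values
(reported, never gating — the screening rule is raw-p by design, the
q-values are modern context). Whether the published ANOVA ran per pairwise
contrast or once across three groups is unstated; both are supported and
per-contrast is the default, matching the three reported comparisons.

Venn partitioning and direction-concordance classes are exact set algebra
(disjoint, exhaustive — property-tested). Sample correlation is Pearson on
the normalised matrix. Clustering of DE miRNAs is average-linkage on
1 − Pearson over row-z-scored log2 expression, with rows pre-sorted by name
so leaf order is permutation-invariant; the linkage is cross-checked
against a naive agglomerative oracle. qPCR fold changes use 2^-ddCt with
U6 as reference and water as calibrator; the calibrator fold is 1 by
construction and the closed-form identities (ddCt +1 → 0.5, −2 → 4) are
exact.

## The synthetic study (`mirforge.synthetic_data`)

The generator emulates the study design end to end: three conditions
(H2O, NaCl, Na2CO3) × three replicates; 12 known precursors with annotated
mature arms (each also emitting an opposite-arm product at 5% of the mature
abundance); 2 foreign precursors implanted in the genome; 6 novel hairpin
loci present only in the genome (one implanted on the minus strand);
contaminant rRNA/tRNA references supplying 20% of reads; 200k reads per
library. Reads are mature sequences with an 80/5/5/5/5
canonical/L+1/L−1/R+1/R−1 end-shift mix (exercising the naming grammar),
substitution errors at 0.1% per base (one substitution per errored read),
the 3' adapter, and random padding to 50 nt. Every read id encodes its
origin, so the truth manifest attributes all reads.

Abundances are lognormal: entity weights are drawn lognormal(0, 1) and
per-library counts are lognormal around the condition mean with replicate
CV 10% — chosen over a negative binomial for the transparency of the CV
knob. Twenty entities are truly DE at fold 4 (ten responding to NaCl, ten
to Na2CO3, half up and half down). Because *every* primary entity is DE in
one contrast, naive direction assignment lets the heaviest entities shift
total library mass ~2× between conditions, and CPM normalisation then
compresses the spiked up-folds below the FC ≥ 2 gate; directions are
therefore assigned greedily down the abundance ranking to keep the expected
library mass balanced — standard spike-in benchmark practice. Novel cores
carry 8-nt stem extensions beyond the mature arms so the hairpin sits
comfortably above the 50-nt length criterion even when the window fold
nibbles an outer pair. Precursor terminal loops are non-pairing (all A)
with a G/C base anchored at the loop-adjacent mature end, making the
intended stem the unique fold optimum.

What passing the benchmark shows — and does not. The simulator exercises
every pipeline branch with known truth: classification recall, naming
round-trips, ledger conservation, DE recall/type-I behaviour, and seed
determinism. It does not model ligation or GC bias, quality-score error
profiles, isomiR abundance structure beyond the fixed shift mix, multi-copy
miRNA families, or genomes with repetitive structure; perfect recall here
therefore bounds software correctness, not expected performance on real
libraries.

## Problem sizes and numerics

The bundled defaults run the full pipeline (9 × 200k reads) in about two
minutes on one core; the test-suite fixtures use 1.5k–8k reads per library
and the folding oracle checks 200 random sequences of length ≤ 30, where
exhaustive enumeration is exact and fast. DE calibration uses 2000 null
miRNAs (type-I rate 0.05 ± 0.01 binomial band) and 20 spikes among 500 for
power. All randomness flows from one seed through
`numpy.random.default_rng`; reruns are byte-identical. Energies are exact
multiples of 0.5 kcal/mol, so DP/traceback comparisons use exact float
equality; ANOVA degenerate inputs (zero within- or total variance) are
resolved by convention before the F quantile is evaluated.

## Known limitations

The stand-in energy model ranks structures by weighted pair count, not
thermodynamics; absolute energies are not comparable to RNAfold's, only the
−15 kcal/mol gate is shared. Alignment is substitution-only (no indels),
appropriate at ≤ 25 nt but blind to rare templated indel isomiRs.
Contaminant filtering is exact-substring, so a contaminant read with a
sequencing error escapes the filter (and ends up unannotated, not
misannotated). The xeno branch requires an exact genome copy of the foreign
hairpin. DE uses raw-p gating by design; with thousands of tested entries
the q-value columns should inform any real-data interpretation.
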