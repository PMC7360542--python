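# Methods

This note documents the models, parameter choices and numerical
behaviour of `polykasp`, in the order of the pipeline.

## Strand decoding

Array manifests publish a bracketed 101 bp context plus two TOP/BOT
designations (submitted "customer" strand and the provider's design
strand). The TOP/BOT rule implemented is the published standard the
manifest columns presuppose: unambiguous SNP pairs {A,C} and {A,G} are
TOP, {T,C} and {T,G} are BOT; the ambiguous pairs {A,T} and {C,G} are
resolved by walking outward from the SNP and letting the first flank
pair with one A/T base and one C/G base decide (A/T on the 5' side →
TOP). Palindromic flanks raise `UNRESOLVABLE_STRAND`. When the two
designations differ, the context is reverse-complemented before probe
extraction. Which 50 bp flank is the physical probe is not recorded in
public manifests; we fix the 50 bases 5'-adjacent to the SNP on the
design strand (single-base-extension convention) and expose
`probe_flank="3prime"` to flip. Declared alleles are interpreted on the
submitted strand. Coordinates are 0-based half-open internally; 1-based
only at serialisation boundaries (BED and assay TSVs).

## Homeolog search

Seed-and-extend: exact 12-mer seeds locate candidate windows; each window
is refined with an affine-gap local alignment (Gotoh, via
`Bio.Align.PairwiseAligner`). Scoring is match +1, mismatch −1, gap of
length L scoring −(2 + 0.5·L) — the tools named in the field's workflows
do not fix scores, so these are package constants, configurable via
`Scoring`.

**Spliced chaining.** Under this scheme a single local alignment
truncates at an intron (a 120 bp gap costs −62, more than the ~41
downstream matches repay), so the search collects local segments by
repeated best-alignment with query masking and selects the best
co-linear chain (query gap ≤ 10, target gap ≤ 5 kb). Splice gaps are
annotated, not scored. Because a local aligner extends noisily into an
intron, junction boundaries are refined to the maximum-match split of
the query bases around each large gap (ties broken toward the rightmost
split). Where the intron's edge base coincidentally equals the adjacent
exon base, alignment-equivalent placements remain and the reported
junction can wobble by a base or two — an identifiability limit of the
data, not an implementation artifact.

**Filters.** Hits must pass two conjunctive filters: percent identity
≥ 0.80, computed as matches over aligned query columns (target-only gap
columns, i.e. introns, are excluded from the denominator — note that
published "similarity" figures rarely state their denominator, so
comparisons against other tools can differ at the margin); and a
Karlin–Altschul-style E-value E = K·m·n·e^(−λS) ≤ 1e−5 with λ = ln 3
(the ungapped solution for the ±1 scheme at uniform composition) and
K = 0.3 as documented calibration constants, not fitted values.
Overlapping same-strand hits within 10 bp merge keeping the higher
score; ordering is by identity descending, ties by (assembly, chrom,
start), making the search deterministic.

**Profiles.** Hit regions are extracted with 150 bp padding, oriented to
the query strand, and joined in a star multiple alignment anchored on
the best hit (assumed to be the probe's source locus). Insertions
relative to the reference get their own columns; mutually unalignable
stretches (e.g. diverged intron interiors) are paired left-to-right,
which is adequate at homeolog-level divergence and only affects columns
already excluded from primer windows. Intron-classified columns are
per-row gap runs ≥ 30 bp (`min_gap`, configurable — large enough to
clear alignment noise, small compared to real introns); shorter runs are
indel segments. `SNP_COLUMN_LOST` is raised when the probe's SNP cannot
be placed in any column.

## Cluster model

Signal equivalents count A/T (green) and C/G (red) characters over the
2c alleles of the bound copies; θ = red/(green+red) is the comparison
coordinate (instrument arctan transforms are monotone in θ, so cluster
order is preserved). Off-target copies are assumed monomorphic within
the modelled population; compositions violating that are classified
`unclassified` rather than forced into the taxonomy. Geometry decides
the class: one bound copy → `simple`; both homozygous classes at mixed
(green>0 and red>0) points → two heterozygous-position clusters; exactly
one pure-color homozygous point → one. A same-color substitution of a
declared allele never changes the layout, so any multi-copy layout whose
declared pair admits such a substitution is flagged `color_ambiguous`
(and a two-het layout is reclassified `hemi_triallelic_ambiguous`);
single-copy declarations are exempt because the submitted probe context
itself anchors the allele identities. Sanger-resolved target alleles
override: set-equality confirms, difference contradicts. The
one-homozygous-cluster hemi case is interpreted as off-target alleles
matching one target allele's color exactly.

## Primer design

Allele-specific primers end 3' exactly on the SNP (lengths 18–30, both
orientations); the common primer sits on the opposite strand within
total amplicon bounds 50–120 bp. Windows are contiguous alignment
columns of the target row; windows crossing intron-classified columns
are excluded for all primers, indel segments are a hard exclusion for
the common primer and a soft flag for allele-specific primers. Off-target
scoring weights a 3'-terminal-base mismatch 4, positions 2–5 weight 2,
elsewhere 1; a copy with no alignable site contributes the
`absent_site_weight` (6) as the strongest uniqueness evidence. When
off-target copies exist, common-primer candidates must have ≥ 1 mismatch
against every copy to be retained at all.

Tm uses the nearest-neighbor model (`Bio.SeqUtils.MeltingTemp.Tm_NN`,
SantaLucia parameters) under PCR-mix-like solution conditions (50 mM
monovalent, 1.5 mM Mg²⁺, 0.6 mM dNTPs, 50 nM primer), targeting
57 ± 3 °C — anchored to the 57 °C annealing/elongation step of the
assay chemistry. The common primer, which has positional freedom, takes
the range as a hard gate; the allele-specific primers are locked onto
the SNP, so their (window-mean) Tm deviation is a soft penalty of
0.5/°C — restrictive thermodynamic rejection is exactly the failure mode
of generic primer designers on position-constrained problems, and
homopolymers and mild 3' self-complementarity are likewise soft
penalties (0.5 per excess base / occurrence), never exclusions. Both
allele-specific primers share one placement, so the allelic amplicons
are equal-length at design time; products differing by > 10 bp (possible
under haplotype indels) are flagged, since size differences drive
preferential amplification.

Selection is deterministic: triples are ordered by (common primer 3'
blocked on every off-target, common uniqueness, allele-primer
uniqueness, Tm proximity, soft penalties, orientation, columns).
Specificity classes: `locus_specific` when the common primer has ≥ 1
mismatch in its 3'-terminal 5 bases against every off-target copy (or no
alignable site — our documented operationalisation of "enough"
discrimination, since no wet-lab threshold is established);
`semi_specific` when it discriminates every copy but somewhere outside
that window; `nonspecific` when some copy is matched perfectly. Failures
are returned as structured reasons (`NO_UNIQUE_SITE`, `INTRON_SPAN`,
`INDEL_REGION`, `SNP_COLUMN_LOST`, `NO_CANDIDATE_IN_TM_RANGE`), never
raised, so batch designs complete. Fluorophore tails are chemistry
constants (the two widely used universal tails), configurable.

The audit re-scans every assembly for all placements of all three
primers with ≤ 3 mismatches; a placement is *productive* only with a
perfect 3'-terminal-5 match (the same extension-blocking assumption the
design rule uses). Feasible amplicons pair a productive allele-specific
placement with a convergent productive common placement ≤ 1.5× the
intended length. Exactly one feasible amplicon is the audit's definition
of locus-specificity; zero placements flag `BROKEN_DESIGN`. Adding
assemblies can only keep or worsen the class.

## Genotype calling and failure modes

Calling normalises to θ and magnitude. Points below the NTC centroid
plus 3 NTC spreads are `missing` (there is no "Null" call anywhere in
the KASP path). Remaining points are clustered by seeded k-means on θ
(k from the expected layout, default 3; fixed `random_state` for
reproducibility), clusters labelled in ascending θ, confidence = the
relative margin between nearest and second-nearest centroid. Centroids
closer than 1e−3 raise `DEGENERATE_CLUSTERS`.

The failure-mode model assigns each allelic product an efficiency
factor exp(−(w₃·m₃ + w_d·min(d,20)/20 + w_s·max(ΔL−10,0)/50)) with
defaults w₃ = 2, w_d = 3, w_s = 1, where m₃ counts 3'-terminal common
primer mismatches, d is a 5' deletion length and ΔL the product-size
difference. This is a qualitative mechanism reproducing the direction
and magnitude of the three documented wrong-clustering scenarios
(common primer binding a second locus; preferential amplification after
a 3' mismatch; a 5' deletion suppressing one product) — not a kinetic
claim. A displaced genotype is predicted mis-called when its θ falls
inside another cluster's assignment radius (half the undistorted
inter-centroid gap). Equal factors recover the undistorted layout
exactly.

## Null-allele haplotype collapse

Rows containing ≥ 1 Null merge into the *unique* Null-free row matching
at all non-Null positions, counts added; rows with no match are retained
and flagged `needs_sequencing`, rows with ≥ 2 matches are retained with
the ambiguity recorded (`AMBIGUOUS_COLLAPSE`). Null-free rows are always
retained regardless of frequency. The operation is idempotent and
conserves counts exactly; frequencies are recomputed from merged counts
and rounded to 0.1%. Printed frequency tables are converted to counts by
nearest-integer at the stated panel size; published corrected
percentages mix two rounding conventions (count-based vs summed
percentages, which can disagree by 0.1 and sum to 100.1%), so exact
comparisons are made only on cells where both conventions agree. The
low-frequency threshold for artifact accounting is strictly < 5%.

## Synthetic data

The generator emulates the structural features the method assumes: a
2 kb base locus duplicated into 3 homeologous copies (defaults) with
binomial point divergence at 5% per site — the realistic range for
recently polyploid subgenomes and comfortably above the 80% retention
threshold for a 101 bp probe; a biallelic target SNP carried only by the
target copy, off-target copies fixed (drawn or configured); optional
introns inserted into every genomic copy (shared position and length,
independent random interiors, since intron sequence diverges fast) while
the probe context is emitted intron-free; optional per-copy deletions at
the documented preset sizes (8/36/53 bp); and an engineered
discriminating column at ±35 bp from the SNP (each off-target copy
forced to differ there) when a guaranteed-unique-window fixture is
requested — both sides, so at least one orientation has a discriminating
site in a Tm-workable context. Signal clouds place Gaussian noise
(default σ = 3% of full scale) around the layout centroids scaled to
instrument-like units (1000), with NTC points near the origin.

Artificial heterozygote mixtures model the endpoint plateau: a template
ratio r maps to an amplified fraction r^γ/(r^γ + (1−r)^γ) with γ = 0.3
before the convex combination of homozygous centroids, reflecting that
competitive endpoint PCR reports allele presence rather than template
dosage — this is why 1:9 through 9:1 mixtures all cluster at the
heterozygous position, and why the calling tests on mixtures check the
assay logic rather than dosage sensitivity. What the generator does not
emulate: repeat landscapes, paralog tandem arrays, base-composition
biases, plate/batch effects, or instrument-specific normalisation — so
passing tests demonstrate correctness of the algorithms under the
modelled structure, not performance on any real genome.

All stochastic operations consume one owned seeded generator; identical
configurations are bit-identical.

## Problem sizes

Oracles and exhaustive scans (full O(nm) dynamic programming, all-window
primer scans, all-placement audits) are kept exact by working at the
2 kb locus scale with 3-copy assemblies; the end-to-end property runs
over 20 seeded fixtures. These sizes were chosen so every cross-check
can be brute-force exact.

## Known limitations

* The star alignment is anchored on the best hit; a badly truncated best
  hit degrades the whole profile.
* Identity denominators differ among tools; the 0.80 threshold is
  calibrated to this package's definition.
* Secondary-structure checks are deliberately permissive (soft
  penalties); no folding thermodynamics are computed.
* The efficiency model for failure modes is directional, not
  quantitative; it is validated against scenario outcomes, not rate
  constants.
* Splice junctions flanked by coincidentally matching bases are
  identifiable only up to alignment equivalence (± a base or two).
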