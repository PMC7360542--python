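# polykasp

Locus-specific KASP assay design from array SNP probes in polyploid
genomes.

## The problem

Trait-associated SNPs are usually discovered on hybridisation arrays
(e.g. Infinium-style 50 bp probes) and then converted into cheap
single-plex KASP (Kompetitive allele-specific PCR) assays for
marker-assisted selection. In an allopolyploid such as hexaploid wheat
this conversion routinely fails, because a probe's 101 bp context matches
two or three homeologous loci at 90–99% identity:

* **Hemi-SNPs.** A probe bound to several copies reports the *sum* of
  their alleles. With the two-color chemistry (A,T → green channel;
  C,G → red), a hexaploid sample's expected signal is the pair of counts
  over all six alleles — e.g. composition `AATTGG` gives (4 green,
  2 red). Homozygous individuals then sit at heterozygous-looking cluster
  positions, and dosage, not genotype, drives the layout.
* **Triallelic hemi-SNPs.** Because A/T (and C/G) are spectrally
  identical, a declared T/G polymorphism and a true A/G polymorphism
  produce *identical* cluster layouts; the declared alleles can be wrong
  while everything looks normal.
* **Null-allele artifacts.** Failed hybridisation is reported as a "Null"
  allele and propagates into spurious low-frequency haplotypes that
  dilute haplotype–trait associations.
* **Primer-site pitfalls.** A common primer that also binds a homeolog,
  a 3'-terminal mismatch or 5' deletion under one allelic product, an
  exon–intron boundary under a primer designed from transcript-derived
  context — each displaces clusters and miscalls heterozygotes.

`polykasp` implements the whole desk-side workflow: TOP/BOT strand
decoding of probe manifests, homeolog discovery and joint alignment
across one or more assemblies, dual-color dosage modelling of cluster
layouts, constraint-based placement of the two tailed allele-specific
primers and the common primer with 3'-weighted off-target scoring, an
exhaustive in-silico specificity audit, endpoint genotype calling with
artificial-heterozygote validation, and the Null-allele haplotype
collapse. A seeded synthetic allopolyploid generator makes every stage
testable without downloading a genome.

## The model in brief

For a probe bound to *c* copies with per-copy diploid alleles
concatenated into a composition string *s* (length 2c), the expected
signal equivalents are

    green(s) = #{ i : s_i ∈ {A, T} },   red(s) = #{ i : s_i ∈ {C, G} },

and the normalised coordinate is θ = red / (green + red). The three
genotype classes at the segregating target locus (off-target copies
monomorphic) map to at most three distinct (green, red) points: one
bound copy gives the classic three-cluster simple SNP; multiple copies
give hemi layouts with one or two heterozygous-position clusters. A
declaration is *color-ambiguous* when a same-color substitution (A↔T,
C↔G) of a declared allele reproduces the identical layout.

Primer placement works on a star multiple alignment of the probe context
and all hit regions: allele-specific primers end 3' exactly on the SNP;
the common primer is chosen on the opposite strand inside the amplicon
bounds, excluded from indel and intron-classified columns, and ranked by
off-target mismatches weighted 4/2/1 for the 3'-terminal base, positions
2–5, and the remainder. An assay is *locus-specific* when the common
primer has ≥ 1 mismatch within its 3'-terminal 5 bases against every
off-target copy (or no alignable site there).

## Worked example

`examples/04_design_assay.py` simulates a hexaploid locus (three
homeologous copies, 5% divergence, off-target states T/T and G/G),
decodes the probe and designs an assay:

```
specificity class: locus_specific
allele A primer (tailed): GAAGGTGACCAAGTTCATGCTTGGCCTGAAGTTATGTTAATTGA
allele B primer (tailed): GAAGGTCGGAGTCAACGGATTTGGCCTGAAGTTATGTTAATTGG
common primer:           CTGTCTGGTTATGGGTGCC
Tm: A 56.9  B 58.0  common 59.7 degC
amplicon length: 76 bp
feasible amplicons anywhere in the assembly: 1
```

The two allele-specific primers differ only in their 3'-terminal base
(the SNP) and carry the two fluorophore tails; the exhaustive audit finds
exactly one feasible amplicon in the whole assembly, i.e. the assay
amplifies the target locus only.

`examples/06_correct_haplotypes.py` runs the Null correction on the
published wheat root-biomass haploblock tables (215 accessions):

```
Hap-5B-RDMa: 7 haplotypes -> 2 after correction
  h1: GCAGGGCAG 91.6% (absorbed h3, h4, h5, h6, h7)
  h2: ATGAAATCT 8.4%
Hap-5B-RDMb: 9 haplotypes -> 4 after correction
  h1: GAGATG 79.5% (absorbed h4, h7, h9)
  h2: AGTGCG 14.4% (absorbed h5)
  h3: GGTGCT 5.6% (absorbed h6)
  h8: GAGGCT 0.5%
```

Eleven haplotypes sit below 5% frequency; ten contain a Null call and
merge into a major haplotype; only the Null-free `h8` survives as a
genuine rare haplotype.

The other examples cover strand decoding (`01`), homeolog mapping
(`02`), cluster-layout prediction and the triallelic ambiguity (`03`),
and genotype calling with artificial heterozygote mixtures (`05`). A
thin CLI mirrors the library:
`polykasp decode|map|classify|design|call|correct-haplotypes|simulate`.

## Layout

```
src/polykasp/     probes, align, mapping, clusters, primers, qc,
                  simulate, datasets, pipeline, cli
examples/         one short narrative script per capability
tests/            pytest suite incl. independent brute-force oracles
docs/methods.md   model assumptions, parameters, numerical choices
```
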