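# Methods

`beemas` implements a single-gene marker-assisted selection (MAS) workflow
for honey bees around the Vitellogenin (*Vg*) gene: catalogue the protein
variants segregating in a breeding stock from long amplicon consensus
sequences, find a short exon region whose SNP combination uniquely tags the
desired allele, screen queens and drones against that tag with cheap
Sanger-style sequencing, and simulate the haplodiploid breeding scheme that
drives the allele to homozygosity. This note records the models, the
parameter choices, and what the synthetic data do and do not establish.

## Coordinate and data model

All internal coordinates are 1-based inclusive gene coordinates on the
coding strand, matching p.S1110T-style protein numbering; conversion to
VCF (1-based) is the identity and conversion to BED (0-based half-open)
happens only at export. A `GeneModel` is the reference sequence plus exon
intervals and CDS bounds; its validator enforces non-overlapping sorted
exons, a spliced CDS divisible by three that begins with ATG and ends at a
stop codon. A SNP is a substitution relative to the reference, annotated
with its exon, synonymy (decided by translating the mutated codon), and —
for nonsynonymous coding changes — the amino-acid change. A *protein
variant* is an equivalence class of haplotypes keyed on the set of
nonsynonymous SNPs; synonymous SNPs stay on the haplotype but do not define
the variant. The reference (empty nsSNP set) is always variant 1.

## Synthetic data generator

The generator is first-class, tested code: every downstream stage is
exercised on data whose truth is known exactly.

**Gene.** `vitellogenin_like_model` builds a 6109-bp, 7-exon gene with a
5310-bp spliced CDS (1769 residues + stop), the scale of honey bee *Vg*.
The random background is constrained to contain no internal in-frame stop
codon. Three screening primer pairs are planted so in-silico PCR yields
620-, 542- and 400-bp products from exons 2, 4 and 5, with codon-phase
placement chosen so that no planted segment introduces a stop codon, and
any spurious occurrence of a primer elsewhere in the random background is
mutated away. Codon 1110 is fixed to TCA (serine) so a single first-base
T>A change produces p.S1110T.

**Pol-line pool.** `polline_pool` is a synthetic stand-in for the breeding
-stock allele survey (whose per-sample tables are not redistributable). It
reproduces the survey's structure: 26 variants built from 34 nsSNPs plus 3
synonymous SNPs; exon 2 carries 9 polymorphic sites forming 7 haplotypes of
which haplotype 1 (all reference alleles) is private to variant 1; exon 4
carries 6 sites forming 3 haplotypes, with the lipid-cavity variant 15
(p.S1110T plus seven other nsSNPs) sharing its exon-4 haplotype with the
rare variant 7, which matches variant 15 base-for-base across exon 4 but
differs in exon 6 and occurs only in colony P7. Every non-reference variant
carries a non-reference exon-2 haplotype, which is what makes exon 2 — and
no other exon — a perfect tag for the reference allele, as in the study
system.

**Population.** The default sample sheet has 416 drone samples (the size of
the screening effort): 161 clean Pol-line drones over 25 colonies (20
reference, 48 variant 15 spread over 16 colonies, 2 variant 7 in P7), 85
and 84 clean drones in two sister stocks where the reference is rare (3 and
1 carriers), and 86 two-haplotype "mixed" samples that the single-haplotype
consensus rule must reject, leaving 330. Per-colony variant frequencies
outside these structural facts are free parameters of the scenario; the
generic `make_allele_pool`/`sample_population` path draws them uniformly
with a configurable target-variant frequency (default 0.3, in the range of
the reference-allele incidences the study reports for its screening
colonies).

**Noise.** Reads are substitution-corrupted copies of the full-gene
haplotype (default 2% per base, 20 reads per sample). Indels, quality
scores and chromatograms are not modelled: the unit of analysis is the
base-called consensus, not raw signal. Sanger base calls of diploids are
modelled as clean double peaks: two-base IUPAC codes exactly at
heterozygous positions.

## Variant catalogue

`enforce_single_haplotype` accepts a read stack only if it supports one
haplotype. Candidate split sites are positions where the minor base reaches
30 % of reads (default 20 reads, so ≥ 6; the chance that independent 2 %
substitution errors produce such a site anywhere in a 6.1-kb stack is
≈ 10⁻⁸ per sample, while a second haplotype produces ≈ 50 % minor support);
reads are clustered by their allele pattern at those sites and the sample
is rejected if the minority clusters exceed `max_minor_fraction` (default
0: *only one type of read per sample*). Mapping uses a positional fast path
for equal-length, high-identity consensus and otherwise a deterministic
global pairwise alignment (match +2, mismatch −1, gap open −5, extend −1);
identity is measured over alignment columns and samples below 70 % are
rejected as unmappable. Samples with a gap inside the CDS are excluded and
reported, not repaired — the catalogue analyses substitution variants only.
Ambiguity codes in a haploid drone are flagged as unexpected
heterozygosity. An independent aligner (MAFFT) is used in the test suite to
cross-check mismatch columns; it is never part of the implementation.

## Signature discovery

A signature is an exon region plus the target allele's bases at every
polymorphic site in it. Candidate regions are single exons — one Sanger
amplicon each — represented by the span of their polymorphic sites among
the discovery records; sites with missing or ambiguous data are
disqualified. A region is feasible for a target when the target's records
are allele-consistent across it and, after excluding the colonies that
harbour any non-target record matching the target's pattern, at least one
target record remains. Among feasible regions the search minimizes, in
order: excluded colonies, number of sites, window length, window start.

Two deliberate choices here. First, the signature keeps *all* polymorphic
sites in the window rather than a minimal discriminating subset: the
amplicon is sequenced in full anyway, the redundancy guards against
single-site dropouts, and it is how the field reports such tags (the study
counts 9 exon-2 and 6 exon-4 signature SNPs, which are window totals — a
minimal subset over 2–6 non-target haplotypes would never need more sites
than haplotypes). `minimize_sites=True` performs the exhaustive subset
search instead and is verified against brute force. Second, colony
exclusion is preferred to window enlargement when a confounder is private
to few colonies: the trade-off order above encodes that preference
explicitly and deterministically. Both synonymous and nonsynonymous SNPs
are usable as signature sites.

The signature also records the alleles each site showed in the discovery
population, which lets the screening stage distinguish "known non-target
allele" from "base never seen here" (the latter fails the sample).

## Screening

`in_silico_pcr` does exact matching of the primer pair in both
orientations; zero products raise "no product", more than one raise
"non-specific primers". The study validated specificity on a gel, so no
mismatch tolerance is modelled. The genotype caller decodes the four bases
and the six two-base IUPAC codes (three/four-base codes and N fail the
site) and calls: `hom_target` when every site shows exactly the target
base; `het_target` (diploids) when every site contains the target and at
least one site is heterozygous; `hom_other` when some site excludes the
target — no chromosome can then carry the tag; `fail` for unreadable or
unexpected bases, uncovered sites, or apparent heterozygosity in a haploid.
Diploid calls are per-site and unphased: two complementary non-target
haplotypes can mimic a heterozygous carrier, which is precisely why the
breeding scheme confirms queens through their haploid drone sons.

## Breeding simulator

Haplodiploid Mendelian inheritance with unlinked loci: a drone receives one
maternal allele per locus, a daughter one random maternal allele plus the
paternal allele. Generations are discrete and non-overlapping; calendar
time is not modelled. The per-generation gates follow the field scheme:
founder queens are genotyped through nine drone sons (a heterozygote is
detected with probability 1 − 2⁻⁹ ≈ 0.998); daughters are grafted from
carrier queens — from homozygous queens as soon as any exist, as in the
final field generations, which also makes the target-allele frequency
non-decreasing in every realization (without that gate, binomial sampling
can transiently dip the frequency even under selection); virgin daughters
are screened and non-carriers culled; each queen is inseminated with a
single drone that is genotyped post hoc, and queens mated to non-carriers
are culled. Defaults: 20 founder queens (heterozygous), 100 grafts and 100
screened daughters per generation, 4 generations, no attrition
(`colony_survival=1`, the study's pesticide loss being an optional
survival probability).

Inbreeding is tracked at the single-locus complementary sex determiner:
queens carry two distinct csd alleles (default 16, equifrequent), and
fertilized brood homozygous at csd is removed as inviable diploid males.
Under random single-drone mating with k equifrequent alleles the expected
diploid-male brood fraction is 2/k · 1/2 = 1/k; the Monte-Carlo mode
agrees within sampling error. The multilocus extension treats loci as
independently segregating, so the diploid genotype space grows as 3ᵏ and
fixation takes at least as many generations as the single-locus scheme.

## Numerical and degenerate-input choices

Randomness always flows through explicit integer seeds (`numpy`
`default_rng`); there is no global random state, and identical
(config, seed) pairs reproduce every artifact byte for byte. Ties in the
signature search break deterministically (exon order, then leftmost
window). A pool of one variant is the reference alone; an empty screening
cohort yields empty tables; a breeding run whose carrier pool empties
raises a lineage-extinction error carrying the trajectory so far.
Provenance blocks embed a SHA-256 of the configuration and the seed, never
timestamps.

## What the synthetic data do not show

The generator reproduces the *structure* of the study system, not its
field realities: no raw-signal error model, no recombination within the
gene (the study flags recombination as a long-term risk to signatures), no
colony-level attrition by default, no phenotypes. Passing tests therefore
demonstrate that the algorithms are correct under their stated assumptions
— single-haplotype amplicons, substitution-only variation, clean Sanger
double peaks, unlinked loci — not that the workflow is robust to every
failure mode of real sequencing. Field-scale outcomes that depend on
attrition (e.g., how many homozygous colonies survive to the final
generation) are outside what the simulator claims; it reports genotype
composition per generation under the configured survival probability.
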