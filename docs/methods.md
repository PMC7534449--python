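# Methods

`sdrmap` locates a male-determining region (SDR) on an XY chromosome pair
that still recombines over most of its length, the situation in the guppy
(*Poecilia reticulata*) LG12 and relatives: a physically small terminal
pseudoautosomal region (PAR) crosses over at a very high rate in male
meiosis, crossovers elsewhere on the pair are rare in males (while females
recombine freely in the proximal region), and progeny sex is determined by
the paternal chromosome carried at the SDR. Because the non-PAR region
almost never recombines in sires, population samples show only partial
associations between variants and sex, and the decisive information comes
from rare recombinant progeny in pedigrees.

## Between-sex F_ST

For one polymorphic site genotyped in `n_m` males and `n_f` females the
package computes

    F_ST = 1 − H_w / H_b

with pair-counting heterozygosities, pairs drawn **without replacement**:

* within one sex with allele counts `c_a` over `T = 2n` alleles,
  `H = 1 − Σ_a c_a (c_a − 1) / (T (T − 1))`;
* `H_w` = unweighted mean of the two within-sex values (the sexes count
  equally regardless of sample size);
* `H_b` = the same quantity over the pooled two-sex allele sample.

For the idealized fully sex-linked configuration (every male heterozygous
X^A Y^B, every female A/A) this is a deterministic function of the sample
sizes: 59/153 ≈ 0.386 at (14 males, 10 females), rising to exactly 1/3 as
both samples grow — the classical "about one-third" expectation for a
fully sex-linked SNP. Properties worth knowing:

* under the null (identical allele frequencies in the sexes) the estimator
  is unbiased up to a small ratio term; across 500 simulated null sites the
  mean is within one standard error of zero;
* negative values are legitimate small-sample outcomes and are reported as
  computed, never clamped. In particular, *identical* genotype counts in
  both sexes give a small negative value (e.g. −1/(8k−2) for k A/A + k G/G
  per sex), because the without-replacement within-sex estimate sits
  slightly above the pooled one at finite n; a plug-in (with-replacement)
  estimator would give exactly 0 there, but is upward-biased under the
  null, which matters more for genome scans;
* monomorphic pooled sites are undefined and are skipped (and counted) by
  the scan.

Exact association tests (heterozygosity-by-sex, crossover-location
contrast) are two-sided Fisher exact tests under the minimum-likelihood
rule: the p-value sums all tables whose point hypergeometric probability
does not exceed the observed table's. Counts from several populations are
pooled by summation before testing. Report percentages round half-up to
integers except rates below 1%, which keep two decimals.

## Sire phasing and the inheritance matrix

A marker is *informative* when the sire is heterozygous and the paternally
transmitted allele is identifiable given the dam: dam homozygous, or dam
alleles disjoint from the sire's. Each progeny then reveals which sire
haplotype it inherited; labelling the haplotypes X and Y turns the sibship
into an inheritance matrix of X/Y states (`U` where the call is missing or
Mendelian-inconsistent; violations are flagged, never silently dropped).

Orientation is decided by a **chain rule with a sex anchor**: the first
informative marker is oriented by majority vote over sexed progeny
(males → Y allele); each subsequent marker is oriented to keep the most
progeny on the same haplotype as the previous phased marker, because a
crossover between adjacent informative markers is the exception. The whole
assignment is finally flipped if overall sex agreement favours the mirror
labelling. The chain is what keeps markers deep in the PAR correctly
oriented — there the per-marker sex signal decays to a coin flip (the
recombination fraction with the SDR approaches 1/2) and independent
per-marker voting would scramble terminal states; with the chain, 458/458
simulated crossovers bracketed by informative markers are recovered at
zero genotype error. Exact chain ties fall back to the marker's own sex
vote; a double tie makes the marker `ambiguous` and it is excluded.

## Crossovers, recombinants, PAR boundary, SDR interval

Crossover detection is minimal-switch parsimony per progeny: uninformative
sites are skipped and every boundary between maximal same-state runs is a
crossover, reported as the closed flanking-marker position pair with the
number of supporting markers on each side. Interior single-marker runs
(one marker flanked by the opposite state on both sides) are segregated
into a discrepancy/genotyping-error channel rather than being called two
crossovers. The raw run-boundary count is provably the parsimony minimum
(verified against brute force in the tests).

The **PAR boundary** is the most distal marker showing zero sex/state
mismatches across the supplied sibships, after excluding progeny flagged
as whole-chromosome-scale recombinants; all distal markers (each with at
least one mismatch) are the operational PAR.

The **SDR interval** intersects recombinant constraints: a male's SDR
allele must lie inside his paternal-Y-derived segments, a female's outside
hers. Must-include Y segments contribute the closed span of their markers,
extended to the chromosome start / PAR boundary when terminal; must-exclude
segments remove only the span their markers certainly cover (crossover
positions between informative markers are unknown, so exclusion does not
reach into the flanking gaps). The result is capped distally by the PAR
boundary. With no recombinants the whole non-PAR region is returned; an
empty intersection raises (conflicting recombinants indicate genotyping
error). If the constraints leave several disjoint components, the one
adjacent to the PAR boundary is reported — the model places the SDR just
proximal to the PAR — and the rest are kept as `other_components`.

The genome-wide male non-PAR recombination rate is the share of sexed
progeny carrying a sire crossover entirely proximal to the PAR boundary,
with a Clopper–Pearson 95% interval.

The PAR genetic map pools pairwise sire-meiosis recombination fractions
across families (per-pair minor fraction, since per-marker labels may be
mirrored between families), orders markers to minimize summed adjacent
fractions — exhaustively for ≤ 8 markers, greedy insertion plus 2-opt
above — and reports cumulative fractions × 100 as cM without a mapping
function (distances are small and order is the object of interest).

## Assembly-discrepancy classification

A recombinant progeny is an assembly probe: fitting a one-crossover model
to its informative state sequence (the cut minimizing mismatches, smallest
cut on ties), any contiguous mismatch run flanked on both sides by ≥ 3
consecutive model-consistent markers is a candidate discrepancy —
`misplaced_proximal` when it segregates with the proximal block while
assembled distal, `misplaced_distal` for the converse. Conflicts without
such flanking are reported as potential genotyping errors.

A single progeny's fit can be ambiguous when its crossover lands near a
displaced block (parsimony may prefer flagging one true marker over five
displaced ones), so candidates are resolved **iteratively**: accept the
best-supported run (most flagging progeny, then longest), mask its
markers, re-fit all progeny, repeat. This is the same mask-and-reassess
reasoning one applies reading such a matrix by eye; artifact candidates
disappear once the true displaced run is masked. On simulated data with a
5-marker block displaced by ~21 Mb the classifier recovers exactly the
displaced run with the correct class in 99/100 replicates and flags
nothing in 100/100 clean replicates. An optional cross-check records which
positional block a flagged run travels with in dam-meiosis segregation.

## Y-duplication signature

If the Y carries an extra copy of a locus (sire X^A / Y^G Y^A), every male
progeny types heterozygous regardless of the Y haplotype inherited, while
females still segregate by the dam. The detector computes the multinomial
point probability of the observed male genotype counts under single-locus
Mendelian transmission from the observed parental genotypes and flags a
marker when (i) that null probability is below α = 0.001, (ii) every
called male is heterozygous (the classes impossible under the duplication
must be empty), and (iii) female counts fit dam-allele transmission
(two-sided binomial test not rejected at 0.05, no unexpected classes).
25/25 heterozygous males under a het × het null give 0.5²⁵ ≈ 3×10⁻⁸.
Sibships with fewer than 5 called males are reported underpowered and
never flagged. The measured null false-positive rate over 1000 simulated
25-male sibships is 0 (the all-het gate alone has null probability
~3×10⁻⁸).

## Forward simulator

`synthetic_data.SimulationConfig` defaults encode the study conditions of
the motivating system, chosen once:

| parameter | default | meaning |
|---|---|---|
| `chrom_length_bp` | 26,440,000 | assembly length of the XY pair |
| `par_start_bp` | 26,000,000 | PAR boundary (≈ the mapped ~26 Mb) |
| `sdr_pos_bp` | 25,700,000 | SDR just proximal to the PAR boundary |
| `male_par_crossover_prob` | 0.5 | one obligate PAR chiasma → half of gametes recombinant |
| `male_nonpar_crossover_prob` | 0.0028 | calibrated to 2/721 observed non-PAR recombinants |
| `female_crossover_rate` | 0.5 | per meiotic product |
| `female_region_fraction` | 4/6 | female crossovers confined to the proximal four-sixths |
| `n_pop_males`, `n_pop_females` | 14, 10 | typical population sample |
| `n_families`, `progeny_per_family` | 11, 66 | pedigree scale |

Crossovers per region are Bernoulli 0/1 per meiosis rather than Poisson,
matching cytological counts of a single crossover per chromosome on
average (`crossover_model="poisson"` is available). Progeny sex is
strictly the paternal SDR chromosome; sex-reversed individuals are not
modelled as biology (they are very rare in this system) but label noise is
available via `sex_error_rate`. Genotype errors are i.i.d. replacements
recorded in the truth record. A configured duplication makes every
Y-carrier type heterozygous at that marker; configured misassembly
permutes *reported* marker positions while the truth keeps real ones.

What the generator does **not** emulate: linkage disequilibrium and
coalescent structure within populations (population sites are independent
draws from X/Y frequency vectors), crossover interference beyond the 0/1
rule, mutation, multi-generation pedigrees, and segregating inversions.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated generative model, not robustness to every feature of real
data.

### Experiment designs used in the tests

Problem sizes were chosen as the smallest that make the binomial success
criteria meaningful. Recovery experiments (crossover recovery, misassembly
recovery) use fully informative founders (X fixed A / Y fixed G, so the
sire is heterozygous and the dam homozygous at every marker, as for the
real informative marker sets) and an elevated male non-PAR crossover
probability of 0.3 with 30 progeny — at the field rate of 0.0028 a single
family almost never contains the recombinant these diagnostics feed on.
SDR-interval recovery runs 200 replicates of 20-progeny sibships at
default (field) rates with the SDR position randomized across the
marker-covered non-PAR region; the interval contains the truth in ≥ 95%
of runs, the misses being confined to breakpoints falling in the same
inter-marker gap as the SDR. The duplication null uses 1000 sibships of
25 males + 17 females from a het × het cross.

## Numerical and degenerate-input conventions

* Coordinates are 1-based inclusive; intervals are closed flanking-marker
  position pairs; nothing is interpolated between markers.
* Missing genotypes are first-class and excluded marker-wise from every
  statistic.
* Microsatellite alleles are fragment-length strings; equality is string
  equality.
* Ties: phase chain ties → sex vote → ambiguous; RBH best-hit ties break
  by (score desc, target id asc); PAR map orders are canonical up to
  mirror image (the lexicographically smaller endpoint comes first);
  discrepancy acceptance breaks ties by support, then run length, then
  marker ids.
* Degenerate inputs raise early with specific messages: empty Fisher
  tables, monomorphic sites, sibships with < 2 sexed progeny, zero
  progeny for the recombination rate, < 2 PAR markers for the map.
* GC windows are half-open tilings; ambiguity codes leave the denominator;
  `Σ gc·n` always equals the global G+C count.

## Known limitations

* The SDR interval reports marker-flank bounds; the true crossover may sit
  anywhere in the flanking gaps, so the printed bounds are the innermost
  certain markers, not outer confidence limits.
* Sex-anchored phasing requires some fully sex-linked markers in the
  sibship; a hypothetical family segregating only PAR markers would phase
  (via the chain) but the X/Y labels would be arbitrary.
* The discrepancy classifier assumes one crossover per recombinant per
  chromosome unless the data force more; densely recombinant chromosomes
  (as in female meiosis) should be analysed per arm or with the dam-meiosis
  corroboration channel.
* `expected_sexlinked_fst` is estimator-specific; other common estimators
  give values between ~0.29 and ~0.48 for the same configuration, so
  cross-study comparisons must fix the estimator first.
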