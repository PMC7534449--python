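"""Population-sample stage: between-sex F_ST, exact tests, allele screens.

Between-sex F_ST
----------------
For a polymorphic site genotyped in n_m males and n_f females we estimate

    F_ST = 1 - H_w / H_b

where every heterozygosity is a *pair-counting* quantity, with pairs drawn
without replacement:

* within a sex with allele counts c_a over T = 2n alleles,
  H = 1 - sum_a c_a (c_a - 1) / (T (T - 1));
* H_w is the unweighted mean of the two within-sex values (the sexes are
  weighted equally regardless of sample size);
* H_b is the same pair-counting diversity computed over the pooled two-sex
  allele sample.

For the idealized fully sex-linked configuration — every male heterozygous
X^A Y^B, every female A/A — this gives 1/3 in the large-sample limit and
about 0.33-0.39 at realistic sample sizes, matching the classical
expectation for a fully sex-linked SNP.  Under the null (identical allele
frequencies in both sexes) the estimator is unbiased up to a small ratio
term; negative values are reported as computed, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_formats import (
    FormatError,
    Genotype,
    GenotypeTable,
    Marker,
    PopulationSample,
    format_percent,
    logger,
)

__all__ = [
    "SiteFst",
    "AssociationResult",
    "AlleleSummary",
    "MaleAlleleCall",
    "TargetCandidate",
    "MonomorphicSiteError",
    "hudson_fst",
    "expected_sexlinked_fst",
    "fst_scan",
    "het_by_sex_test",
    "crossover_location_test",
    "allele_summary",
    "male_specific_allele_screen",
    "select_target_snps",
]


class MonomorphicSiteError(ValueError):
    """The pooled sample carries a single allele; F_ST is undefined."""


@dataclass
class SiteFst:
    marker: Marker
    fst: float
    n_m: int
    n_f: int
    h_within: float
    h_between: float


@dataclass
class AssociationResult:
    marker: Optional[Marker]
    table: tuple  # ((r1c1, r1c2), (r2c1, r2c2))
    p_value: float
    test: str  # "het_by_sex" | "crossover_location"
    pct_het_males: Optional[str] = None
    male_variant_freq: Optional[str] = None


def _allele_counts(calls: Iterable[Genotype]) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for g in calls:
        if g.is_missing:
            continue
        for a in g.alleles:
            counts[a] = counts.get(a, 0) + 1
    return counts


def _pair_diversity(counts: Dict[str, int]) -> float:
    """Probability two alleles drawn without replacement differ."""
    total = sum(counts.values())
    if total < 2:
        raise ValueError("need at least 2 alleles for pair diversity")
    same = sum(c * (c - 1) for c in counts.values())
    return 1.0 - same / (total * (total - 1))


def hudson_fst(male_calls: Sequence[Genotype], female_calls: Sequence[Genotype],
               marker: Optional[Marker] = None) -> SiteFst:
    """Between-sex F_ST at one site (see module docstring for the estimator).

    Raises :class:`MonomorphicSiteError` when the pooled site carries one
    allele, and ``ValueError`` when either sex has no called individual.
    """
    males = [g for g in male_calls if not g.is_missing]
    females = [g for g in female_calls if not g.is_missing]
    n_m, n_f = len(males), len(females)
    if n_m < 1 or n_f < 1:
        raise ValueError(f"need >=1 called individual per sex (got {n_m} males, {n_f} females)")
    cm, cf = _allele_counts(males), _allele_counts(females)
    pooled = dict(cm)
    for a, c in cf.items():
        pooled[a] = pooled.get(a, 0) + c
    if len(pooled) < 2:
        raise MonomorphicSiteError(
            f"site {(marker.id if marker else '?')} is monomorphic in the pooled sample"
        )
    h_w = 0.5 * (_pair_diversity(cm) + _pair_diversity(cf))
    h_b = _pair_diversity(pooled)
    return SiteFst(marker=marker, fst=1.0 - h_w / h_b, n_m=n_m, n_f=n_f,
                   h_within=h_w, h_between=h_b)


def expected_sexlinked_fst(n_m: int, n_f: int) -> float:
    """F_ST expected for a fully sex-linked SNP at the given sample sizes.

    Every male is heterozygous X^A Y^B and every female is A/A; the value is
    ``hudson_fst`` applied to that configuration, a deterministic function
    of (n_m, n_f).  Tends to exactly 1/3 as both samples grow.
    """
    if n_m < 1 or n_f < 1:
        raise ValueError("need at least one individual of each sex")
    males = [Genotype.of("A", "B")] * n_m
    females = [Genotype.of("A", "A")] * n_f
    return hudson_fst(males, females).fst


def fst_scan(sample: PopulationSample) -> List[SiteFst]:
    """Per-site between-sex F_ST over a sexed population sample.

    One :class:`SiteFst` per polymorphic site, ordered by position;
    monomorphic sites and sites with a sex entirely missing are skipped
    (counts logged).
    """
    table = sample.table
    male_ids = [i.id for i in table.individuals_with_sex("male")]
    female_ids = [i.id for i in table.individuals_with_sex("female")]
    out: List[SiteFst] = []
    n_mono = n_skipped = 0
    for m in table.markers:
        col = table.calls_at(m.id)
        by_id = {ind.id: g for ind, g in zip(table.individuals, col)}
        males = [by_id[i] for i in male_ids]
        females = [by_id[i] for i in female_ids]
        try:
            out.append(hudson_fst(males, females, m))
        except MonomorphicSiteError:
            n_mono += 1
        except ValueError:
            n_skipped += 1
    if n_mono or n_skipped:
        logger.info("fst_scan %s: %d monomorphic sites skipped, %d with a sex uncalled",
                    sample.population_id, n_mono, n_skipped)
    if not out:
        logger.warning("fst_scan %s: no polymorphic sites", sample.population_id)
    return out


# ---------------------------------------------------------------------------
# exact association tests
# ---------------------------------------------------------------------------

def _fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p: sum of tables with point hypergeometric
    probability <= that of the observed table (minimum-likelihood rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def het_by_sex_test(tables, marker: Optional[Marker] = None) -> AssociationResult:
    """Pooled test that males are heterozygous more often than females.

    ``tables`` is an iterable of per-population 2x2 counts
    ``((male_het, male_hom), (female_het, female_hom))``; populations are
    pooled by summation, then a two-sided Fisher exact test is applied.
    Also reports the heterozygous-male percentage and the variant allele
    frequency among males (each het male carries one copy).
    """
    pooled = np.zeros((2, 2), dtype=int)
    n_tables = 0
    for t in tables:
        pooled += np.asarray(t, dtype=int)
        n_tables += 1
    if n_tables == 0 or pooled.sum() == 0:
        raise ValueError("no counts supplied")
    m_het, m_hom = int(pooled[0, 0]), int(pooled[0, 1])
    n_males = m_het + m_hom
    p = _fisher_two_sided(pooled)
    return AssociationResult(
        marker=marker,
        table=tuple(map(tuple, pooled.tolist())),
        p_value=p,
        test="het_by_sex",
        pct_het_males=format_percent(m_het / n_males) if n_males else None,
        male_variant_freq=format_percent(m_het / (2 * n_males)) if n_males else None,
    )


def crossover_location_test(table) -> AssociationResult:
    """Two-sided Fisher exact test on a sex x (terminal, proximal) crossover
    count table, e.g. males (12 terminal, 1 proximal) vs females (0, 15)."""
    p = _fisher_two_sided(table)
    t = np.asarray(table, dtype=int)
    return AssociationResult(marker=None, table=tuple(map(tuple, t.tolist())),
                             p_value=p, test="crossover_location")


# ---------------------------------------------------------------------------
# microsatellite allele summaries and male-specific screens
# ---------------------------------------------------------------------------

@dataclass
class AlleleSummary:
    marker: Marker
    counts: dict  # (allele, population_id, sex) -> allele count
    male_hom_counts: dict  # allele -> number of males homozygous for it (pooled)
    n_alleles_total: int
    n_alleles_shared: int  # alleles present in >= 2 populations


@dataclass
class MaleAlleleCall:
    marker: Marker
    allele: str
    n_male_copies: int
    n_female_copies: int
    male_only: bool
    male_only_refuted_by_homozygote: bool
    singleton: bool


def allele_summary(tables_by_population: dict, marker_id: str) -> AlleleSummary:
    """Per-population per-sex allele counts for one microsatellite marker.

    ``tables_by_population`` maps population id -> GenotypeTable.  Column
    sums equal twice the number of called individuals of that population
    and sex.  Raises for SNP markers (wrong marker kind).
    """
    marker = None
    counts: dict = {}
    male_hom: dict = {}
    pops_by_allele: dict = {}
    for pop_id in sorted(tables_by_population):
        table = tables_by_population[pop_id]
        m = table.marker(marker_id)
        if m.kind != "microsatellite":
            raise FormatError(f"allele_summary: marker {marker_id} is a {m.kind}, not a microsatellite")
        marker = m
        for ind, g in zip(table.individuals, table.calls_at(marker_id)):
            if g.is_missing or ind.sex not in ("male", "female"):
                continue
            for a in g.alleles:
                counts[(a, pop_id, ind.sex)] = counts.get((a, pop_id, ind.sex), 0) + 1
                pops_by_allele.setdefault(a, set()).add(pop_id)
            if ind.sex == "male" and g.is_hom:
                male_hom[g.alleles[0]] = male_hom.get(g.alleles[0], 0) + 1
    if marker is None:
        raise ValueError("no populations supplied")
    n_total = len(pops_by_allele)
    n_shared = sum(1 for pops in pops_by_allele.values() if len(pops) >= 2)
    return AlleleSummary(marker=marker, counts=counts, male_hom_counts=male_hom,
                         n_alleles_total=n_total, n_alleles_shared=n_shared)


def male_specific_allele_screen(summary: AlleleSummary) -> List[MaleAlleleCall]:
    """Screen a microsatellite allele summary for candidate Y-specific alleles.

    An allele is ``male_only`` when it is carried by at least one male and
    by no female, pooled over all populations.  A male homozygous for the
    allele refutes strict Y-linkage (a homozygote implies an X-borne copy).
    Singletons (one copy observed in total) are flagged.
    """
    alleles = sorted({a for (a, _, _) in summary.counts})
    out: List[MaleAlleleCall] = []
    for a in alleles:
        n_m = sum(c for (al, _, sex), c in summary.counts.items() if al == a and sex == "male")
        n_f = sum(c for (al, _, sex), c in summary.counts.items() if al == a and sex == "female")
        male_only = n_m >= 1 and n_f == 0
        refuted = male_only and summary.male_hom_counts.get(a, 0) > 0
        out.append(MaleAlleleCall(marker=summary.marker, allele=a,
                                  n_male_copies=n_m, n_female_copies=n_f,
                                  male_only=male_only,
                                  male_only_refuted_by_homozygote=refuted,
                                  singleton=(n_m + n_f) == 1))
    return out


# ---------------------------------------------------------------------------
# SNP target selection for assay design
# ---------------------------------------------------------------------------

@dataclass
class TargetCandidate:
    """A candidate SNP for targeted genotyping, with design annotation."""

    marker: Marker
    coding: bool
    flank_coding_left_bp: Optional[int]
    flank_coding_right_bp: Optional[int]
    freq_males: Optional[float]
    freq_females: Optional[float]


def select_target_snps(candidates: Sequence[TargetCandidate],
                       min_flank_bp: int = 50) -> List[TargetCandidate]:
    """Filter candidate SNPs for a targeted genotyping panel.

    Keeps candidates that (i) lie in coding sequence, (ii) have at least
    ``min_flank_bp`` of coding sequence flanking on *both* sides, and
    (iii) do not have allele frequency exactly 0.5 in both sexes
    simultaneously (a repetitive-sequence signature).  Candidates with
    missing annotation are excluded with the reason logged.
    """
    kept: List[TargetCandidate] = []
    for c in candidates:
        if c.coding is None or c.flank_coding_left_bp is None or c.flank_coding_right_bp is None \
                or c.freq_males is None or c.freq_females is None:
            logger.info("select_target_snps: %s excluded (missing annotation)", c.marker.id)
            continue
        if not c.coding:
            logger.info("select_target_snps: %s excluded (non-coding)", c.marker.id)
            continue
        if c.flank_coding_left_bp < min_flank_bp or c.flank_coding_right_bp < min_flank_bp:
            logger.info("select_target_snps: %s excluded (coding flank < %d bp)", c.marker.id, min_flank_bp)
            continue
        if c.freq_males == 0.5 and c.freq_females == 0.5:
            logger.info("select_target_snps: %s excluded (0.5/0.5 frequency)", c.marker.id)
            continue
        kept.append(c)
    return kept
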