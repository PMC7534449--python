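"""Forward simulator and printed-table fixtures for the XY mapping pipeline.

The generative model mirrors the mapping system the pipeline targets: an
acrocentric XY pair whose terminal pseudoautosomal region (PAR) crosses
over at a very high rate in male meiosis, a male-determining locus (SDR)
just proximal to the PAR boundary, extremely rare male crossovers elsewhere,
and female crossovers concentrated in the centromere-proximal region.
Progeny sex is strictly determined by the paternal chromosome carried at
the SDR position (XX males / XY females are not modelled as biology; label
noise is available through ``sex_error_rate``).

Crossovers per region default to Bernoulli 0/1 per meiosis rather than
Poisson — cytological counts in this system show a single crossover per
chromosome on average — with a Poisson option in the config.

``make_study_fixtures`` builds, deterministically and without any seed, the
small data sets transcribed from the printed tables of the motivating
study (population genotype counts, the recombinant-male sibship, the
duplication-signature family, the eleven-family progeny skeleton, and the
PAR-boundary family structures), so that every desk-scale analysis is
reproducible from the package alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import Genotype, GenotypeTable, Individual, Marker, MISSING, PopulationSample
from .family_mapping import FamilyMeioses, RecombinantConstraint, Sibship

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "FamilySimulation",
    "PopulationSimulation",
    "FixtureBundle",
    "simulate_family",
    "simulate_population",
    "make_study_fixtures",
    "default_marker_positions",
]


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

def default_marker_positions(chrom_length_bp: int = 26_440_000,
                             par_start_bp: int = 26_000_000,
                             n_nonpar: int = 90, n_par: int = 10) -> List[int]:
    """Evenly spread marker positions: ``n_nonpar`` proximal to the PAR
    boundary and ``n_par`` inside the PAR."""
    nonpar = np.linspace(400_000, par_start_bp - 100_000, n_nonpar)
    par = np.linspace(par_start_bp + 10_000, chrom_length_bp - 10_000, n_par)
    return [int(p) for p in np.concatenate([nonpar, par])]


@dataclass
class SimulationConfig:
    """Generative parameters for one simulated family or population sample.

    Defaults encode the study conditions of the motivating system: a
    26.44 Mb chromosome, PAR boundary near 26 Mb, SDR at 25.7 Mb (just
    proximal to the PAR boundary), one obligate male chiasma in the PAR
    (gamete recombination probability 0.5), male non-PAR crossovers at
    0.28% of meiotic products, and female crossovers (rate 0.5 per meiotic
    product) placed uniformly in the proximal four-sixths of the
    chromosome.
    """

    chrom_length_bp: int = 26_440_000
    par_start_bp: int = 26_000_000
    sdr_pos_bp: int = 25_700_000
    marker_positions: Optional[List[int]] = None
    marker_kinds: Optional[List[str]] = None
    male_par_crossover_prob: float = 0.5
    male_nonpar_crossover_prob: float = 0.0028
    female_crossover_rate: float = 0.5
    female_region_fraction: float = 4.0 / 6.0  # proximal share receiving female crossovers
    crossover_model: str = "bernoulli"  # or "poisson"
    x_allele_freqs: Optional[List[Dict[str, float]]] = None
    y_allele_freqs: Optional[List[Dict[str, float]]] = None
    duplication: Optional[Tuple[str, str]] = None  # (marker id, Y-borne extra allele)
    misassembly: Optional[Dict[str, int]] = None  # marker id -> displaced reported pos
    genotype_error_rate: float = 0.0
    sex_error_rate: float = 0.0
    n_families: int = 11
    progeny_per_family: int = 66
    n_pop_males: int = 14
    n_pop_females: int = 10
    chrom: str = "LG12"

    def __post_init__(self):
        if not (self.sdr_pos_bp < self.par_start_bp <= self.chrom_length_bp):
            raise ValueError("require sdr_pos_bp < par_start_bp <= chrom_length_bp "
                             "(the SDR must be proximal to the PAR)")
        for p in (self.male_par_crossover_prob, self.male_nonpar_crossover_prob,
                  self.genotype_error_rate, self.sex_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.crossover_model not in ("bernoulli", "poisson"):
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")

    def positions(self) -> List[int]:
        if self.marker_positions is not None:
            return list(self.marker_positions)
        return default_marker_positions(self.chrom_length_bp, self.par_start_bp)

    def markers(self) -> List[Marker]:
        pos = self.positions()
        kinds = self.marker_kinds or ["snp"] * len(pos)
        out = []
        for i, (p, kind) in enumerate(zip(pos, kinds)):
            reported = p
            mid = f"M{i + 1:04d}"
            if self.misassembly and mid in self.misassembly:
                reported = self.misassembly[mid]
            alleles = frozenset("ACGT") if kind == "snp" else frozenset(
                str(a) for a in range(200, 300, 2))
            out.append(Marker(id=mid, chrom=self.chrom, pos_bp=reported, kind=kind,
                              alleles=alleles))
        return out


@dataclass
class TruthRecord:
    """Ground truth for one simulated family."""

    sdr_pos_bp: int
    true_positions: Dict[str, int]  # marker id -> true (pre-misassembly) position
    duplicated_markers: List[str]
    progeny_sex: Dict[str, str]
    paternal_crossovers: Dict[str, List[int]]  # progeny id -> crossover positions (sire meiosis)
    maternal_crossovers: Dict[str, List[int]]
    paternal_origin: Dict[str, Dict[str, str]]  # progeny id -> marker id -> "X"/"Y"
    sire_haplotypes: Dict[str, Tuple[str, str]]  # marker id -> (X allele, Y allele)
    perturbed_calls: List[Tuple[str, str]]  # (individual id, marker id) hit by the error injector


@dataclass
class FamilySimulation:
    sibship: Sibship
    truth: TruthRecord


@dataclass
class PopulationSimulation:
    sample: "PopulationSample"
    x_freqs: List[Dict[str, float]]
    y_freqs: List[Dict[str, float]]


def _default_freqs(rng: np.random.Generator, markers: Sequence[Marker],
                   sexlinked: bool = False) -> Tuple[List[Dict[str, float]], List[Dict[str, float]]]:
    """Biallelic founder frequencies; Y equals X (freely exchanging sites)
    unless ``sexlinked``, which fixes an X/Y difference at every site."""
    x_f, y_f = [], []
    for m in markers:
        if m.kind == "snp":
            a, b = rng.choice(sorted("ACGT"), size=2, replace=False)
        else:
            a, b = rng.choice(sorted(m.alleles), size=2, replace=False)
        if sexlinked:
            x_f.append({str(a): 1.0})
            y_f.append({str(b): 1.0})
        else:
            p = rng.uniform(0.2, 0.8)
            x_f.append({str(a): p, str(b): 1.0 - p})
            y_f.append({str(a): p, str(b): 1.0 - p})
    return x_f, y_f


def _draw_haplotype(rng: np.random.Generator, freqs: List[Dict[str, float]]) -> List[str]:
    hap = []
    for f in freqs:
        alleles = sorted(f)
        probs = np.array([f[a] for a in alleles])
        hap.append(str(rng.choice(alleles, p=probs / probs.sum())))
    return hap


def _crossover_positions(rng: np.random.Generator, prob: float, lo: int, hi: int,
                         model: str) -> List[int]:
    if hi <= lo:
        return []
    if model == "bernoulli":
        n = int(rng.random() < prob)
    else:
        n = int(rng.poisson(prob))
    return sorted(int(rng.integers(lo, hi)) for _ in range(n))


def _gamete(true_pos: List[int], hap0: List[str], hap1: List[str],
            crossovers: List[int], start_on_1: bool) -> Tuple[List[str], List[int]]:
    """Walk markers in true-position order, switching haplotype at each
    crossover; returns (allele list, origin list of 0/1)."""
    alleles, origin = [], []
    for j, p in enumerate(true_pos):
        n_before = sum(1 for c in crossovers if c < p)
        on_1 = (int(start_on_1) + n_before) % 2 == 1
        origin.append(1 if on_1 else 0)
        alleles.append(hap1[j] if on_1 else hap0[j])
    return alleles, origin


def simulate_family(config: SimulationConfig, seed: int,
                    family_id: str = "SIM1") -> FamilySimulation:
    """Simulate one full sibship with complete ground truth.

    The sire carries one X and one Y haplotype drawn from the configured
    founder frequencies; the dam carries two X haplotypes.  Each sire
    meiosis places 0/1 crossovers in the PAR and 0/1 in the non-PAR region
    (positions uniform within the region); dam meioses place crossovers in
    the proximal ``female_region_fraction`` of the chromosome.  Progeny sex
    is set by the paternal chromosome at the SDR.  Same seed + config give
    byte-identical output.
    """
    rng = np.random.default_rng(seed)
    markers = config.markers()
    n_mark = len(markers)
    true_pos_by_id = {f"M{i + 1:04d}": p for i, p in enumerate(config.positions())}
    true_pos = [true_pos_by_id[m.id] for m in markers]  # aligned with marker list

    x_freqs, y_freqs = config.x_allele_freqs, config.y_allele_freqs
    if x_freqs is None or y_freqs is None:
        dx, dy = _default_freqs(rng, markers)
        x_freqs = x_freqs or dx
        y_freqs = y_freqs or dy
    if len(x_freqs) != n_mark or len(y_freqs) != n_mark:
        raise ValueError("allele frequency vectors must match the number of markers")

    sire_x = _draw_haplotype(rng, x_freqs)
    sire_y = _draw_haplotype(rng, y_freqs)
    dam_x1 = _draw_haplotype(rng, x_freqs)
    dam_x2 = _draw_haplotype(rng, x_freqs)

    sire = Individual(id=f"{family_id}_sire", sex="male", family_id=family_id, role="sire")
    dam = Individual(id=f"{family_id}_dam", sex="female", family_id=family_id, role="dam")

    # order for the meiotic walk must follow *true* positions
    walk_order = sorted(range(n_mark), key=lambda i: true_pos[i])
    walk_pos = [true_pos[i] for i in walk_order]

    dup_marker, dup_allele = config.duplication if config.duplication else (None, None)
    fem_hi = int(config.chrom_length_bp * config.female_region_fraction)

    progeny: List[Individual] = []
    rows: List[List[Genotype]] = []
    truth = TruthRecord(
        sdr_pos_bp=config.sdr_pos_bp,
        true_positions=dict(true_pos_by_id),
        duplicated_markers=[dup_marker] if dup_marker else [],
        progeny_sex={}, paternal_crossovers={}, maternal_crossovers={},
        paternal_origin={}, perturbed_calls=[],
        sire_haplotypes={m.id: (sire_x[j], sire_y[j]) for j, m in enumerate(markers)},
    )

    for k in range(config.progeny_per_family):
        pid = f"{family_id}_p{k + 1:03d}"
        pat_xo = (_crossover_positions(rng, config.male_nonpar_crossover_prob, 1,
                                       config.par_start_bp, config.crossover_model)
                  + _crossover_positions(rng, config.male_par_crossover_prob,
                                         config.par_start_bp, config.chrom_length_bp,
                                         config.crossover_model))
        pat_xo.sort()
        pat_start_y = bool(rng.random() < 0.5)
        mat_xo = _crossover_positions(rng, config.female_crossover_rate, 1, fem_hi,
                                      config.crossover_model)
        mat_start_2 = bool(rng.random() < 0.5)

        pat_walk = [sire_x[i] for i in walk_order], [sire_y[i] for i in walk_order]
        pat_alleles_w, pat_origin_w = _gamete(walk_pos, pat_walk[0], pat_walk[1],
                                              pat_xo, pat_start_y)
        mat_walk = [dam_x1[i] for i in walk_order], [dam_x2[i] for i in walk_order]
        mat_alleles_w, _ = _gamete(walk_pos, mat_walk[0], mat_walk[1], mat_xo, mat_start_2)

        # back to marker-list order
        pat_alleles = [None] * n_mark
        pat_origin = [None] * n_mark
        mat_alleles = [None] * n_mark
        for w, i in enumerate(walk_order):
            pat_alleles[i] = pat_alleles_w[w]
            pat_origin[i] = pat_origin_w[w]
            mat_alleles[i] = mat_alleles_w[w]

        # sex from the paternal chromosome at the SDR position
        n_before = sum(1 for c in pat_xo if c < config.sdr_pos_bp)
        sdr_on_y = (int(pat_start_y) + n_before) % 2 == 1
        sex = "male" if sdr_on_y else "female"
        if config.sex_error_rate and rng.random() < config.sex_error_rate:
            sex = "female" if sex == "male" else "male"

        row = []
        for j, m in enumerate(markers):
            if m.id == dup_marker and pat_origin[j] == 1:
                # Y-carrier at the duplicated locus: assay sees the union of
                # the maternal allele and both Y-borne copies -> heterozygous
                seen = {mat_alleles[j], pat_alleles[j], dup_allele}
                seen.discard(None)
                pair = sorted(seen)
                g = Genotype.of(pair[0], pair[-1])
            else:
                g = Genotype.of(pat_alleles[j], mat_alleles[j])
            row.append(g)
        ind = Individual(id=pid, sex=sex, family_id=family_id, role="progeny")
        progeny.append(ind)
        rows.append(row)
        truth.progeny_sex[pid] = "male" if sdr_on_y else "female"
        truth.paternal_crossovers[pid] = pat_xo
        truth.maternal_crossovers[pid] = mat_xo
        truth.paternal_origin[pid] = {m.id: ("Y" if pat_origin[j] else "X")
                                      for j, m in enumerate(markers)}

    individuals = [sire, dam] + progeny
    calls = np.full((len(individuals), n_mark), MISSING, dtype=object)
    calls[0, :] = [Genotype.of(a, b) for a, b in zip(sire_x, sire_y)]
    calls[1, :] = [Genotype.of(a, b) for a, b in zip(dam_x1, dam_x2)]
    if dup_marker is not None:
        jdup = [j for j, m in enumerate(markers) if m.id == dup_marker]
        if jdup:
            j = jdup[0]
            seen = sorted({sire_x[j], sire_y[j], dup_allele})
            calls[0, j] = Genotype.of(seen[0], seen[-1])
    for i, row in enumerate(rows):
        calls[2 + i, :] = row

    # i.i.d. genotype errors: replace the call with a uniformly random
    # genotype over the observed alleles at the marker
    if config.genotype_error_rate > 0:
        for i, ind in enumerate(individuals):
            for j, m in enumerate(markers):
                if rng.random() < config.genotype_error_rate:
                    pool = sorted({sire_x[j], sire_y[j], dam_x1[j], dam_x2[j]}
                                  | set("ACGT" if m.kind == "snp" else []))
                    a, b = rng.choice(pool, size=2, replace=True)
                    calls[i, j] = Genotype.of(str(a), str(b))
                    truth.perturbed_calls.append((ind.id, m.id))

    table = GenotypeTable(markers, individuals, calls, validate=False)
    sibship = Sibship(sire=sire, dam=dam, progeny=progeny, table=table, family_id=family_id)
    return FamilySimulation(sibship=sibship, truth=truth)


def simulate_population(config: SimulationConfig, seed: int,
                        population_id: str = "SIMPOP", river: str = "sim",
                        predation: str = "NA") -> PopulationSimulation:
    """Simulate a sexed population sample.

    Each male is one X draw plus one Y draw per marker; each female is two
    X draws.  Fully sex-linked sites are configured as a fixed difference
    between the X and Y frequency vectors; freely exchanging sites use
    identical vectors.
    """
    rng = np.random.default_rng(seed)
    markers = config.markers()
    x_freqs, y_freqs = config.x_allele_freqs, config.y_allele_freqs
    if x_freqs is None or y_freqs is None:
        dx, dy = _default_freqs(rng, markers)
        x_freqs = x_freqs or dx
        y_freqs = y_freqs or dy
    if len(x_freqs) != len(markers) or len(y_freqs) != len(markers):
        raise ValueError("allele frequency vectors must match the number of markers")

    individuals = []
    rows = []
    for i in range(config.n_pop_males):
        individuals.append(Individual(id=f"{population_id}_m{i + 1:03d}", sex="male",
                                      role="population_sample"))
        x = _draw_haplotype(rng, x_freqs)
        y = _draw_haplotype(rng, y_freqs)
        rows.append([Genotype.of(a, b) for a, b in zip(x, y)])
    for i in range(config.n_pop_females):
        individuals.append(Individual(id=f"{population_id}_f{i + 1:03d}", sex="female",
                                      role="population_sample"))
        x1 = _draw_haplotype(rng, x_freqs)
        x2 = _draw_haplotype(rng, x_freqs)
        rows.append([Genotype.of(a, b) for a, b in zip(x1, x2)])
    calls = np.array(rows, dtype=object)
    table = GenotypeTable(markers, individuals, calls, validate=False)
    sample = PopulationSample(population_id=population_id, river=river,
                              predation=predation, table=table)
    return PopulationSimulation(sample=sample, x_freqs=x_freqs, y_freqs=y_freqs)


# ---------------------------------------------------------------------------
# printed-table fixtures
# ---------------------------------------------------------------------------

@dataclass
class PopulationCounts:
    """One population row of the candidate-gene SNP association table."""

    population: str
    river: str
    predation: str
    n_males: int
    n_females: int
    males_het: int
    females_het: int = 0  # the variant was never seen in females

    @property
    def het_by_sex_table(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return ((self.males_het, self.n_males - self.males_het),
                (self.females_het, self.n_females - self.females_het))


@dataclass
class FixtureBundle:
    candidate_snp_counts: List[PopulationCounts]
    qhpg5_sibship1: Sibship
    qhpg5_sibship2: Sibship
    lah_duplication: Sibship
    lah_dup_marker_id: str
    lah_boundary: Sibship
    alp2b2_boundary: Sibship
    pmlpb2_f23r: RecombinantConstraint
    eleven_families: List[FamilyMeioses]
    gu1066_tables: Dict[str, GenotypeTable]
    manifest: Dict[str, object]


# printed coordinates of the recombinant-male sibship marker blocks:
# (n markers, first bp, last bp, state of the recombinant male)
_SIB2_BLOCKS = [
    (5, 458_883, 2_756_939, "X"),     # centromere-proximal markers
    (3, 2_952_176, 2_953_254, "Y"),   # true location more terminal (Discrepancy 2)
    (75, 3_100_000, 20_599_360, "X"),
    (10, 21_049_596, 23_293_233, "Y"),
    (9, 24_166_053, 24_508_654, "X"),  # true location more proximal (Discrepancy 1)
    (6, 24_829_827, 25_998_942, "Y"),  # sex-linked through the PAR boundary
]


def _block_positions(n: int, first: int, last: int) -> List[int]:
    if n == 1:
        return [first]
    return [int(round(p)) for p in np.linspace(first, last, n)]


def _sexlinked_sibship(family_id: str, marker_pos: List[int], progeny_spec,
                       recomb_states: Optional[Dict[str, List[str]]] = None,
                       par_pos: Optional[List[int]] = None,
                       chrom: str = "LG12") -> Sibship:
    """Build a sibship whose sire is A/G at every marker (X allele A, Y
    allele G) and dam A/A, with per-progeny paternal states as requested.

    ``progeny_spec`` is a list of (id, sex); by default males inherit Y
    everywhere and females X.  ``recomb_states`` overrides the full state
    list for specific progeny.  ``par_pos`` markers are partially
    sex-linked: a deterministic subset of progeny receives the opposite
    paternal allele there.
    """
    all_pos = list(marker_pos) + list(par_pos or [])
    markers = [Marker(id=f"{family_id}_M{i + 1:04d}", chrom=chrom, pos_bp=p, kind="snp",
                      alleles=frozenset({"A", "G"}))
               for i, p in enumerate(all_pos)]
    sire = Individual(id=f"{family_id}_sire", sex="male", family_id=family_id, role="sire")
    dam = Individual(id=f"{family_id}_dam", sex="female", family_id=family_id, role="dam")
    progeny = [Individual(id=pid, sex=sex, family_id=family_id, role="progeny")
               for pid, sex in progeny_spec]
    individuals = [sire, dam] + progeny
    n_core = len(marker_pos)
    calls = np.full((len(individuals), len(markers)), MISSING, dtype=object)
    calls[0, :] = Genotype.of("A", "G")
    calls[1, :] = Genotype.of("A", "A")
    for i, (pid, sex) in enumerate(progeny_spec):
        if recomb_states and pid in recomb_states:
            states = recomb_states[pid]
        else:
            states = ["Y" if sex == "male" else "X"] * n_core
        for j in range(n_core):
            calls[2 + i, j] = Genotype.of("A", "G") if states[j] == "Y" else Genotype.of("A", "A")
        # PAR markers: flip the paternal state for a rotating subset of
        # progeny so every PAR marker shows >= 1 sex/state mismatch
        for jp in range(n_core, len(markers)):
            base = "Y" if sex == "male" else "X"
            flip = (i + jp) % len(progeny_spec) == 0 or (i + jp) % len(progeny_spec) == 1
            state = ("X" if base == "Y" else "Y") if flip else base
            calls[2 + i, jp] = Genotype.of("A", "G") if state == "Y" else Genotype.of("A", "A")
    table = GenotypeTable(markers, individuals, calls, validate=False)
    return Sibship(sire=sire, dam=dam, progeny=progeny, table=table, family_id=family_id)


def _build_qhpg5_sibship2() -> Sibship:
    pos: List[int] = []
    male07_states: List[str] = []
    for n, first, last, state in _SIB2_BLOCKS:
        pos.extend(_block_positions(n, first, last))
        male07_states.extend([state] * n)
    progeny_spec = ([("QHPG5m%02d" % i, "male") for i in (5, 6, 8)]
                    + [("QHPG5m07r", "male")]
                    + [("QHPG5f%02d" % i, "female") for i in range(1, 7)])
    return _sexlinked_sibship("QHPG5s2", pos, progeny_spec,
                              recomb_states={"QHPG5m07r": male07_states})


def _build_qhpg5_sibship1() -> Sibship:
    """Sibship 1: 137 fully sex-linked informative markers plus 10 partially
    sex-linked terminal (PAR) markers; 13 progeny, no recombinant."""
    core: List[int] = []
    for n, first, last, _ in _SIB2_BLOCKS:
        core.extend(_block_positions(n, first, last))
    extra = [int(p) for p in np.linspace(3_300_000, 20_000_000, 29)]
    core = sorted(set(core) | set(extra))
    assert len(core) == 137
    par = [int(p) for p in np.linspace(26_050_000, 26_430_000, 10)]
    progeny_spec = ([(f"QHPG5s1m{i:02d}", "male") for i in range(1, 8)]
                    + [(f"QHPG5s1f{i:02d}", "female") for i in range(1, 7)])
    return _sexlinked_sibship("QHPG5s1", core, progeny_spec, par_pos=par)


def _build_boundary_family(family_id: str, boundary_bp: int, n_progeny_m: int,
                           n_progeny_f: int) -> Sibship:
    """A family whose most distal fully co-segregating marker sits at
    ``boundary_bp``; markers distal to it are partially sex-linked."""
    core = [int(p) for p in np.linspace(500_000, 24_500_000, 20)] + [boundary_bp]
    par = [25_998_942] + [int(p) for p in np.linspace(26_050_000, 26_430_000, 9)]
    progeny_spec = ([(f"{family_id}m{i:02d}", "male") for i in range(1, n_progeny_m + 1)]
                    + [(f"{family_id}f{i:02d}", "female") for i in range(1, n_progeny_f + 1)])
    return _sexlinked_sibship(family_id, core, progeny_spec, par_pos=par)


def _build_lah_duplication() -> Tuple[Sibship, str]:
    """The duplication-signature family at the 2,953,218 bp site: dam A/G,
    sire types A/G, female progeny 6 A/G + 11 A/A, male progeny 25 A/G."""
    marker = Marker(id="LAH_dup2953218", chrom="LG12", pos_bp=2_953_218, kind="snp",
                    alleles=frozenset({"A", "G"}))
    sire = Individual(id="LAH_sire", sex="male", family_id="LAH", role="sire")
    dam = Individual(id="LAH_dam", sex="female", family_id="LAH", role="dam")
    progeny, genotypes = [], []
    for i in range(6):
        progeny.append(Individual(id=f"LAHf{i + 1:02d}", sex="female", family_id="LAH", role="progeny"))
        genotypes.append(Genotype.of("A", "G"))
    for i in range(11):
        progeny.append(Individual(id=f"LAHf{i + 7:02d}", sex="female", family_id="LAH", role="progeny"))
        genotypes.append(Genotype.of("A", "A"))
    for i in range(25):
        progeny.append(Individual(id=f"LAHm{i + 1:02d}", sex="male", family_id="LAH", role="progeny"))
        genotypes.append(Genotype.of("A", "G"))
    individuals = [sire, dam] + progeny
    calls = np.full((len(individuals), 1), MISSING, dtype=object)
    calls[0, 0] = Genotype.of("A", "G")
    calls[1, 0] = Genotype.of("A", "G")
    for i, g in enumerate(genotypes):
        calls[2 + i, 0] = g
    table = GenotypeTable([marker], individuals, calls, validate=False)
    return Sibship(sire=sire, dam=dam, progeny=progeny, table=table, family_id="LAH"), marker.id


def _build_gu1066_tables() -> Dict[str, GenotypeTable]:
    """Synthetic stand-in for the gu1066-style microsatellite survey.

    Three populations, 16 individuals (32 alleles) per sex per population;
    constructed so that 29 distinct alleles are observed in total, 11 of
    them shared between two or more populations, with allele "264" carried
    by 4 males of the first population and 1 male of the third and
    homozygous in one of those 4 (so it is X-borne as well): a synthetic
    data set reproducing the printed summary numbers, not a transcription
    of the underlying survey.
    """
    common = [str(a) for a in range(230, 250, 2)]  # 10 alleles present in all pops
    unique = {"Guanapo": ["260", "262", "266", "268", "270", "272"],
              "Oropuche": [str(a) for a in range(280, 292, 2)],
              "Yarra": [str(a) for a in range(300, 312, 2)]}
    # "264" occurs in Guanapo and Yarra males only -> the 11th shared allele;
    # 10 common + 18 population-unique + 264 = 29 distinct alleles.
    all_alleles = (frozenset(common) | frozenset({"264"})
                   | frozenset(a for u in unique.values() for a in u))
    marker = Marker(id="gu1066", chrom="LG12", pos_bp=25_311_467, kind="microsatellite",
                    alleles=all_alleles)
    tables = {}
    for pop, uniq in unique.items():
        individuals, rows = [], []
        special = {"Guanapo": 4, "Yarra": 1}.get(pop, 0)  # males carrying 264
        for i in range(16):
            individuals.append(Individual(id=f"{pop}_m{i + 1:02d}", sex="male",
                                          role="population_sample"))
            if i < special:
                # one Guanapo male is homozygous: 264 is X-borne as well
                g = Genotype.of("264", "264") if (pop == "Guanapo" and i == 0) \
                    else Genotype.of("264", common[i % len(common)])
            elif i - special < 6:
                g = Genotype.of(uniq[i - special], common[i % len(common)])
            else:
                g = Genotype.of(common[i % len(common)], common[(i + 3) % len(common)])
            rows.append([g])
        for i in range(16):
            individuals.append(Individual(id=f"{pop}_f{i + 1:02d}", sex="female",
                                          role="population_sample"))
            if i < 6:
                g = Genotype.of(uniq[i], common[(i + 1) % len(common)])
            else:
                g = Genotype.of(common[i % len(common)], common[(i + 5) % len(common)])
            rows.append([g])
        calls = np.array(rows, dtype=object)
        tables[pop] = GenotypeTable([marker], individuals, calls, validate=False)
    return tables


def make_study_fixtures() -> FixtureBundle:
    """Deterministic, seed-free construction of the printed-table fixtures."""
    counts = [
        PopulationCounts("Guanapo LP (GLZ)", "Guanapo", "LP", 14, 10, 3),
        PopulationCounts("Aripo HP (AH)", "Aripo", "HP", 14, 10, 1),
        PopulationCounts("Aripo LP (AL)", "Aripo", "LP", 14, 10, 3),
        PopulationCounts("Quare HP", "Quare", "HP", 16, 10, 1),
        PopulationCounts("Turure LP", "Turure", "LP", 16, 10, 6),
        PopulationCounts("Turure HP", "Turure", "HP", 16, 10, 1),
    ]
    sib1 = _build_qhpg5_sibship1()
    sib2 = _build_qhpg5_sibship2()
    lah_dup, lah_marker = _build_lah_duplication()
    lah_boundary = _build_boundary_family("LAH", 25_194_513, 21, 21)
    alp2b2_boundary = _build_boundary_family("ALP2B2", 25_194_513, 68, 68)

    pmlpb2 = RecombinantConstraint(
        progeny_id="PMLPB2_f23r", sex="female",
        segments=[("Y", 1_200_000, 11_700_000), ("X", 21_300_000, 21_300_000)])

    eleven = [
        FamilyMeioses("QHPG5", 23, ["QHPG5m07r"]),
        FamilyMeioses("PMLPB2", 137, ["PMLPB2_f23r"]),
        FamilyMeioses("LAH", 42, []),
        FamilyMeioses("ALP2B2", 136, []),
    ] + [FamilyMeioses(f"FAM{i + 5:02d}", n, [])
         for i, n in enumerate([55, 55, 55, 55, 55, 54, 54])]

    manifest = {
        "approximate_coordinates": {
            "PMLPB2_f23r distal X marker": "21.3 Mb placeholder (21,300,000); "
                                           "no bp coordinate is printed",
            "QHPG5 sibship-2 non-terminal block interiors": "interpolated between the "
                                                            "printed block end positions",
        },
        "synthetic_stand_ins": ["gu1066_tables (reproduces the printed summary counts only)"],
        "totals": {"eleven_family_progeny": sum(f.n_progeny_sexed for f in eleven)},
    }
    return FixtureBundle(
        candidate_snp_counts=counts,
        qhpg5_sibship1=sib1,
        qhpg5_sibship2=sib2,
        lah_duplication=lah_dup,
        lah_dup_marker_id=lah_marker,
        lah_boundary=lah_boundary,
        alp2b2_boundary=alp2b2_boundary,
        pmlpb2_f23r=pmlpb2,
        eleven_families=eleven,
        gu1066_tables=_build_gu1066_tables(),
        manifest=manifest,
    )
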