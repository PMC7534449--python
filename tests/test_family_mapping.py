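"""Pedigree stage: parentage, phasing, crossovers, boundary, SDR interval."""

import itertools

import numpy as np
import pytest

from sdrmap.io_formats import Genotype, GenotypeTable, Individual, Marker, UnresolvedFamily
from sdrmap.family_mapping import (
    ConflictingConstraintsError,
    FamilyMeioses,
    InheritanceMatrix,
    RecombinantConstraint,
    assign_parentage,
    detect_crossovers,
    find_recombinant_progeny,
    mendelian_consistent,
    mendelian_violations,
    nonpar_recombination_rate,
    par_boundary,
    par_genetic_map,
    phase_sire,
    recombinant_constraints,
    sdr_interval,
)
from sdrmap.map_diagnostics import classify_discrepancies
from sdrmap.synthetic_data import SimulationConfig, simulate_family

from conftest import build_matrix, build_sibship


def min_switches_bruteforce(states):
    """Oracle: smallest number of haplotype switches explaining a state
    sequence, by exhaustive search over switch sets and start states."""
    n = len(states)
    if n == 0:
        return 0
    for k in range(0, n):
        for start in ("X", "Y"):
            for gaps in itertools.combinations(range(n - 1), k):
                s, out = start, []
                for j in range(n):
                    out.append(s)
                    if j in gaps:
                        s = "X" if s == "Y" else "Y"
                if out == list(states):
                    return k
    raise AssertionError("unreachable")


class TestMendelian:
    def test_consistency_rules(self):
        ag, aa, gg, cc = (Genotype.of(*p) for p in [("A", "G"), ("A", "A"), ("G", "G"), ("C", "C")])
        assert mendelian_consistent(ag, ag, aa)
        assert not mendelian_consistent(gg, ag, aa)
        assert not mendelian_consistent(cc, ag, aa)
        assert mendelian_consistent(Genotype(None), ag, aa)

    def test_flags_exactly_the_detectable_perturbations(self):
        # at hom x hom markers every child call is forced, so an injected
        # error is always detectable; flagged set == perturbed set
        xf = [{"A": 1.0}] * 20
        cfg = SimulationConfig(marker_positions=[100_000 * (i + 1) for i in range(20)],
                               x_allele_freqs=xf, y_allele_freqs=xf,
                               male_par_crossover_prob=0.0, female_crossover_rate=0.0,
                               par_start_bp=21_000_000, sdr_pos_bp=20_000_000,
                               chrom_length_bp=22_000_000, progeny_per_family=10)
        sim = simulate_family(cfg, seed=5)
        assert mendelian_violations(sim.sibship) == []
        t = sim.sibship.table
        perturbed = [(sim.sibship.progeny[0].id, t.markers[3].id),
                     (sim.sibship.progeny[4].id, t.markers[11].id)]
        for pid, mid in perturbed:
            t.set(pid, mid, Genotype.of("G", "G"))
        assert sorted(mendelian_violations(sim.sibship)) == sorted(perturbed)


class TestAssignParentage:
    def _family(self, rng, n_dams, n_progeny, n_markers=8):
        alleles = [str(a) for a in range(200, 240, 2)]
        markers = [Marker(id=f"ms{j}", chrom="LG12", pos_bp=1000 + j, kind="microsatellite",
                          alleles=frozenset(alleles)) for j in range(n_markers)]
        hap = lambda: [alleles[rng.integers(len(alleles))] for _ in range(n_markers)]
        sire = Individual(id="sire", sex="male", role="candidate_parent")
        dams = [Individual(id=f"dam{k}", sex="female", role="candidate_parent")
                for k in range(n_dams)]
        sire_h = (hap(), hap())
        dam_h = {d.id: (hap(), hap()) for d in dams}
        rows = [[Genotype.of(a, b) for a, b in zip(*sire_h)]]
        rows += [[Genotype.of(a, b) for a, b in zip(*dam_h[d.id])] for d in dams]
        progeny, truth = [], {}
        for i in range(n_progeny):
            d = dams[rng.integers(n_dams)]
            truth[f"p{i}"] = d.id
            rows.append([Genotype.of(sire_h[rng.integers(2)][j], dam_h[d.id][rng.integers(2)][j])
                         for j in range(n_markers)])
            progeny.append(Individual(id=f"p{i}", sex="male", family_id="FAM", role="progeny"))
        table = GenotypeTable(markers, [sire] + dams + progeny,
                              np.array(rows, dtype=object), validate=False)
        return UnresolvedFamily("FAM", [sire], dams, progeny), table, truth

    def test_two_dam_family_split_by_diagnostic_alleles(self):
        fam, table, truth = self._family(np.random.default_rng(1), 2, 12)
        rep = assign_parentage(fam, table)
        for sib in rep.sibships:
            for p in sib.progeny:
                assert truth[p.id] == sib.dam.id

    def test_single_candidate_pair_trivial(self):
        fam, table, truth = self._family(np.random.default_rng(2), 1, 5)
        rep = assign_parentage(fam, table)
        assert len(rep.sibships) == 1 and len(rep.sibships[0].progeny) == 5

    def test_three_dam_simulation_mostly_correct(self):
        rng = np.random.default_rng(3)
        fam, table, truth = self._family(rng, 3, 40)
        rep = assign_parentage(fam, table)
        assigned = {p.id: sib.dam.id for sib in rep.sibships for p in sib.progeny}
        correct = sum(1 for pid, did in assigned.items() if truth[pid] == did)
        assert correct >= 0.95 * 40
        # ambiguous/unassigned progeny are excluded, never misassigned
        assert all(truth[pid] == did for pid, did in assigned.items())


class TestPhaseSire:
    def test_simulated_phase_matches_truth_at_informative_markers(self):
        xf = [{"A": 1.0}] * 100
        yf = [{"G": 1.0}] * 100
        cfg = SimulationConfig(x_allele_freqs=xf, y_allele_freqs=yf, progeny_per_family=20)
        sim = simulate_family(cfg, seed=11)
        pa, matrix = phase_sire(sim.sibship)
        phased = [pm for pm in pa.by_marker.values() if pm.status == "phased"]
        assert phased
        for pm in phased:
            tx, ty = sim.truth.sire_haplotypes[pm.marker.id]
            assert (pm.sire_x_allele, pm.sire_y_allele) == (tx, ty)
        for p in sim.sibship.progeny:
            for j, m in enumerate(matrix.markers):
                s = matrix.states_for(p.id)[j]
                if s in ("X", "Y"):
                    assert s == sim.truth.paternal_origin[p.id][m.id]

    def test_homozygous_sire_yields_zero_phased_markers(self):
        sib = build_sibship([100, 200], {"p1": ("male", "YY"), "p2": ("female", "XX")},
                            sire_gt=("A", "A"))
        pa, matrix = phase_sire(sib)
        assert pa.phased_markers() == [] and matrix.markers == []

    def test_fewer_than_two_sexed_progeny_errors(self):
        sib = build_sibship([100], {"p1": ("male", "Y")})
        sib.progeny = sib.progeny[:1]
        sib.progeny[0].sex = "unknown"
        with pytest.raises(ValueError):
            phase_sire(sib)

    def test_fifty_fifty_split_marker_is_ambiguous(self):
        # 2 males with Y-pattern, 2 males with X-pattern at a lone marker:
        # no orientation is favoured
        sib = build_sibship([100], {"p1": ("male", "Y"), "p2": ("male", "Y"),
                                    "p3": ("male", "X"), "p4": ("male", "X")})
        pa, _ = phase_sire(sib)
        assert pa.by_marker[sib.table.markers[0].id].status == "ambiguous"

    def test_allele_relabelling_leaves_states_invariant(self):
        states = {"p1": ("male", "YYYY"), "p2": ("male", "YYXX"),
                  "p3": ("female", "XXXX"), "p4": ("female", "XXXX")}
        a = build_sibship([10, 20, 30, 40], states, sire_gt=("A", "G"))
        b = build_sibship([10, 20, 30, 40], states, sire_gt=("G", "A"), dam_gt=("G", "G"))
        _, ma = phase_sire(a)
        _, mb = phase_sire(b)
        for pid in states:
            assert list(ma.states_for(pid)) == list(mb.states_for(pid))


class TestDetectCrossovers:
    def test_all_x_progeny_has_no_crossover(self):
        m = build_matrix([10, 20, 30], {"p": ("female", "XXX")})
        assert detect_crossovers(m).events == []

    def test_single_switch_reported_with_flanks_and_support(self):
        m = build_matrix([10, 20, 30, 40], {"p": ("male", "XXYY")})
        (e,) = detect_crossovers(m).events
        assert e.interval == (20, 30)
        assert (e.n_support_proximal, e.n_support_distal) == (2, 2)

    def test_interior_singleton_is_a_candidate_not_a_crossover(self):
        m = build_matrix([10, 20, 30, 40, 50], {"p": ("male", "YYXYY")})
        scan = detect_crossovers(m)
        assert scan.events == []
        assert [s.marker.pos_bp for s in scan.singletons] == [30]
        assert len(scan.raw_events) == 2  # parsimony still sees both switches

    def test_uninformative_sites_are_skipped(self):
        m = build_matrix([10, 20, 30, 40], {"p": ("male", "XUUY")})
        (e,) = detect_crossovers(m).events
        assert e.interval == (10, 40)

    def test_raw_events_are_a_parsimony_minimum(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(1, 16))
            states = "".join(rng.choice(["X", "Y"], n))
            m = build_matrix([10 * (j + 1) for j in range(n)], {"p": ("male", states)})
            raw = [e for e in detect_crossovers(m).raw_events]
            assert len(raw) == min_switches_bruteforce(list(states))

    def test_simulated_crossovers_recovered_within_flanking_markers(self):
        xf = [{"A": 1.0}] * 100
        yf = [{"G": 1.0}] * 100
        rng = np.random.default_rng(8)
        found = total = 0
        for _ in range(10):
            cfg = SimulationConfig(male_nonpar_crossover_prob=0.3, progeny_per_family=30,
                                   x_allele_freqs=xf, y_allele_freqs=yf)
            sim = simulate_family(cfg, seed=int(rng.integers(2**31)))
            _, matrix = phase_sire(sim.sibship)
            ev = {}
            for e in detect_crossovers(matrix).events:
                ev.setdefault(e.progeny_id, []).append(e.interval)
            pos = [m.pos_bp for m in matrix.markers]
            for pid, xos in sim.truth.paternal_crossovers.items():
                inside = [c for c in xos if pos[0] <= c <= pos[-1]]
                for c in inside:
                    gap = np.searchsorted(pos, c)
                    if any(np.searchsorted(pos, o) == gap for o in inside if o != c):
                        continue  # two crossovers in one gap cancel: unrecoverable
                    total += 1
                    found += any(lo <= c <= hi for (lo, hi) in ev.get(pid, []))
        assert total > 100
        assert found / total >= 0.99


class TestParBoundary:
    def test_qhpg5_fixture_boundary(self, bundle):
        _, m1 = phase_sire(bundle.qhpg5_sibship1)
        _, m2 = phase_sire(bundle.qhpg5_sibship2)
        bd = par_boundary([m1, m2], exclude_progeny=["QHPG5m07r"], families=["QHPG5"])
        assert bd.boundary_pos_bp == 25_998_942
        assert len(bd.par_markers) == 10
        assert all(m.pos_bp > bd.boundary_pos_bp for m in bd.par_markers)

    def test_lah_alp2b2_fixture_boundary(self, bundle):
        _, ml = phase_sire(bundle.lah_boundary)
        _, ma = phase_sire(bundle.alp2b2_boundary)
        bd = par_boundary([ml, ma], families=["LAH", "ALP2B2"])
        assert bd.boundary_pos_bp == 25_194_513

    def test_all_cosegregating_markers_give_most_distal_and_empty_par(self):
        m = build_matrix([10, 20, 30], {"p1": ("male", "YYY"), "p2": ("female", "XXX")})
        bd = par_boundary([m])
        assert bd.boundary_pos_bp == 30 and bd.par_markers == []

    def test_no_cosegregating_marker_errors(self):
        m = build_matrix([10], {"p1": ("male", "X"), "p2": ("female", "Y")})
        with pytest.raises(ValueError):
            par_boundary([m])


class TestSdrInterval:
    def _boundary(self):
        m = build_matrix([100, 25_998_942], {"p1": ("male", "YY"), "p2": ("female", "XX")})
        return par_boundary([m])

    def test_male_recombinant_constrains_to_his_y_segment(self, bundle):
        _, matrix = phase_sire(bundle.qhpg5_sibship2)
        scan = detect_crossovers(matrix)
        diag = classify_discrepancies(matrix, scan)
        masked = [mid for f in diag.flags for mid in f.marker_ids]
        cons = recombinant_constraints(matrix, ["QHPG5m07r"], exclude_markers=masked)
        iv = sdr_interval(cons, self._boundary(), (1, 26_440_000))
        assert iv.proximal_bound_bp == 21_049_596
        assert iv.distal_bound_bp == 25_998_942

    def test_female_recombinant_excludes_her_y_segment(self, bundle):
        iv = sdr_interval([bundle.pmlpb2_f23r], self._boundary(), (1, 26_440_000))
        assert iv.proximal_bound_bp > 11_700_000  # not proximal to 11.7 Mb
        assert iv.other_components  # the proximal arm survives as a minor component

    def test_no_recombinants_give_whole_nonpar_region(self):
        iv = sdr_interval([], self._boundary(), (1, 26_440_000))
        assert (iv.proximal_bound_bp, iv.distal_bound_bp) == (1, 25_998_942)

    def test_conflicting_constraints_error(self):
        male = RecombinantConstraint("m", "male",
                                     [("X", 100, 200), ("Y", 300, 400), ("X", 500, 25_998_942)])
        female = RecombinantConstraint("f", "female", [("X", 100, 200), ("Y", 300, 400)])
        with pytest.raises(ConflictingConstraintsError):
            sdr_interval([male, female], self._boundary(), (1, 26_440_000))

    def test_label_swap_invariance_of_events_and_interval(self, bundle):
        # crossover calls and the SDR interval are functions of the
        # sex-anchored phase, so rebuilding after a global allele relabel
        # changes nothing
        sib = bundle.qhpg5_sibship2
        _, m1 = phase_sire(sib)
        t = sib.table
        swap = {"A": "G", "G": "A"}
        swapped = np.array([[Genotype(tuple(sorted(swap[a] for a in g.alleles)))
                             if not g.is_missing else g for g in row] for row in t.calls],
                           dtype=object)
        table2 = GenotypeTable(t.markers, t.individuals, swapped, validate=False)
        from sdrmap.family_mapping import Sibship

        sib_swapped = Sibship(sire=sib.sire, dam=sib.dam, progeny=sib.progeny, table=table2,
                              family_id=sib.family_id)
        _, m2 = phase_sire(sib_swapped)
        e1 = [(e.progeny_id, e.interval) for e in detect_crossovers(m1).events]
        e2 = [(e.progeny_id, e.interval) for e in detect_crossovers(m2).events]
        assert e1 == e2
        for pid in ("QHPG5m07r", "QHPG5m05"):
            assert list(m1.states_for(pid)) == list(m2.states_for(pid))

    def test_boundary_not_proximal_to_sdr_proximal_bound(self, bundle):
        _, matrix = phase_sire(bundle.qhpg5_sibship2)
        scan = detect_crossovers(matrix)
        diag = classify_discrepancies(matrix, scan)
        masked = [mid for f in diag.flags for mid in f.marker_ids]
        cons = recombinant_constraints(matrix, ["QHPG5m07r"], exclude_markers=masked)
        bd = self._boundary()
        iv = sdr_interval(cons, bd, (1, 26_440_000))
        assert bd.boundary_pos_bp >= iv.proximal_bound_bp

    def test_parameter_recovery_sdr_contained(self):
        # scaled-down version of the 200-replicate recovery experiment
        rng = np.random.default_rng(55)
        hits = n = 40
        hits = 0
        for _ in range(n):
            sdr = int(rng.integers(1_000_000, 25_800_000))
            cfg = SimulationConfig(sdr_pos_bp=sdr, progeny_per_family=20)
            sim = simulate_family(cfg, seed=int(rng.integers(2**31)))
            _, matrix = phase_sire(sim.sibship)
            scan = detect_crossovers(matrix)
            recs = find_recombinant_progeny(scan)
            excl = [pid for pid in recs
                    if any(e.interval[1] <= 26_000_000 for e in scan.events
                           if e.progeny_id == pid)]
            bd = par_boundary([matrix], exclude_progeny=excl)
            cons = recombinant_constraints(matrix, recs)
            iv = sdr_interval(cons, bd, (1, cfg.chrom_length_bp))
            hits += sim.truth.sdr_pos_bp in iv
        assert hits >= 0.95 * n


class TestNonparRate:
    def test_eleven_family_fixture(self, bundle):
        rate = nonpar_recombination_rate(bundle.eleven_families)
        assert (rate.n_recombinant, rate.n_progeny) == (2, 721)
        assert rate.percent == "0.28"
        assert rate.ci_low < 2 / 721 < rate.ci_high

    def test_zero_recombinants(self):
        rate = nonpar_recombination_rate([FamilyMeioses("f", 50, [])])
        assert rate.rate == 0.0 and rate.ci_low == 0.0

    def test_zero_progeny_errors(self):
        with pytest.raises(ValueError):
            nonpar_recombination_rate([])

    def test_estimator_coverage_under_simulation(self):
        # binomial sampling of recombinant counts at the configured rate:
        # the Clopper-Pearson interval covers truth in >= 95% of replicates
        rng = np.random.default_rng(4)
        p = 0.003
        cover = 0
        for _ in range(200):
            k = rng.binomial(2000, p)
            fams = [FamilyMeioses("f", 2000, [f"r{i}" for i in range(k)])]
            rate = nonpar_recombination_rate(fams)
            cover += rate.ci_low <= p <= rate.ci_high
        assert cover >= 0.95 * 200


class TestParGeneticMap:
    def test_two_markers_distance(self):
        states = {}
        for i in range(10):
            states[f"p{i}"] = ("male", "XX" if i else "XY")  # 1/10 recombinant
        m = build_matrix([26_000_100, 26_000_200], states)
        pm = par_genetic_map([m])
        assert pm.positions_cM[-1] == pytest.approx(10.0)

    def test_simulated_order_recovered_up_to_mirror(self):
        rng = np.random.default_rng(11)
        true_order = [f"P{j}" for j in range(6)]
        mats = []
        for fam in range(11):
            markers = [Marker(id=f"P{j}", chrom="LG12", pos_bp=26_000_000 + j * 50_000,
                              kind="snp", alleles=frozenset({"A", "G"})) for j in range(6)]
            prog = [Individual(id=f"f{fam}p{i}", sex="male", family_id=str(fam),
                               role="progeny") for i in range(30)]
            states = np.empty((30, 6), dtype=object)
            for i in range(30):
                h = rng.integers(2)
                for j in range(6):
                    if j > 0 and rng.random() < 0.08:
                        h = 1 - h
                    states[i, j] = "XY"[h]
            mats.append(InheritanceMatrix(prog, markers, states))
        pm = par_genetic_map(mats)
        assert pm.marker_order in (true_order, true_order[::-1])

    def test_fewer_than_two_markers_errors(self):
        m = build_matrix([26_000_100], {"p1": ("male", "Y"), "p2": ("male", "X")})
        with pytest.raises(ValueError):
            par_genetic_map([m])

    def test_unplaced_scaffold_markers_placed_proximal_and_terminal(self):
        # scaffold markers flank the assembled PAR markers in the genetic
        # map: one most proximal, the other terminal
        rng = np.random.default_rng(13)
        ids = ["NW_007615023.1_ms", "A", "B", "NW_007615031.1_ms"]
        markers = [Marker(id=i, chrom="PAR", pos_bp=k + 1, kind="snp",
                          alleles=frozenset({"A", "G"})) for k, i in enumerate(ids)]
        prog = [Individual(id=f"p{i}", sex="male", role="progeny", family_id="F")
                for i in range(60)]
        states = np.empty((60, 4), dtype=object)
        for i in range(60):
            h = rng.integers(2)
            for j in range(4):
                if j > 0 and rng.random() < 0.10:
                    h = 1 - h
                states[i, j] = "XY"[h]
        pm = par_genetic_map([InheritanceMatrix(prog, markers, states)])
        ends = {pm.marker_order[0], pm.marker_order[-1]}
        assert ends == {"NW_007615023.1_ms", "NW_007615031.1_ms"}
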