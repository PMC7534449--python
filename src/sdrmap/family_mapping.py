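"""Pedigree stage: parentage, sire X/Y phasing, crossovers, PAR boundary, SDR.

The logic follows the standard family-mapping argument for a recombining XY
pair.  At a marker where the sire is heterozygous and the paternally
transmitted allele is identifiable given the dam's genotype (dam homozygous,
or dam alleles disjoint from the sire's), each progeny reveals which sire
haplotype it inherited.  Labelling the sire's two haplotypes X and Y so that
the majority of male progeny carry the Y-labelled allele gives an
inheritance matrix of X/Y states per progeny; state switches along the
chromosome are sire-meiosis crossovers, progeny whose states switch are
recombinants, the most distal marker that co-segregates perfectly with sex
defines the pseudoautosomal (PAR) boundary, and each recombinant constrains
the interval that can contain the male-determining locus (SDR): a male's
SDR allele must lie in his paternal-Y-derived segments and a female's must
lie outside hers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_formats import Genotype, GenotypeTable, Individual, Marker, UnresolvedFamily, logger

__all__ = [
    "Sibship",
    "PhasedMarker",
    "PhaseAssignment",
    "InheritanceMatrix",
    "CrossoverEvent",
    "CrossoverScan",
    "ParBoundary",
    "SdrInterval",
    "RecombinantConstraint",
    "ParMap",
    "FamilyMeioses",
    "RecombinationRate",
    "ConflictingConstraintsError",
    "mendelian_consistent",
    "mendelian_violations",
    "assign_parentage",
    "phase_sire",
    "detect_crossovers",
    "find_recombinant_progeny",
    "par_boundary",
    "recombinant_constraints",
    "sdr_interval",
    "nonpar_recombination_rate",
    "par_genetic_map",
]


@dataclass
class Sibship:
    """A full-sib family: one sire, one dam, sexed progeny, genotypes."""

    sire: Individual
    dam: Individual
    progeny: List[Individual]
    table: Optional[GenotypeTable] = None
    family_id: Optional[str] = None

    def __post_init__(self):
        if self.family_id is None and self.progeny:
            self.family_id = self.progeny[0].family_id


@dataclass
class PhasedMarker:
    marker: Marker
    status: str  # "phased" | "uninformative" | "ambiguous"
    sire_x_allele: Optional[str] = None
    sire_y_allele: Optional[str] = None


@dataclass
class PhaseAssignment:
    """Sire X/Y allele assignment per marker, keyed by marker id."""

    by_marker: Dict[str, PhasedMarker]

    def phased_markers(self) -> List[Marker]:
        return [pm.marker for pm in self.by_marker.values() if pm.status == "phased"]


class InheritanceMatrix:
    """Progeny x phased-marker matrix of paternal-haplotype states.

    States are ``"X"``, ``"Y"`` or ``"U"`` (uninformative: missing call or
    Mendelian conflict at that cell).  Markers are ordered by assembly
    position.
    """

    def __init__(self, progeny: Sequence[Individual], markers: Sequence[Marker],
                 states: np.ndarray):
        order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos_bp))
        self.progeny = list(progeny)
        self.markers = [markers[i] for i in order]
        self.states = states[:, order]
        self._p_index = {p.id: i for i, p in enumerate(self.progeny)}

    def states_for(self, progeny_id: str) -> np.ndarray:
        return self.states[self._p_index[progeny_id], :]

    def marker_by_id(self, marker_id: str) -> Marker:
        if not hasattr(self, "_m_index"):
            self._m_index = {m.id: j for j, m in enumerate(self.markers)}
        return self.markers[self._m_index[marker_id]]

    def sex_of(self, progeny_id: str) -> str:
        return self.progeny[self._p_index[progeny_id]].sex


@dataclass
class CrossoverEvent:
    progeny_id: str
    meiosis: str  # "sire" | "dam"
    interval: Tuple[int, int]  # (proximal flank pos_bp, distal flank pos_bp)
    n_support_proximal: int
    n_support_distal: int

    def __post_init__(self):
        if not self.interval[0] < self.interval[1]:
            raise ValueError(f"crossover interval must be increasing, got {self.interval}")


@dataclass
class SingletonSwitch:
    """A single informative marker flanked by opposite states on both sides —
    a discrepancy/genotyping-error candidate, not a crossover."""

    progeny_id: str
    marker: Marker


@dataclass
class CrossoverScan:
    events: List[CrossoverEvent]  # after singleton masking
    singletons: List[SingletonSwitch]
    raw_events: List[CrossoverEvent]  # every run boundary (parsimony minimum)


@dataclass
class ParBoundary:
    boundary_pos_bp: int
    boundary_marker_id: str
    par_markers: List[Marker]  # partially sex-linked markers distal to the boundary
    families: List[str]


@dataclass
class SdrInterval:
    proximal_bound_bp: int
    distal_bound_bp: int
    supporting_recombinants: List[str]
    other_components: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.proximal_bound_bp < self.distal_bound_bp:
            raise ValueError("SDR interval bounds must be increasing")

    def __contains__(self, pos_bp: int) -> bool:
        return self.proximal_bound_bp <= pos_bp <= self.distal_bound_bp


class ConflictingConstraintsError(ValueError):
    """Recombinant constraints intersect to nothing — signals genotyping error."""


# ---------------------------------------------------------------------------
# Mendelian checks and parentage assignment
# ---------------------------------------------------------------------------

def mendelian_consistent(child: Genotype, sire: Genotype, dam: Genotype) -> bool:
    """True when the child's genotype can arise from sire x dam (missing
    genotypes are treated as compatible with anything)."""
    if child.is_missing or sire.is_missing or dam.is_missing:
        return True
    a, b = child.alleles
    return (a in sire and b in dam) or (b in sire and a in dam)


def mendelian_violations(sibship: Sibship) -> List[Tuple[str, str]]:
    """(progeny id, marker id) pairs whose calls are inconsistent with
    sire x dam.  Violations are flagged, never silently dropped."""
    t = sibship.table
    out = []
    for m in t.markers:
        sg = t.get(sibship.sire.id, m.id)
        dg = t.get(sibship.dam.id, m.id)
        for p in sibship.progeny:
            if not mendelian_consistent(t.get(p.id, m.id), sg, dg):
                out.append((p.id, m.id))
    return out


@dataclass
class ParentageReport:
    sibships: List[Sibship]
    unassigned: List[str]  # progeny compatible with zero pairs
    ambiguous: List[str]  # progeny compatible with more than one pair


def assign_parentage(family: UnresolvedFamily, table: GenotypeTable) -> ParentageReport:
    """Assign each progeny to the (sire, dam) pair with zero Mendelian exclusions.

    Progeny compatible with no pair are reported unassigned; progeny
    compatible with more than one pair are ambiguous and excluded from
    phasing.  Assigned progeny are grouped into full sibships per pair.
    """
    pairs = [(s, d) for s in family.candidate_sires for d in family.candidate_dams]
    if not pairs:
        raise ValueError(f"family {family.family_id}: no candidate parent pairs")
    by_pair: Dict[Tuple[str, str], List[Individual]] = {}
    unassigned, ambiguous = [], []
    for p in family.progeny:
        compatible = []
        for s, d in pairs:
            n_excl = 0
            for m in table.markers:
                if not mendelian_consistent(table.get(p.id, m.id),
                                            table.get(s.id, m.id),
                                            table.get(d.id, m.id)):
                    n_excl += 1
            if n_excl == 0:
                compatible.append((s, d))
        if len(compatible) == 0:
            unassigned.append(p.id)
        elif len(compatible) > 1:
            ambiguous.append(p.id)
        else:
            s, d = compatible[0]
            by_pair.setdefault((s.id, d.id), []).append(p)
    sibships = []
    parent_by_id = {i.id: i for i in family.candidate_sires + family.candidate_dams}
    for (sid, did), progeny in sorted(by_pair.items()):
        member_ids = [sid, did] + [p.id for p in progeny]
        sibships.append(Sibship(sire=parent_by_id[sid], dam=parent_by_id[did],
                                progeny=progeny, table=table.subset(member_ids),
                                family_id=family.family_id))
    return ParentageReport(sibships=sibships, unassigned=unassigned, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# sire phasing
# ---------------------------------------------------------------------------

def _paternal_allele(child: Genotype, sire: Genotype, dam: Genotype) -> Optional[str]:
    """The allele the sire transmitted, or None when not determinable."""
    if child.is_missing or sire.is_missing or dam.is_missing or not sire.is_het:
        return None
    s = set(sire.alleles)
    d = set(dam.alleles)
    a, b = child.alleles
    if len(d) == 1:  # dam homozygous
        (dm,) = d
        if a == dm and b in s:
            # child (dm, b): maternal dm, paternal b; for child dm/dm paternal is dm
            return b if b != dm or dm in s else None
        if b == dm and a in s:
            return a
        return None  # Mendelian conflict
    if s.isdisjoint(d):  # dam heterozygous but alleles disjoint from sire's
        pa = [x for x in (a, b) if x in s]
        ma = [x for x in (a, b) if x in d]
        if len(pa) == 1 and len(ma) == 1:
            return pa[0]
        return None
    return None  # dam shares one allele with the het sire: not resolvable


def phase_sire(sibship: Sibship) -> Tuple[PhaseAssignment, InheritanceMatrix]:
    """Phase the sire's haplotypes into X and Y using progeny sexes.

    For each informative marker the orientation is chosen so that the
    majority of male progeny carry the Y-labelled allele and the majority
    of female progeny the X-labelled allele (combined majority vote over
    sexed progeny; exact ties make the marker ambiguous).  Progeny whose
    states conflict with their sex at a minority of markers are candidate
    recombinants — they are expected output, not errors.
    """
    t = sibship.table
    sexed = [p for p in sibship.progeny if p.sex in ("male", "female")]
    if len(sexed) < 2:
        raise ValueError(f"sibship {sibship.family_id}: need >=2 sexed progeny to phase")
    ordered = sorted(t.markers, key=lambda m: (m.chrom, m.pos_bp))
    phased: Dict[str, PhasedMarker] = {}
    cols: List[np.ndarray] = []
    kept_markers: List[Marker] = []
    prev_col: Optional[List[Optional[str]]] = None  # previous marker's per-progeny state
    for m in ordered:
        sg = t.get(sibship.sire.id, m.id)
        dg = t.get(sibship.dam.id, m.id)
        if sg.is_missing or not sg.is_het or dg.is_missing:
            phased[m.id] = PhasedMarker(marker=m, status="uninformative")
            continue
        paternal = {p.id: _paternal_allele(t.get(p.id, m.id), sg, dg) for p in sibship.progeny}
        if all(v is None for v in paternal.values()):
            phased[m.id] = PhasedMarker(marker=m, status="uninformative")
            continue
        a1, a2 = sg.alleles
        # sex vote: positive favours Y = a2 (majority of males carry a2,
        # majority of females a1)
        sex_vote = 0
        for p in sexed:
            pa = paternal[p.id]
            if pa is None:
                continue
            sex_vote += 1 if (p.sex == "male") == (pa == a2) else -1
        # chain vote against the previous phased marker: a crossover between
        # adjacent informative markers is the exception, so the orientation
        # keeping most progeny on the same haplotype is preferred (this
        # anchors markers deep in the PAR, where the sex signal fades)
        chain_vote = 0
        if prev_col is not None:
            for i, p in enumerate(sibship.progeny):
                pa = paternal[p.id]
                if pa is None or prev_col[i] is None:
                    continue
                chain_vote += 1 if (prev_col[i] == "Y") == (pa == a2) else -1
        vote = chain_vote if chain_vote != 0 else sex_vote
        if vote == 0:
            phased[m.id] = PhasedMarker(marker=m, status="ambiguous")
            continue
        x_allele, y_allele = (a1, a2) if vote > 0 else (a2, a1)
        phased[m.id] = PhasedMarker(marker=m, status="phased",
                                    sire_x_allele=x_allele, sire_y_allele=y_allele)
        col = [None if paternal[p.id] is None else ("Y" if paternal[p.id] == y_allele else "X")
               for p in sibship.progeny]
        prev_col = col
        cols.append(np.array(["U" if s is None else s for s in col], dtype=object))
        kept_markers.append(m)

    # global anchor: the chain fixes relative orientation; flip everything if
    # the overall sex agreement favours the mirror labelling
    if kept_markers:
        states = np.stack(cols, axis=1)
        agree = 0
        for i, p in enumerate(sibship.progeny):
            if p.sex not in ("male", "female"):
                continue
            expected = "Y" if p.sex == "male" else "X"
            for s in states[i, :]:
                if s == "U":
                    continue
                agree += 1 if s == expected else -1
        if agree < 0:
            flip = {"X": "Y", "Y": "X", "U": "U"}
            states = np.vectorize(flip.get)(states).astype(object)
            for pm in phased.values():
                if pm.status == "phased":
                    pm.sire_x_allele, pm.sire_y_allele = pm.sire_y_allele, pm.sire_x_allele
    else:
        states = np.empty((len(sibship.progeny), 0), dtype=object)
    matrix = InheritanceMatrix(sibship.progeny, kept_markers, states)
    return PhaseAssignment(by_marker=phased), matrix


# ---------------------------------------------------------------------------
# crossover detection
# ---------------------------------------------------------------------------

def _runs(seq: List[Tuple[int, str]]) -> List[Tuple[str, List[int]]]:
    """Group an (index, state) sequence into maximal same-state runs."""
    runs: List[Tuple[str, List[int]]] = []
    for idx, s in seq:
        if runs and runs[-1][0] == s:
            runs[-1][1].append(idx)
        else:
            runs.append((s, [idx]))
    return runs


def detect_crossovers(matrix: InheritanceMatrix, meiosis: str = "sire",
                      exclude_markers: Iterable[str] = ()) -> CrossoverScan:
    """Minimal-crossover parsimony scan of an inheritance matrix.

    Per progeny, uninformative sites (and ``exclude_markers``) are ignored
    and each switch between maximal X/Y runs is a crossover, reported with
    its flanking informative markers and the number of supporting markers
    on each side.  Interior single-marker runs (one marker flanked by the
    opposite state on both sides) are reported separately as
    discrepancy/genotyping-error candidates, not crossovers; ``raw_events``
    keeps every run boundary, which is the parsimony minimum.
    """
    excluded = set(exclude_markers)
    pos = [m.pos_bp for m in matrix.markers]
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            raise ValueError("marker list must be strictly increasing by position")

    def boundary_events(runs, pid):
        ev = []
        for left, right in zip(runs, runs[1:]):
            ev.append(CrossoverEvent(
                progeny_id=pid, meiosis=meiosis,
                interval=(matrix.markers[left[1][-1]].pos_bp, matrix.markers[right[1][0]].pos_bp),
                n_support_proximal=len(left[1]), n_support_distal=len(right[1])))
        return ev

    events, singles, raw = [], [], []
    for p in matrix.progeny:
        seq = [(j, s) for j, s in enumerate(matrix.states_for(p.id))
               if s in ("X", "Y") and matrix.markers[j].id not in excluded]
        runs = _runs(seq)
        raw.extend(boundary_events(runs, p.id))
        # mask interior singletons, then re-merge adjacent equal runs
        kept = [r for i, r in enumerate(runs)
                if not (0 < i < len(runs) - 1 and len(r[1]) == 1)]
        for i, r in enumerate(runs):
            if 0 < i < len(runs) - 1 and len(r[1]) == 1:
                singles.append(SingletonSwitch(progeny_id=p.id, marker=matrix.markers[r[1][0]]))
        merged: List[Tuple[str, List[int]]] = []
        for s, idxs in kept:
            if merged and merged[-1][0] == s:
                merged[-1][1].extend(idxs)
            else:
                merged.append((s, list(idxs)))
        events.extend(boundary_events(merged, p.id))
    return CrossoverScan(events=events, singletons=singles, raw_events=raw)


def find_recombinant_progeny(scan: CrossoverScan) -> List[str]:
    """Progeny ids with at least one crossover (after singleton masking)."""
    return sorted({e.progeny_id for e in scan.events})


# ---------------------------------------------------------------------------
# PAR boundary
# ---------------------------------------------------------------------------

def par_boundary(matrices: Sequence[InheritanceMatrix],
                 exclude_progeny: Iterable[str] = (),
                 families: Optional[Sequence[str]] = None) -> ParBoundary:
    """Most distal marker that co-segregates completely with sex.

    A mismatch at a marker is a sexed progeny (not excluded) whose state
    conflicts with its sex (male with X, or female with Y).  The boundary
    is the most distal marker with zero mismatches across all supplied
    matrices; every marker distal to it (which necessarily shows >= 1
    mismatch) is listed as a PAR marker.  Whole-chromosome-scale
    recombinants (known from the crossover scan) should be passed in
    ``exclude_progeny``.
    """
    excluded = set(exclude_progeny)
    mismatches: Dict[int, int] = {}
    seen: Dict[int, Marker] = {}
    for matrix in matrices:
        for j, m in enumerate(matrix.markers):
            key = m.pos_bp
            seen.setdefault(key, m)
            for p in matrix.progeny:
                if p.id in excluded or p.sex not in ("male", "female"):
                    continue
                s = matrix.states_for(p.id)[j]
                if s == "U":
                    continue
                expected = "Y" if p.sex == "male" else "X"
                if s != expected:
                    mismatches[key] = mismatches.get(key, 0) + 1
    if not seen:
        raise ValueError("no phased markers supplied")
    clean = [pos for pos in seen if mismatches.get(pos, 0) == 0]
    if not clean:
        raise ValueError("no fully co-segregating marker: no sex-linked region detectable")
    boundary_pos = max(clean)
    par = [seen[pos] for pos in sorted(seen) if pos > boundary_pos]
    return ParBoundary(boundary_pos_bp=boundary_pos,
                       boundary_marker_id=seen[boundary_pos].id,
                       par_markers=par,
                       families=list(families or []))


# ---------------------------------------------------------------------------
# SDR interval from recombinant constraints
# ---------------------------------------------------------------------------

@dataclass
class RecombinantConstraint:
    """A recombinant progeny's paternal X/Y segments, by marker position.

    ``segments`` is an ordered list of (state, first_marker_pos, last_marker_pos).
    """

    progeny_id: str
    sex: str
    segments: List[Tuple[str, int, int]]


def recombinant_constraints(matrix: InheritanceMatrix, progeny_ids: Iterable[str],
                            exclude_markers: Iterable[str] = ()) -> List[RecombinantConstraint]:
    """Build SDR constraints from the (optionally discrepancy-masked) matrix."""
    excluded = set(exclude_markers)
    out = []
    for pid in progeny_ids:
        seq = [(j, s) for j, s in enumerate(matrix.states_for(pid))
               if s in ("X", "Y") and matrix.markers[j].id not in excluded]
        segs = [(state, matrix.markers[idxs[0]].pos_bp, matrix.markers[idxs[-1]].pos_bp)
                for state, idxs in _runs(seq)]
        out.append(RecombinantConstraint(progeny_id=pid, sex=matrix.sex_of(pid), segments=segs))
    return out


def _intersect(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                out.append((lo, hi))
    return sorted(out)


def sdr_interval(constraints: Sequence[RecombinantConstraint], boundary: ParBoundary,
                 chrom_span: Tuple[int, int]) -> SdrInterval:
    """Intersect recombinant constraints into the SDR-containing interval.

    A male's SDR allele must lie within his paternal-Y-derived segments;
    a female's must lie outside her paternal-Y-derived segments.  Segment
    bounds are flanking informative-marker positions: a must-include Y
    segment contributes the closed span of its markers (extended to the
    chromosome start / the PAR boundary when it is the first / last
    segment), while a must-exclude Y segment removes only the span its
    markers certainly cover.  The interval is additionally capped distally
    by the PAR boundary.  With no recombinants the whole non-PAR region is
    returned.  If the constraints intersect into several disjoint
    components, the one adjacent to the PAR boundary is reported (the SDR
    sits just proximal to the PAR under the mapping model) and the others
    are kept in ``other_components``.
    """
    start = chrom_span[0]
    allowed: List[Tuple[int, int]] = [(start, boundary.boundary_pos_bp)]
    supporting = []
    for c in constraints:
        if c.sex not in ("male", "female") or len(c.segments) < 2:
            continue
        supporting.append(c.progeny_id)
        y_spans = []
        for i, (state, lo, hi) in enumerate(c.segments):
            if state != "Y":
                continue
            if i == 0:
                lo = start
            if i == len(c.segments) - 1:
                hi = max(hi, boundary.boundary_pos_bp)
            y_spans.append((lo, hi))
        if c.sex == "male":
            allowed = _intersect(allowed, y_spans)
        else:
            # subtract only the certainly-Y marker spans (no flank extension)
            certain = [(lo, hi) for (state, lo, hi) in c.segments if state == "Y"]
            for lo, hi in certain:
                nxt = []
                for s, e in allowed:
                    if hi < s or lo > e:
                        nxt.append((s, e))
                        continue
                    if s <= lo - 1:
                        nxt.append((s, lo - 1))
                    if hi + 1 <= e:
                        nxt.append((hi + 1, e))
                allowed = nxt
        if not allowed:
            raise ConflictingConstraintsError(
                "recombinant constraints have empty intersection (conflicting "
                "recombinants — check for genotyping error)")
    allowed = sorted(allowed)
    final = allowed[-1]  # component adjacent to the PAR boundary
    return SdrInterval(proximal_bound_bp=final[0], distal_bound_bp=final[1],
                       supporting_recombinants=supporting,
                       other_components=allowed[:-1])


# ---------------------------------------------------------------------------
# non-PAR recombination rate
# ---------------------------------------------------------------------------

@dataclass
class FamilyMeioses:
    """Per-family crossover accounting for the non-PAR recombination rate."""

    family_id: str
    n_progeny_sexed: int
    nonpar_recombinant_progeny: List[str]


@dataclass
class RecombinationRate:
    n_recombinant: int
    n_progeny: int
    rate: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> str:
        from .io_formats import format_percent

        return format_percent(self.rate)


def nonpar_recombination_rate(families: Sequence[FamilyMeioses],
                              confidence: float = 0.95) -> RecombinationRate:
    """Share of meiotic products with a sire crossover proximal to the PAR
    boundary, with a Clopper-Pearson confidence interval."""
    n = sum(f.n_progeny_sexed for f in families)
    if n == 0:
        raise ValueError("zero progeny")
    k = sum(len(set(f.nonpar_recombinant_progeny)) for f in families)
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return RecombinationRate(n_recombinant=k, n_progeny=n, rate=k / n, ci_low=lo, ci_high=hi)


def nonpar_events(scan: CrossoverScan, boundary: ParBoundary) -> List[CrossoverEvent]:
    """Sire crossovers whose interval lies entirely proximal to the PAR boundary."""
    return [e for e in scan.events
            if e.meiosis == "sire" and e.interval[1] <= boundary.boundary_pos_bp]


# ---------------------------------------------------------------------------
# PAR genetic map
# ---------------------------------------------------------------------------

@dataclass
class ParMap:
    marker_order: List[str]
    positions_cM: List[float]
    rf: Dict[Tuple[str, str], float]


def _pairwise_rf(matrices: Sequence[InheritanceMatrix], marker_ids: List[str]) -> Dict[Tuple[str, str], float]:
    diff: Dict[Tuple[str, str], int] = {}
    tot: Dict[Tuple[str, str], int] = {}
    for matrix in matrices:
        idx = {m.id: j for j, m in enumerate(matrix.markers)}
        present = [mid for mid in marker_ids if mid in idx]
        for a, b in itertools.combinations(present, 2):
            ja, jb = idx[a], idx[b]
            d = t = 0
            for p in matrix.progeny:
                sa = matrix.states_for(p.id)[ja]
                sb = matrix.states_for(p.id)[jb]
                if sa == "U" or sb == "U":
                    continue
                t += 1
                if sa != sb:
                    d += 1
            key = (a, b) if a < b else (b, a)
            diff[key] = diff.get(key, 0) + d
            tot[key] = tot.get(key, 0) + t
    rf = {}
    for key, t in tot.items():
        if t == 0:
            continue
        d = diff[key]
        # per-marker haplotype labels may be arbitrarily flipped between
        # families, so take the minor fraction
        rf[key] = min(d, t - d) / t
    return rf


def _order_cost(order: Sequence[str], rf: Dict[Tuple[str, str], float]) -> float:
    cost = 0.0
    for a, b in zip(order, order[1:]):
        key = (a, b) if a < b else (b, a)
        cost += rf.get(key, 0.5)
    return cost


def par_genetic_map(matrices: Sequence[InheritanceMatrix],
                    marker_ids: Optional[List[str]] = None) -> ParMap:
    """Order PAR markers by sire-meiosis recombination, pooled over families.

    Pairwise recombination fractions are pooled across families; the order
    minimizing the summed adjacent recombination fractions (equivalently,
    total crossovers across all progeny) is found exhaustively for <= 8
    markers and by greedy insertion plus 2-opt refinement above that.  Map
    positions are cumulative recombination fractions x 100 (cM, no mapping
    function).  The returned order is canonical up to mirror image.
    """
    if marker_ids is None:
        ids = sorted({m.id for matrix in matrices for m in matrix.markers})
    else:
        ids = list(marker_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 informative PAR markers")
    rf = _pairwise_rf(matrices, ids)

    if len(ids) <= 8:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(ids):
            if perm[0] > perm[-1]:  # skip mirror images
                continue
            c = _order_cost(perm, rf)
            if c < best_cost - 1e-12:
                best, best_cost = list(perm), c
        order = best
    else:
        order = [ids[0]]
        for mid in ids[1:]:
            cands = [order[:k] + [mid] + order[k:] for k in range(len(order) + 1)]
            order = min(cands, key=lambda o: _order_cost(o, rf))
        improved = True
        while improved:
            improved = False
            for i in range(len(order) - 1):
                for j in range(i + 1, len(order)):
                    cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                    if _order_cost(cand, rf) < _order_cost(order, rf) - 1e-12:
                        order, improved = cand, True
    if order[0] > order[-1]:
        order = order[::-1]
    positions = [0.0]
    for a, b in zip(order, order[1:]):
        key = (a, b) if a < b else (b, a)
        positions.append(positions[-1] + 100.0 * rf.get(key, 0.0))
    return ParMap(marker_order=order, positions_cM=positions, rf=rf)
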