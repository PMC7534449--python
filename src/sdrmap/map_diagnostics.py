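"""Assembly-order and duplication diagnostics, RBH assignment, GC windows.

Rare recombinant progeny double as assembly probes: in a region that never
recombines in male meiosis, marker order cannot be established genetically,
but a recombinant's single crossover splits the chromosome into two state
blocks, and any contiguous run of markers whose states side with the
*opposite* block betrays a mis-assembled position.  A second diagnostic
covers apparent sex linkage produced by a Y-borne duplication: if the Y
carries an extra copy of a locus, every male types heterozygous regardless
of which Y-linked haplotype he inherited, while female progeny still
segregate according to the dam — a pattern that is vanishingly unlikely
under single-locus Mendelian transmission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FormatError, Genotype, Marker, logger
from .family_mapping import CrossoverScan, InheritanceMatrix, Sibship

__all__ = [
    "DiscrepancyFlag",
    "DiagnosticsResult",
    "DuplicationCall",
    "RbhPair",
    "GcProfile",
    "classify_discrepancies",
    "duplication_signature",
    "reciprocal_best_hits",
    "read_hit_table",
    "rbh_scaffold_summary",
    "gc_windows",
]


# ---------------------------------------------------------------------------
# assembly-order discrepancies
# ---------------------------------------------------------------------------

@dataclass
class DiscrepancyFlag:
    """A contiguous run of markers conflicting with its positional block.

    ``misplaced_proximal``: the run segregates with the proximal block but
    is assembled distal of the crossover (true location more proximal).
    ``misplaced_distal``: the converse (true location more terminal).
    """

    marker_ids: List[str]
    positions: Tuple[int, int]  # (first, last) assembly pos of the run
    klass: str  # "misplaced_proximal" | "misplaced_distal"
    progeny_id: str
    evidence: str
    corroboration: Optional[str] = None


@dataclass
class DiagnosticsResult:
    flags: List[DiscrepancyFlag]
    genotyping_error_candidates: List[Tuple[str, str]]  # (progeny, marker)


def _best_single_crossover(seq: List[str]) -> Tuple[int, str, str, int]:
    """Fit the one-crossover model to an informative state sequence.

    Returns (cut index k, proximal state, distal state, n mismatches) where
    markers [0, k) are modelled as the proximal state and [k, n) as the
    distal state; the fit minimizing mismatches wins (smallest k on ties).
    """
    n = len(seq)
    best = None
    for p_state, d_state in (("X", "Y"), ("Y", "X")):
        # prefix mismatches against p_state
        mism_prefix = np.cumsum([0] + [s != p_state for s in seq])
        mism_suffix = np.cumsum([0] + [s != d_state for s in seq[::-1]])[::-1]
        for k in range(1, n):  # require both blocks non-empty
            m = int(mism_prefix[k] + mism_suffix[k])
            cand = (m, k, p_state, d_state)
            if best is None or cand[:2] < best[:2]:
                best = cand
    m, k, p_state, d_state = best
    return k, p_state, d_state, m


def _per_progeny_candidates(matrix: InheritanceMatrix, recombinants: Sequence[str],
                            exclude: frozenset, min_flank: int):
    """One-crossover fit per recombinant progeny -> candidate conflict runs.

    Returns (candidates, errors): candidates are (progeny_id, marker-id
    tuple, class) for mismatch runs flanked on both sides by >= min_flank
    consecutive model-consistent markers; conflicts without such flanking
    go to errors as potential genotyping errors.
    """
    candidates, errors = [], []
    for pid in recombinants:
        full = matrix.states_for(pid)
        idxs = [j for j, s in enumerate(full)
                if s in ("X", "Y") and matrix.markers[j].id not in exclude]
        seq = [full[j] for j in idxs]
        if len(set(seq)) < 2:
            continue
        k, p_state, d_state, _ = _best_single_crossover(seq)
        model = [p_state] * k + [d_state] * (len(seq) - k)
        mismatch = [s != m for s, m in zip(seq, model)]
        i = 0
        while i < len(seq):
            if not mismatch[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(seq) and mismatch[j + 1]:
                j += 1
            left = 0
            x = i - 1
            while x >= 0 and not mismatch[x]:
                left += 1
                x -= 1
            right = 0
            x = j + 1
            while x < len(seq) and not mismatch[x]:
                right += 1
                x += 1
            run = tuple(matrix.markers[idxs[x]].id for x in range(i, j + 1))
            run_state = seq[i]
            klass = "misplaced_proximal" if run_state == p_state and i >= k else (
                "misplaced_distal" if run_state == d_state and j < k else None)
            if left >= min_flank and right >= min_flank and klass is not None:
                candidates.append((pid, run, klass))
            else:
                errors.extend((pid, mid) for mid in run)
            i = j + 1
    return candidates, errors


def classify_discrepancies(matrix: InheritanceMatrix, scan: CrossoverScan,
                           min_flank: int = 3) -> DiagnosticsResult:
    """Flag marker runs whose segregation conflicts with their assembly block.

    For each recombinant progeny (any progeny with a located crossover in
    ``scan``), the minimal-crossover model — one crossover unless more are
    forced — is fit to its informative state sequence.  Contiguous runs of
    mismatching markers flanked on both sides by at least ``min_flank``
    consecutive model-consistent markers are candidate discrepancies: a run
    matching the proximal-side state while assembled distal is
    ``misplaced_proximal``, and vice versa.  Isolated conflicts without
    such flanking are reported as potential genotyping errors instead.

    Because a single progeny's one-crossover fit can be ambiguous when its
    crossover lands near a displaced block, candidates are resolved
    iteratively: the best-supported run (most flagging progeny, then
    longest) is accepted, its markers are masked, and all progeny are
    re-fit — exactly the mask-and-reassess reasoning used when a
    recombinant is read by eye.  Artifact candidates disappear once the
    true displaced run is masked.  Clean data yield no flags.
    """
    recombinants = sorted({e.progeny_id for e in scan.events} |
                          {e.progeny_id for e in scan.raw_events})
    accepted: List[DiscrepancyFlag] = []
    excluded: set = set()
    errors: List[Tuple[str, str]] = []
    for _ in range(len(matrix.markers) + 1):
        candidates, errors = _per_progeny_candidates(matrix, recombinants,
                                                     frozenset(excluded), min_flank)
        if not candidates:
            break
        groups: Dict[tuple, Dict[str, list]] = {}
        for pid, run, klass in candidates:
            g = groups.setdefault(run, {"progeny": [], "classes": []})
            g["progeny"].append(pid)
            g["classes"].append(klass)
        best_run = max(groups, key=lambda r: (len(groups[r]["progeny"]), len(r), r))
        g = groups[best_run]
        klass = max(sorted(set(g["classes"])), key=g["classes"].count)
        run_markers = [matrix.marker_by_id(mid) for mid in best_run]
        accepted.append(DiscrepancyFlag(
            marker_ids=list(best_run),
            positions=(run_markers[0].pos_bp, run_markers[-1].pos_bp),
            klass=klass,
            progeny_id=",".join(sorted(g["progeny"])),
            evidence=(f"{len(best_run)} markers segregate with the "
                      f"{'proximal' if klass == 'misplaced_proximal' else 'distal'} block "
                      f"in {len(g['progeny'])} recombinant progeny"),
        ))
        excluded.update(best_run)
    accepted.sort(key=lambda f: f.positions)
    return DiagnosticsResult(flags=accepted, genotyping_error_candidates=sorted(set(errors)))


def corroborate_discrepancies(result: DiagnosticsResult,
                              dam_matrix: InheritanceMatrix) -> DiagnosticsResult:
    """Cross-check flagged runs against dam-meiosis co-segregation.

    For each flagged run present in a dam-informative matrix, record which
    positional block of dam-informative markers the run's inheritance
    column travels with (majority state agreement with proximal vs distal
    halves); stored in ``corroboration`` as "proximal"/"distal".
    """
    ids = {m.id: j for j, m in enumerate(dam_matrix.markers)}
    n = len(dam_matrix.markers)
    if n < 4:
        return result
    half = n // 2
    for flag in result.flags:
        cols = [ids[mid] for mid in flag.marker_ids if mid in ids]
        if not cols:
            continue
        agree_prox = agree_dist = total = 0
        for p in dam_matrix.progeny:
            states = dam_matrix.states_for(p.id)
            run_states = [states[c] for c in cols if states[c] in ("X", "Y")]
            if not run_states:
                continue
            run_state = max(set(run_states), key=run_states.count)
            prox = [s for s in states[:half] if s in ("X", "Y")]
            dist = [s for s in states[half:] if s in ("X", "Y")]
            if prox:
                agree_prox += run_state == max(set(prox), key=prox.count)
            if dist:
                agree_dist += run_state == max(set(dist), key=dist.count)
            total += 1
        if total:
            flag.corroboration = "proximal" if agree_prox >= agree_dist else "distal"
    return result


# ---------------------------------------------------------------------------
# Y-duplication segregation signature
# ---------------------------------------------------------------------------

@dataclass
class DuplicationCall:
    marker: Marker
    flagged: bool
    inferred_configuration: Optional[str]
    null_probability: float
    female_fit_p: Optional[float]
    underpowered: bool = False
    notes: str = ""


def _cross_probs(sire: Genotype, dam: Genotype) -> Dict[Genotype, float]:
    probs: Dict[Genotype, float] = {}
    for pa in sire.alleles:
        for ma in dam.alleles:
            g = Genotype.of(pa, ma)
            probs[g] = probs.get(g, 0.0) + 0.25
    return probs


def duplication_signature(sibship: Sibship, marker_id: str,
                          alpha: float = 1e-3) -> DuplicationCall:
    """Test one marker for the Y-borne-duplication segregation signature.

    The null is single-locus Mendelian transmission from the observed
    parental genotypes; ``null_probability`` is the multinomial point
    probability of the observed male-progeny genotype counts under that
    null.  The marker is flagged when (i) the null probability falls below
    ``alpha``, (ii) every called male progeny is heterozygous (the classes
    not expected under a duplicated Y must be empty), and (iii) female
    progeny frequencies fit transmission of the dam's alleles (two-sided
    binomial test not rejected at 0.05, no unexpected female classes).
    Sibships with fewer than 5 called male progeny are returned
    underpowered and never flagged.
    """
    t = sibship.table
    marker = t.marker(marker_id)
    sire_g = t.get(sibship.sire.id, marker_id)
    dam_g = t.get(sibship.dam.id, marker_id)
    if dam_g.is_missing:
        raise ValueError(f"duplication_signature: dam genotype missing at {marker_id}")
    if sire_g.is_missing or not sire_g.is_het:
        return DuplicationCall(marker=marker, flagged=False, inferred_configuration=None,
                               null_probability=1.0, female_fit_p=None,
                               notes="sire not heterozygous: no signature testable")

    males = [t.get(p.id, marker_id) for p in sibship.progeny if p.sex == "male"]
    females = [t.get(p.id, marker_id) for p in sibship.progeny if p.sex == "female"]
    males = [g for g in males if not g.is_missing]
    females = [g for g in females if not g.is_missing]

    probs = _cross_probs(sire_g, dam_g)
    classes = sorted(probs, key=str)
    counts = [sum(1 for g in males if g == c) for c in classes]
    n_off_class = len(males) - sum(counts)
    if n_off_class:  # genotypes impossible under the cross: null probability 0
        null_p = 0.0
    else:
        null_p = float(stats.multinomial.pmf(counts, n=len(males), p=[probs[c] for c in classes]))

    if len(males) < 5:
        return DuplicationCall(marker=marker, flagged=False, inferred_configuration=None,
                               null_probability=null_p, female_fit_p=None,
                               underpowered=True, notes=f"only {len(males)} called males")

    all_males_het = all(g.is_het for g in males)

    # infer the paternal X allele from the female progeny: females carry
    # (x, maternal allele); pick the sire allele consistent with every female
    female_fit_p: Optional[float] = None
    x_allele = None
    if females:
        for cand in sire_g.alleles:
            expected = {Genotype.of(cand, ma) for ma in dam_g.alleles}
            if all(g in expected for g in females):
                x_allele = cand
                break
        if x_allele is not None and dam_g.is_het:
            d1, d2 = dam_g.alleles
            k = sum(1 for g in females if g == Genotype.of(x_allele, d1))
            female_fit_p = float(stats.binomtest(k, len(females), 0.5).pvalue)
        elif x_allele is not None:
            female_fit_p = 1.0  # dam homozygous: a single expected class

    females_fit = female_fit_p is not None and female_fit_p >= 0.05
    flagged = null_p < alpha and all_males_het and (not females or females_fit)

    config = None
    if flagged:
        if x_allele is None:
            x_allele = sire_g.alleles[0]
        y_allele = [a for a in sire_g.alleles if a != x_allele][0]
        config = f"X^{x_allele}/Y^{y_allele} Y^{x_allele}"
    return DuplicationCall(marker=marker, flagged=flagged, inferred_configuration=config,
                           null_probability=null_p, female_fit_p=female_fit_p)


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float
    target_position: Optional[float] = None


def read_hit_table(path) -> pd.DataFrame:
    """Read a 4-column hit-table TSV: query, target, score[, target_position]."""
    df = pd.read_csv(path, sep="\t")
    required = {"query", "target", "score"}
    if not required <= set(df.columns):
        raise FormatError(f"hit table {path}: missing columns {sorted(required - set(df.columns))}")
    return df


def _best_hits(df: pd.DataFrame) -> Dict[str, Tuple[str, float]]:
    dup = df.duplicated(subset=["query", "target"], keep=False)
    if dup.any():
        logger.warning("hit table: %d duplicate (query,target) rows; keeping highest score",
                       int(dup.sum()))
        df = df.sort_values("score").drop_duplicates(subset=["query", "target"], keep="last")
    best: Dict[str, Tuple[str, float]] = {}
    # deterministic tie-break: highest score, then lexicographically smallest target
    for q, grp in df.groupby("query"):
        ordered = grp.sort_values(["score", "target"], ascending=[False, True])
        best[q] = (ordered.iloc[0]["target"], float(ordered.iloc[0]["score"]))
    return best


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> List[RbhPair]:
    """Pairs of genes that are each other's best-scoring hit.

    Ties within a query are broken deterministically by (score desc, target
    id asc).  The output is symmetric under swapping the two tables (up to
    the roles of ``gene_a``/``gene_b``).
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pos_col = "target_position" if "target_position" in hits_ab.columns else None
    pos_lookup = {}
    if pos_col:
        for _, row in hits_ab.iterrows():
            pos_lookup[(row["query"], row["target"])] = float(row[pos_col])
    pairs = []
    for a in sorted(best_ab):
        b, s_ab = best_ab[a]
        if b in best_ba and best_ba[b][0] == a:
            pairs.append(RbhPair(gene_a=a, gene_b=b, score_ab=s_ab, score_ba=best_ba[b][1],
                                 target_position=pos_lookup.get((a, b))))
    return pairs


def rbh_scaffold_summary(pairs: Sequence[RbhPair], scaffold_of: Dict[str, str]) -> pd.DataFrame:
    """Summarise RBH gene placements per query scaffold.

    ``scaffold_of`` maps gene_a ids to their scaffold; the summary gives
    the RBH gene count and the min/median/max target position per scaffold
    (supporting claims that a scaffold belongs to, e.g., the terminal
    region of the homologous chromosome).
    """
    rows = []
    by_scaf: Dict[str, List[RbhPair]] = {}
    for p in pairs:
        scaf = scaffold_of.get(p.gene_a)
        if scaf is not None:
            by_scaf.setdefault(scaf, []).append(p)
    for scaf in sorted(by_scaf):
        ps = [p.target_position for p in by_scaf[scaf] if p.target_position is not None]
        rows.append({
            "scaffold": scaf,
            "n_rbh_genes": len(by_scaf[scaf]),
            "target_pos_min": min(ps) if ps else np.nan,
            "target_pos_median": float(np.median(ps)) if ps else np.nan,
            "target_pos_max": max(ps) if ps else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GC windows
# ---------------------------------------------------------------------------

@dataclass
class GcProfile:
    windows: List[Tuple[int, int, float, int]]  # (start, end, gc_fraction, n_counted)

    def total_gc(self) -> float:
        return sum(gc * n for (_, _, gc, n) in self.windows)


def gc_windows(seq: str, window_bp: int) -> GcProfile:
    """Windowed GC content over half-open tiling windows.

    ``gc_fraction`` = (G+C) / (A+C+G+T counted bases); ambiguity codes are
    excluded from the denominator.  The final partial window is included;
    an empty sequence yields an empty profile.  The identity
    sum(gc_fraction x n_counted) == global G+C count always holds.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    seq = seq.upper()
    windows = []
    for start in range(0, len(seq), window_bp):
        chunk = seq[start:start + window_bp]
        gc = chunk.count("G") + chunk.count("C")
        at = chunk.count("A") + chunk.count("T")
        n = gc + at
        windows.append((start, start + len(chunk), (gc / n) if n else 0.0, n))
    return GcProfile(windows=windows)
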