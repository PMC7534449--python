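"""Domain types and file formats for XY sex-linkage mapping.

This module houses the shared containers used by every pipeline stage —
markers, unordered genotypes, individuals, genotype tables, population
samples — together with readers for the plain-text formats the pipeline
consumes (genotype TSV, marker-map TSV, pedigree TSV, VCF, FASTA) and a
deterministic report writer.

Conventions
-----------
* Assembly coordinates are 1-based inclusive throughout.  Intervals between
  markers are reported as closed (proximal flank, distal flank) position
  pairs; nothing is interpolated between markers.
* Genotypes are unordered allele pairs; ``"A/G"`` and ``"G/A"`` parse to the
  same value.  Missing calls (``"./."``) are first-class and are excluded
  marker-wise from every downstream statistic.
* Microsatellite alleles are identified by their fragment-length label
  (e.g. ``"264"``); equality is string equality of the label.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sdrmap")

__all__ = [
    "Marker",
    "Genotype",
    "MISSING",
    "Individual",
    "GenotypeTable",
    "PopulationSample",
    "UnresolvedFamily",
    "FormatError",
    "read_marker_map",
    "read_genotype_tsv",
    "read_vcf",
    "read_pedigree",
    "read_fasta",
    "write_report",
    "write_genotype_tsv",
    "format_percent",
    "round_half_up",
]

SNP_ALLELES = frozenset("ACGT")
SEXES = ("male", "female", "unknown")
ROLES = ("sire", "dam", "progeny", "candidate_parent", "population_sample")


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent input files."""


@dataclass(frozen=True, order=True)
class Marker:
    """A mapped marker on an assembly: SNP or microsatellite.

    ``alleles`` is the marker's allele universe: SNP bases, or
    microsatellite fragment lengths in bp given as strings (e.g. ``"264"``).
    """

    chrom: str
    pos_bp: int
    id: str = dataclasses.field(compare=False)
    kind: str = dataclasses.field(default="snp", compare=False)
    alleles: frozenset = dataclasses.field(default=frozenset(), compare=False)

    def __post_init__(self):
        if self.pos_bp < 1:
            raise FormatError(f"marker {self.id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.kind not in ("snp", "microsatellite"):
            raise FormatError(f"marker {self.id}: unknown kind {self.kind!r}")
        if self.alleles:
            if self.kind == "snp" and not set(self.alleles) <= SNP_ALLELES:
                raise FormatError(f"marker {self.id}: SNP alleles must be in ACGT, got {sorted(self.alleles)}")
            if self.kind == "microsatellite":
                for a in self.alleles:
                    try:
                        ok = int(a) > 0
                    except ValueError:
                        ok = False
                    if not ok:
                        raise FormatError(
                            f"marker {self.id}: microsatellite allele label {a!r} "
                            "does not parse as a positive integer"
                        )


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid allele pair, or missing.

    ``Genotype.of("G", "A") == Genotype.of("A", "G")``.
    """

    alleles: Optional[tuple] = None

    @classmethod
    def of(cls, a: str, b: str) -> "Genotype":
        return cls(tuple(sorted((str(a), str(b)))))

    @classmethod
    def from_string(cls, cell: str, sep: str = "/") -> "Genotype":
        cell = cell.strip()
        if cell in ("", ".", "./.", ".|.", "NA"):
            return MISSING
        parts = cell.replace("|", sep).split(sep)
        if len(parts) != 2 or "." in parts:
            return MISSING
        return cls.of(*parts)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def __str__(self) -> str:
        if self.alleles is None:
            return "./."
        return "/".join(self.alleles)

    def __contains__(self, allele: str) -> bool:
        return self.alleles is not None and allele in self.alleles


MISSING = Genotype(None)


@dataclass
class Individual:
    id: str
    sex: str = "unknown"
    family_id: Optional[str] = None
    role: str = "population_sample"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise FormatError(f"individual {self.id}: unknown sex {self.sex!r}")
        if self.role not in ROLES:
            raise FormatError(f"individual {self.id}: unknown role {self.role!r}")
        if self.role == "progeny" and self.family_id is None:
            raise FormatError(f"progeny {self.id} has no family_id")


class GenotypeTable:
    """Individuals x markers container of unordered genotype calls.

    Markers are kept sorted by (chrom, pos_bp); calls live in a dense object
    array aligned with ``self.individuals`` (rows) and ``self.markers``
    (columns).  Every non-missing call's alleles must belong to its marker's
    allele set (when the marker declares one).
    """

    def __init__(self, markers: Sequence[Marker], individuals: Sequence[Individual],
                 calls: Optional[np.ndarray] = None, validate: bool = True):
        order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos_bp))
        self.markers: list[Marker] = [markers[i] for i in order]
        self.individuals: list[Individual] = list(individuals)
        if calls is None:
            self.calls = np.full((len(individuals), len(self.markers)), MISSING, dtype=object)
        else:
            if calls.shape != (len(individuals), len(markers)):
                raise FormatError("calls array shape does not match individuals x markers")
            self.calls = calls[:, order].copy()
        self._m_index = {m.id: j for j, m in enumerate(self.markers)}
        self._i_index = {ind.id: i for i, ind in enumerate(self.individuals)}
        if len(self._m_index) != len(self.markers):
            raise FormatError("duplicate marker ids")
        if len(self._i_index) != len(self.individuals):
            raise FormatError("duplicate individual ids")
        if validate:
            self._validate()

    def _validate(self):
        for j, m in enumerate(self.markers):
            if not m.alleles:
                continue
            for i, ind in enumerate(self.individuals):
                g = self.calls[i, j]
                if not g.is_missing and not set(g.alleles) <= set(m.alleles):
                    raise FormatError(
                        f"call {g} for individual {ind.id} at marker {m.id}: "
                        f"allele not in marker allele set {sorted(m.alleles)}"
                    )

    # -- accessors -------------------------------------------------------
    def marker(self, marker_id: str) -> Marker:
        return self.markers[self._m_index[marker_id]]

    def individual(self, ind_id: str) -> Individual:
        return self.individuals[self._i_index[ind_id]]

    def get(self, ind_id: str, marker_id: str) -> Genotype:
        return self.calls[self._i_index[ind_id], self._m_index[marker_id]]

    def set(self, ind_id: str, marker_id: str, genotype: Genotype) -> None:
        self.calls[self._i_index[ind_id], self._m_index[marker_id]] = genotype

    def calls_at(self, marker_id: str) -> list:
        """All calls at one marker, aligned with ``self.individuals``."""
        return list(self.calls[:, self._m_index[marker_id]])

    def individuals_with_sex(self, sex: str) -> list:
        return [ind for ind in self.individuals if ind.sex == sex]

    def subset(self, ind_ids: Iterable[str]) -> "GenotypeTable":
        rows = [self._i_index[i] for i in ind_ids]
        return GenotypeTable(
            self.markers,
            [self.individuals[r] for r in rows],
            self.calls[rows, :],
            validate=False,
        )

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class PopulationSample:
    """A sexed population sample for between-sex statistics."""

    population_id: str
    river: str
    predation: str  # HP / LP / NA
    table: GenotypeTable

    def __post_init__(self):
        n_m = len(self.table.individuals_with_sex("male"))
        n_f = len(self.table.individuals_with_sex("female"))
        if n_m < 1 or n_f < 1:
            raise FormatError(
                f"population {self.population_id}: need at least one male and one "
                f"female for between-sex statistics (got {n_m} m, {n_f} f)"
            )


@dataclass
class UnresolvedFamily:
    """A breeding group with multiple candidate parents, pending parentage assignment."""

    family_id: str
    candidate_sires: list
    candidate_dams: list
    progeny: list


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_marker_map(map_path) -> list:
    """Read a marker map TSV with columns id, chrom, pos_bp, kind[, alleles].

    The optional ``alleles`` column is comma-separated; when absent the
    marker's allele set is inferred later from observed calls.
    """
    df = pd.read_csv(map_path, sep="\t", dtype=str)
    required = {"id", "chrom", "pos_bp", "kind"}
    if not required <= set(df.columns):
        raise FormatError(f"marker map {map_path}: missing columns {sorted(required - set(df.columns))}")
    markers = []
    for _, row in df.iterrows():
        alleles = frozenset()
        if "alleles" in df.columns and isinstance(row.get("alleles"), str):
            alleles = frozenset(row["alleles"].split(","))
        markers.append(Marker(id=row["id"], chrom=row["chrom"], pos_bp=int(row["pos_bp"]),
                              kind=row["kind"], alleles=alleles))
    return markers


def _infer_alleles(marker: Marker, calls: Iterable[Genotype]) -> Marker:
    observed = set()
    for g in calls:
        if not g.is_missing:
            observed.update(g.alleles)
    return dataclasses.replace(marker, alleles=frozenset(observed))


def read_genotype_tsv(path, map_path) -> GenotypeTable:
    """Read a genotype TSV (rows = individuals, columns = markers).

    Expected header: ``id  sex  family_id  role  <marker1>  <marker2> ...``
    with genotype cells like ``A/G`` or ``./.``.  Markers must all be present
    in the map; markers come back sorted by (chrom, pos_bp).
    """
    markers = {m.id: m for m in read_marker_map(map_path)}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta_cols = ["id", "sex", "family_id", "role"]
    if list(df.columns[:4]) != meta_cols:
        raise FormatError(f"{path}: first four columns must be {meta_cols}")
    marker_ids = list(df.columns[4:])
    for mid in marker_ids:
        if mid not in markers:
            raise FormatError(f"{path}: marker {mid} absent from map {map_path}")
    individuals = []
    for _, row in df.iterrows():
        fam = row["family_id"] if row["family_id"] not in ("", ".", "NA") else None
        individuals.append(Individual(id=row["id"], sex=row["sex"] or "unknown",
                                      family_id=fam, role=row["role"] or "population_sample"))
    used = [markers[mid] for mid in marker_ids]
    calls = np.full((len(individuals), len(used)), MISSING, dtype=object)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, mid in enumerate(marker_ids):
            g = Genotype.from_string(row[mid])
            if not g.is_missing and used[j].alleles and not set(g.alleles) <= set(used[j].alleles):
                raise FormatError(
                    f"{path}: unknown allele label in cell {row[mid]!r} at marker {mid}, "
                    f"row for individual {row['id']}"
                )
            calls[i, j] = g
    # infer allele sets for markers lacking a declared one
    used = [
        m if m.alleles else _infer_alleles(m, calls[:, j])
        for j, m in enumerate(used)
    ]
    return GenotypeTable(used, individuals, calls)


def read_vcf(path, sex_map_path) -> GenotypeTable:
    """Read biallelic SNP records from a VCF into a GenotypeTable.

    Diploid GT fields become unordered genotypes; half-calls and non-diploid
    GTs become missing.  Multiallelic records are skipped (count logged).
    Samples absent from the sex map get sex "unknown" with a warning.
    """
    from cyvcf2 import VCF

    sex_df = pd.read_csv(sex_map_path, sep="\t", dtype=str, header=None, names=["id", "sex"])
    sex_by_id = dict(zip(sex_df["id"], sex_df["sex"]))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    individuals = []
    for s in samples:
        sex = sex_by_id.get(s)
        if sex is None:
            logger.warning("VCF sample %s absent from sex map; sex set to unknown", s)
            sex = "unknown"
        individuals.append(Individual(id=s, sex=sex, role="population_sample"))

    markers, columns = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in SNP_ALLELES or var.ALT[0] not in SNP_ALLELES:
            n_multi += 1
            continue
        alleles = (var.REF, var.ALT[0])
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        markers.append(Marker(id=mid, chrom=var.CHROM, pos_bp=var.POS, kind="snp",
                              alleles=frozenset(alleles)))
        col = []
        for gt in var.genotypes:
            a, b = gt[0], gt[1]
            if len(gt) != 3 or a < 0 or b < 0:
                col.append(MISSING)
            else:
                col.append(Genotype.of(alleles[a], alleles[b]))
        columns.append(col)
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_multi)
    calls = np.empty((len(samples), len(markers)), dtype=object)
    for j, col in enumerate(columns):
        calls[:, j] = col
    return GenotypeTable(markers, individuals, calls)


def read_pedigree(path):
    """Read a pedigree TSV (family_id, id, role, sex).

    Returns ``(sibships, unresolved)``: families with exactly one sire and
    one dam become shell sibships (genotype table attached later); families
    with multiple candidate parents are returned as
    :class:`UnresolvedFamily` for parentage assignment.
    """
    from .family_mapping import Sibship  # deferred: avoids an import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["family_id", "id", "role", "sex"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: columns must start with {required}")
    sibships, unresolved = [], []
    for fam_id, fam in df.groupby("family_id", sort=True):
        sires, dams, progeny = [], [], []
        for _, row in fam.iterrows():
            sex = row["sex"] or "unknown"
            role = row["role"]
            ind = Individual(id=row["id"], sex=sex,
                             family_id=fam_id if role == "progeny" else fam_id,
                             role=role if role in ROLES else "candidate_parent")
            if role == "sire":
                sires.append(ind)
            elif role == "dam":
                dams.append(ind)
            elif role == "progeny":
                progeny.append(ind)
            else:
                raise FormatError(f"{path}: unknown role {role!r} for {row['id']}")
        if progeny and not (sires or dams):
            raise FormatError(f"family {fam_id}: progeny listed with no candidate parents")
        if len(sires) == 1 and len(dams) == 1:
            sibships.append(Sibship(sire=sires[0], dam=dams[0], progeny=progeny, table=None))
        else:
            unresolved.append(UnresolvedFamily(family_id=fam_id, candidate_sires=sires,
                                               candidate_dams=dams, progeny=progeny))
    return sibships, unresolved


_IUPAC = frozenset("ACGTURYSWKMBDHVN-")


def read_fasta(path) -> dict:
    """Read FASTA into ``{record id: uppercase sequence}``; rejects non-IUPAC characters."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(f"record {rec.id}: non-IUPAC characters {sorted(bad)}")
        records[rec.id] = seq
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def _as_rows(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = []
    for r in results:
        if dataclasses.is_dataclass(r):
            d = {}
            for f in dataclasses.fields(r):
                v = getattr(r, f.name)
                if isinstance(v, Marker):
                    d["marker"] = v.id
                    d["pos_bp"] = v.pos_bp
                elif isinstance(v, (list, tuple, dict, frozenset, set)):
                    d[f.name] = json.dumps(sorted(v) if isinstance(v, (set, frozenset)) else list(v) if isinstance(v, (list, tuple)) else v)
                else:
                    d[f.name] = v
            rows.append(d)
        elif isinstance(r, Mapping):
            rows.append(dict(r))
        else:
            raise FormatError(f"cannot serialise result of type {type(r).__name__}")
    return pd.DataFrame(rows)


def write_report(results, path, columns: Optional[Sequence[str]] = None,
                 metadata: Optional[Mapping] = None) -> None:
    """Write a stage output as a deterministic TSV plus a JSON metadata sidecar.

    Floats are formatted to 6 significant digits; column order is stable;
    the sidecar (``<path>.meta.json``) records seed/config hash/version when
    supplied.  Writing the same input twice yields byte-identical files.
    """
    path = Path(path)
    df = _as_rows(results)
    if columns is not None:
        if df.empty:
            df = pd.DataFrame(columns=list(columns))
        else:
            df = df[list(columns)]
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    from . import __version__

    meta = {"version": __version__, "n_rows": int(len(df))}
    if metadata:
        meta.update(metadata)
    if "config" in meta and not isinstance(meta["config"], str):
        blob = json.dumps(meta["config"], sort_keys=True, default=str)
        meta["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        del meta["config"]
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
        fh.write("\n")


def write_genotype_tsv(table: GenotypeTable, path, map_path=None) -> None:
    """Write a GenotypeTable (and optionally its marker map) in the dialect
    :func:`read_genotype_tsv` reads, so that write-then-read round-trips."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "sex", "family_id", "role"] + [m.id for m in table.markers]) + "\n")
        for i, ind in enumerate(table.individuals):
            cells = [str(table.calls[i, j]) for j in range(len(table.markers))]
            fh.write("\t".join([ind.id, ind.sex, ind.family_id or ".", ind.role] + cells) + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            fh.write("id\tchrom\tpos_bp\tkind\talleles\n")
            for m in table.markers:
                fh.write(f"{m.id}\t{m.chrom}\t{m.pos_bp}\t{m.kind}\t{','.join(sorted(m.alleles))}\n")


# ---------------------------------------------------------------------------
# formatting helpers
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    """Round half away from zero (so 16.5 -> 17), unlike banker's rounding."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_percent(fraction: float) -> str:
    """Report convention: percentages round half-up to integers, except
    rates below 1%, which get two decimals (e.g. 0.28)."""
    pct = 100.0 * fraction
    if 0 < pct < 1:
        return f"{pct:.2f}"
    return str(round_half_up(pct))
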