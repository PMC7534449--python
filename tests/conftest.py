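import numpy as np
import pytest

from sdrmap.io_formats import Genotype, GenotypeTable, Individual, Marker, MISSING
from sdrmap.family_mapping import InheritanceMatrix, Sibship
from sdrmap.synthetic_data import make_study_fixtures


@pytest.fixture(scope="session")
def bundle():
    return make_study_fixtures()


def build_sibship(marker_pos, progeny_states, family_id="FAM", sire_gt=("A", "G"),
                  dam_gt=("A", "A")):
    """Construct a sibship from explicit per-progeny paternal states.

    ``progeny_states`` maps progeny id -> (sex, list of 'X'/'Y' states, one
    per marker).  Sire X allele is sire_gt[0], Y allele sire_gt[1]; the dam
    is homozygous so every marker is informative.
    """
    markers = [Marker(id=f"{family_id}_m{j:03d}", chrom="LG12", pos_bp=p, kind="snp",
                      alleles=frozenset({"A", "G"}))
               for j, p in enumerate(marker_pos)]
    sire = Individual(id=f"{family_id}_sire", sex="male", family_id=family_id, role="sire")
    dam = Individual(id=f"{family_id}_dam", sex="female", family_id=family_id, role="dam")
    progeny = [Individual(id=pid, sex=sex, family_id=family_id, role="progeny")
               for pid, (sex, _) in progeny_states.items()]
    individuals = [sire, dam] + progeny
    calls = np.full((len(individuals), len(markers)), MISSING, dtype=object)
    calls[0, :] = Genotype.of(*sire_gt)
    calls[1, :] = Genotype.of(*dam_gt)
    for i, (pid, (sex, states)) in enumerate(progeny_states.items()):
        for j, s in enumerate(states):
            pat = sire_gt[1] if s == "Y" else sire_gt[0]
            calls[2 + i, j] = Genotype.of(pat, dam_gt[0])
    table = GenotypeTable(markers, individuals, calls, validate=False)
    return Sibship(sire=sire, dam=dam, progeny=progeny, table=table, family_id=family_id)


def build_matrix(marker_pos, progeny_states):
    """Directly build an InheritanceMatrix from per-progeny state strings."""
    markers = [Marker(id=f"m{j:03d}", chrom="LG12", pos_bp=p, kind="snp",
                      alleles=frozenset({"A", "G"}))
               for j, p in enumerate(marker_pos)]
    progeny = [Individual(id=pid, sex=sex, family_id="F", role="progeny")
               for pid, (sex, _) in progeny_states.items()]
    states = np.array([list(st) for _, (_, st) in progeny_states.items()], dtype=object)
    return InheritanceMatrix(progeny, markers, states)
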