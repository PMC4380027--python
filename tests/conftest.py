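"""Shared fixtures: tiny peptide sets and synthetic datasets, all generated
in-process so the suite needs no data files."""

from __future__ import annotations

import numpy as np
import pytest

from ampfam import (
    AAIndexProperty,
    AAIndexTable,
    FamilySpec,
    Peptide,
    PlantedEnrichment,
    SyntheticSpec,
    generate,
)
from ampfam.io_formats import CANONICAL_AA

#: the published worked example: basic residues at 1-based positions
#: 2, 4, 8, 15, 16, 19 -> gaps 2, 4, 7, 1, 3 -> bins (1, 3, 1, 0, 0, 0)
EXAMPLE_SEQUENCE = "ARMRAASKAALLMAHKNAK"


def make_property(accession: str, values, description: str = "test scale"):
    """Property scale from a 20-vector in alphabetical residue order."""
    return AAIndexProperty(
        accession=accession,
        description=description,
        values={aa: float(v) for aa, v in zip(CANONICAL_AA, values)},
    )


@pytest.fixture
def toy_table():
    """Three hand-made property scales (index, doubled copy, reversed)."""
    base = np.arange(20, dtype=float)
    return AAIndexTable(
        [
            make_property("TOY1", base),
            make_property("TOY2", 2 * base + 3),  # r = 1 with TOY1
            make_property("TOY3", base[::-1] ** 2),
        ]
    )


def recovery_dataset(seed: int):
    """The frozen parameter-recovery conditions: 3 families of 20 peptides
    plus 40 background, lengths 30-60, target family fam1 planted with
    moderate (weight 8) enrichments of D in n2, S in n4 and T in C."""
    w = 8.0
    fam1 = FamilySpec(
        "fam1",
        20,
        enrichments=[
            PlantedEnrichment("n2", "D", w),
            PlantedEnrichment("n4", "S", w),
            PlantedEnrichment("C", "T", w),
        ],
    )
    fam2 = FamilySpec("fam2", 20, enrichments=[PlantedEnrichment("n1", "G", w)])
    fam3 = FamilySpec("fam3", 20, enrichments=[PlantedEnrichment("C", "A", w)])
    spec = SyntheticSpec(
        families=[fam1, fam2, fam3],
        n_background=40,
        length_range=(30, 60),
        d_N=10,
        d_C=10,
        seed=seed,
    )
    return generate(spec)


@pytest.fixture
def small_labeled_dataset():
    """One seeded draw of the recovery conditions (peptides + truth)."""
    return recovery_dataset(seed=0)


def identical_family(n: int = 4, sequence: str = "ARNDCQEGHILKMFPSTWYVAR"):
    return [Peptide(f"id{i}", sequence, family="fam") for i in range(n)]
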