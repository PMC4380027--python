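"""The 184-dimensional compositional encoding of a peptide.

Layout (fixed order, independent of input order):

* amino-acid composition over n1, n2, n3, n4, M, C and the full sequence
  (7 regions x 20 residues = 140 features),
* twin-residue composition in M — adjacent identical pairs, overlapping,
  normalised by ``len(M) - 1`` (20 features),
* six-bin distance frequencies of the basic residues (R, K, H) over the
  concatenated N block n1+n2+n3+n4 and over M (12 features),
* six-bin distance frequencies of the hydrophobic residues
  (I, V, L, F, M, A, G, W, P) over M (6 features),
* six-bin distance frequencies of the remaining residues
  (D, N, E, Q, Y, S, T, C) over M (6 features).

The distance ``H`` between successive class members (difference of their
positions) is binned as H=1, 1<H<=6, 6<H<=11, 11<H<=16, 16<H<=21, H>21;
the bins hold raw counts.  For the sequence ARMRAASKAALLMAHKNAK the basic
residues sit at positions 2, 4, 8, 15, 16, 19 (1-based), the gaps are
2, 4, 7, 1, 3 and the bin vector is (1, 3, 1, 0, 0, 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import (
    CANONICAL_AA,
    FeatureDescriptor,
    FeatureMatrix,
    Peptide,
)
from .regions import FULL, REGION_NAMES, RegionPartition, partition, region_residues

_CANONICAL_SET = frozenset(CANONICAL_AA)

BASIC_RESIDUES = frozenset("RKH")
HYDROPHOBIC_RESIDUES = frozenset("IVLFMAGWP")
OTHER_RESIDUES = frozenset("DNEQYSTC")

RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "basic": BASIC_RESIDUES,
    "hydrophobic": HYDROPHOBIC_RESIDUES,
    "other": OTHER_RESIDUES,
}

#: upper edges of the distance bins; the first bin is exactly H == 1
DISTANCE_BIN_EDGES = (1, 6, 11, 16, 21)
N_DISTANCE_BINS = 6

#: the N block used for basic-residue distances is n1+n2+n3+n4 concatenated
N_BLOCK = "N"

N_BASIC_FEATURES = 184


def _check_canonical(residues: str) -> None:
    bad = set(residues) - _CANONICAL_SET
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)}")


def composition(residues: str) -> np.ndarray:
    """Fraction of each canonical residue; empty input yields zeros."""
    _check_canonical(residues)
    counts = np.zeros(20)
    if not residues:
        return counts
    for ch in residues:
        counts[CANONICAL_AA.index(ch)] += 1
    return counts / len(residues)


def twin_composition(residues: str) -> np.ndarray:
    """Overlapping identical-adjacent-pair counts per residue / (len - 1)."""
    _check_canonical(residues)
    counts = np.zeros(20)
    if len(residues) <= 1:
        return counts
    for a, b in zip(residues, residues[1:]):
        if a == b:
            counts[CANONICAL_AA.index(a)] += 1
    return counts / (len(residues) - 1)


def class_gaps(residues: str, members: frozenset[str]) -> list[int]:
    """Gaps between successive occurrences of class members."""
    positions = [i for i, ch in enumerate(residues) if ch in members]
    return [b - a for a, b in zip(positions, positions[1:])]


def distance_frequencies(residues: str, members: frozenset[str]) -> np.ndarray:
    """Six-bin histogram (raw counts) of successive class-member gaps."""
    _check_canonical(residues)
    counts = np.zeros(N_DISTANCE_BINS)
    for gap in class_gaps(residues, members):
        if gap == 1:
            counts[0] += 1
        elif gap <= 6:
            counts[1] += 1
        elif gap <= 11:
            counts[2] += 1
        elif gap <= 16:
            counts[3] += 1
        elif gap <= 21:
            counts[4] += 1
        else:
            counts[5] += 1
    return counts


def basic_descriptors() -> list[FeatureDescriptor]:
    """Descriptor list of the 184 compositional features, in encoding order."""
    desc: list[FeatureDescriptor] = []
    for region in list(REGION_NAMES) + [FULL]:
        for aa in CANONICAL_AA:
            desc.append(FeatureDescriptor(aa, region, "composition"))
    for aa in CANONICAL_AA:
        desc.append(FeatureDescriptor(aa, "M", "twin"))
    for i in range(N_DISTANCE_BINS):
        desc.append(FeatureDescriptor(f"bin{i + 1}", N_BLOCK, "distance_basic"))
    for i in range(N_DISTANCE_BINS):
        desc.append(FeatureDescriptor(f"bin{i + 1}", "M", "distance_basic"))
    for i in range(N_DISTANCE_BINS):
        desc.append(
            FeatureDescriptor(f"bin{i + 1}", "M", "distance_hydrophobic")
        )
    for i in range(N_DISTANCE_BINS):
        desc.append(FeatureDescriptor(f"bin{i + 1}", "M", "distance_other"))
    assert len(desc) == N_BASIC_FEATURES
    return desc


def encode_basic(peptide: Peptide, part: RegionPartition) -> np.ndarray:
    """Encode one peptide as its 184-feature compositional vector."""
    if len(peptide) != part.L:
        raise ValueError(
            f"peptide {peptide.id!r} length {len(peptide)} does not match "
            f"partition L={part.L}"
        )
    blocks: list[np.ndarray] = []
    for region in list(REGION_NAMES) + [FULL]:
        blocks.append(composition(region_residues(peptide, part, region)))
    m_res = region_residues(peptide, part, "M")
    blocks.append(twin_composition(m_res))
    n_block = "".join(
        region_residues(peptide, part, r) for r in ("n1", "n2", "n3", "n4")
    )
    blocks.append(distance_frequencies(n_block, BASIC_RESIDUES))
    blocks.append(distance_frequencies(m_res, BASIC_RESIDUES))
    blocks.append(distance_frequencies(m_res, HYDROPHOBIC_RESIDUES))
    blocks.append(distance_frequencies(m_res, OTHER_RESIDUES))
    vec = np.concatenate(blocks)
    assert vec.shape == (N_BASIC_FEATURES,)
    return vec


def encode_dataset(
    peptides: list[Peptide], d_N: int, d_C: int
) -> FeatureMatrix:
    """Encode a dataset: one 184-feature row per peptide.

    Feature order is fixed by :func:`basic_descriptors`; row order follows
    the input peptide order.
    """
    desc = basic_descriptors()
    columns = [d.column for d in desc]
    rows = [encode_basic(p, partition(len(p), d_N, d_C)) for p in peptides]
    data = pd.DataFrame(
        np.array(rows).reshape(len(peptides), N_BASIC_FEATURES),
        index=[p.id for p in peptides],
        columns=columns,
        dtype=float,
    )
    labels = pd.Series(
        [p.family if p.family is not None else "" for p in peptides],
        index=data.index,
    )
    return FeatureMatrix(data=data, labels=labels)
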