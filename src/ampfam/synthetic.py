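"""Synthetic peptide families with planted, recoverable signals.

Stands in for a curated antimicrobial-peptide collection: every pipeline
stage can be exercised, and its output checked against known ground
truth, without any external database.  Two kinds of signal are planted
per family:

* **compositional enrichment** — inside one region, a residue's sampling
  weight is multiplied by a factor, so the family's composition feature
  for that (region, residue) shifts away from the background mean;
* **property restriction** — inside one region, only residues whose
  value under a named property scale falls in a given interval are
  sampled, so that (property, region) becomes restrictive for the family
  and its median feature separates the family from the background.

Background peptides are sampled with no bias from the background residue
distribution (uniform over the 20 residues by default).  Lengths are
drawn uniformly from the configured range; the default range 10–212
spans the lengths typical of mature antimicrobial peptides.  Generation
is fully reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AAIndexProperty,
    AAIndexTable,
    CANONICAL_AA,
    FeatureDescriptor,
    Peptide,
)
from .regions import REGION_NAMES, partition

BACKGROUND_FAMILY = "background"


@dataclass(frozen=True)
class PlantedEnrichment:
    region: str
    residue: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("enrichment weight must be positive")

    @property
    def feature_column(self) -> str:
        return FeatureDescriptor(self.residue, self.region, "composition").column


@dataclass(frozen=True)
class PlantedRestriction:
    region: str
    accession: str
    lo: float
    hi: float

    @property
    def feature_column(self) -> str:
        return FeatureDescriptor(self.accession, self.region, "physchem").column


@dataclass
class FamilySpec:
    name: str
    n_peptides: int = 20
    enrichments: list[PlantedEnrichment] = field(default_factory=list)
    restrictions: list[PlantedRestriction] = field(default_factory=list)


@dataclass
class SyntheticSpec:
    """Everything needed to synthesize one labelled peptide dataset."""

    families: list[FamilySpec]
    n_background: int = 40
    length_range: tuple[int, int] = (10, 212)
    d_N: int = 10
    d_C: int = 10
    background_freqs: dict[str, float] | None = None  # default: uniform
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 6 or hi < lo:
            raise ValueError("length range must satisfy 6 <= lo <= hi")


@dataclass
class GroundTruth:
    """Feature columns the generator planted, per family."""

    planted_features: dict[str, list[str]]
    enrichments: dict[str, list[PlantedEnrichment]]
    restrictions: dict[str, list[PlantedRestriction]]


def _base_weights(spec: SyntheticSpec) -> np.ndarray:
    if spec.background_freqs is None:
        return np.ones(20)
    w = np.array(
        [spec.background_freqs.get(aa, 0.0) for aa in CANONICAL_AA]
    )
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("invalid background residue distribution")
    return w


def _region_weights(
    spec: SyntheticSpec,
    fam: FamilySpec,
    region: str,
    table: AAIndexTable | None,
) -> np.ndarray:
    w = _base_weights(spec).astype(float).copy()
    for enr in fam.enrichments:
        if enr.region == region:
            w[CANONICAL_AA.index(enr.residue)] *= enr.weight
    for res in fam.restrictions:
        if res.region != region:
            continue
        if table is None:
            raise ValueError(
                "planted property restrictions require a property table"
            )
        prop = table[res.accession]
        for i, aa in enumerate(CANONICAL_AA):
            if not (res.lo <= prop.values[aa] <= res.hi):
                w[i] = 0.0
    if w.sum() == 0:
        raise ValueError(
            f"family {fam.name!r}, region {region}: no residue satisfies "
            "the planted restrictions"
        )
    return w / w.sum()


def _sample_peptide(
    spec: SyntheticSpec,
    fam: FamilySpec | None,
    pid: str,
    rng: np.random.Generator,
    table: AAIndexTable | None,
) -> Peptide:
    lo, hi = spec.length_range
    L = int(rng.integers(lo, hi + 1))
    part = partition(L, spec.d_N, spec.d_C)
    residues: list[str] = []
    aa = np.array(list(CANONICAL_AA))
    for region in REGION_NAMES:
        width = part.width(region)
        if width == 0:
            continue
        if fam is None:
            probs = _base_weights(spec)
            probs = probs / probs.sum()
        else:
            probs = _region_weights(spec, fam, region, table)
        residues.extend(rng.choice(aa, size=width, p=probs))
    family = fam.name if fam is not None else BACKGROUND_FAMILY
    return Peptide(id=pid, sequence="".join(residues), family=family)


def generate(
    spec: SyntheticSpec, table: AAIndexTable | None = None
) -> tuple[list[Peptide], GroundTruth]:
    """Sample the dataset described by ``spec``.

    Returns the labelled peptides (family members first, then the
    background pool) and the ground truth listing every planted feature
    column.  Same spec + seed -> identical output.
    """
    rng = np.random.default_rng(spec.seed)
    peptides: list[Peptide] = []
    planted: dict[str, list[str]] = {}
    for fam in spec.families:
        planted[fam.name] = [e.feature_column for e in fam.enrichments] + [
            r.feature_column for r in fam.restrictions
        ]
        for k in range(fam.n_peptides):
            peptides.append(
                _sample_peptide(spec, fam, f"{fam.name}_{k + 1}", rng, table)
            )
    for k in range(spec.n_background):
        peptides.append(
            _sample_peptide(spec, None, f"bg_{k + 1}", rng, table)
        )
    truth = GroundTruth(
        planted_features=planted,
        enrichments={f.name: list(f.enrichments) for f in spec.families},
        restrictions={f.name: list(f.restrictions) for f in spec.families},
    )
    return peptides, truth


def make_property_fixture(
    n_properties: int, n_correlated_pairs: int, seed: int = 0
) -> AAIndexTable:
    """Synthetic amino-acid property scales for exercising the pipeline.

    Produces ``n_properties`` scales of which ``n_correlated_pairs``
    pairs are exactly affinely related (|r| = 1), so correlation pruning
    must collapse each pair; all other pairs correlate below 0.9 by
    construction.  Values are standard-normal draws per residue.
    """
    if n_properties < 1:
        raise ValueError("need at least one property")
    if 2 * n_correlated_pairs > n_properties:
        raise ValueError("too many correlated pairs for the table size")
    rng = np.random.default_rng(seed)
    n_base = n_properties - n_correlated_pairs
    bases: list[np.ndarray] = []
    while len(bases) < n_base:
        v = rng.normal(size=20)
        ok = all(
            abs(np.corrcoef(v, b)[0, 1]) < 0.85 for b in bases
        )
        if ok:
            bases.append(v)
    props: list[AAIndexProperty] = []
    for i, v in enumerate(bases):
        props.append(
            AAIndexProperty(
                accession=f"SYN{i + 1:04d}",
                description=f"synthetic property scale {i + 1}",
                values={aa: float(x) for aa, x in zip(CANONICAL_AA, v)},
            )
        )
    for j in range(n_correlated_pairs):
        twin = 2.0 * bases[j] + 3.0
        props.append(
            AAIndexProperty(
                accession=f"SYN{n_base + j + 1:04d}",
                description=f"synthetic twin of SYN{j + 1:04d} (r=1)",
                values={aa: float(x) for aa, x in zip(CANONICAL_AA, twin)},
            )
        )
    return AAIndexTable(properties=props)
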