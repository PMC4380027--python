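"""Family-specific physicochemical features.

Two steps make the second half of the feature vector:

1. the property table is de-redundified — properties whose residue-value
   vectors correlate at |Pearson r| >= 0.9 are grouped (connected
   components of the threshold graph) and one representative per group is
   kept, chosen uniformly at random under a fixed seed;
2. for the family under study, "restrictive" (property, region) pairs are
   mined with a leave-one-out envelope test: a property is restrictive in
   a region when, for at least 90% of family peptides, every residue of
   the held-out peptide in that region has a property value inside the
   [min, max] envelope spanned by the region's residues across the other
   family peptides.

Each retained (property, region) pair then contributes one feature to
every peptide: the median property value of the peptide's residues in
that region (median of an even count = mean of the two central values;
an empty region scores 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .features_basic import N_BASIC_FEATURES, encode_dataset
from .io_formats import (
    AAIndexProperty,
    AAIndexTable,
    FeatureDescriptor,
    FeatureMatrix,
    Peptide,
)
from .regions import REGION_NAMES, RegionPartition, partition, region_residues


@dataclass(frozen=True)
class RestrictiveProperty:
    """A property restricted within one region of a peptide family."""

    accession: str
    region: str
    envelope_min: float
    envelope_max: float
    coverage: float  # fraction of family peptides passing the LOO test

    def __post_init__(self) -> None:
        if self.envelope_min > self.envelope_max:
            raise ValueError("envelope_min > envelope_max")


@dataclass
class PrunedTable:
    """Correlation-pruned property table plus the collapsed groups."""

    retained: AAIndexTable
    groups: list[list[str]] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.retained)

    @property
    def properties(self) -> list[AAIndexProperty]:
        return self.retained.properties


def prune_correlated(
    table: AAIndexTable, threshold: float = 0.9, seed: int = 0
) -> PrunedTable:
    """Collapse groups of mutually correlated property scales.

    Builds a graph over properties with an edge wherever the absolute
    Pearson correlation of the two 20-residue value vectors reaches
    ``threshold``, and keeps one property per connected component, drawn
    uniformly with ``seed``.  A zero-variance property (correlation
    undefined) is kept as its own singleton with a warning.
    """
    props = table.properties
    n = len(props)
    if n == 0:
        return PrunedTable(retained=AAIndexTable([]), groups=[], seed=seed)
    values = np.array([p.value_array() for p in props])  # n x 20
    sd = values.std(axis=1)
    degenerate = sd == 0
    for p, is_deg in zip(props, degenerate):
        if is_deg:
            warnings.warn(
                f"property {p.accession}: zero variance across residues; "
                "kept as a singleton",
                stacklevel=2,
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.atleast_2d(np.corrcoef(values))
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) >= threshold
    adj[degenerate, :] = False
    adj[:, degenerate] = False
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    rng = np.random.default_rng(seed)
    groups: list[list[str]] = []
    keep_idx: list[int] = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        groups.append([props[i].accession for i in members])
        keep_idx.append(int(rng.choice(members)))
    keep_idx.sort()  # preserve original table order among representatives
    retained = AAIndexTable([props[i] for i in keep_idx])
    return PrunedTable(retained=retained, groups=groups, seed=seed)


def _property_values(prop: AAIndexProperty, residues: str) -> np.ndarray:
    return np.array([prop.values[aa] for aa in residues], dtype=float)


def mine_restrictive(
    family_peptides: list[Peptide],
    d_N: int,
    d_C: int,
    table: PrunedTable | AAIndexTable,
    coverage_threshold: float = 0.9,
    alignment=None,
) -> list[RestrictiveProperty]:
    """Mine restrictive (property, region) pairs for one family.

    For each property and region, each family peptide is held out in turn
    and passes when all of its residues in that region carry property
    values within the min/max envelope of the region's residues over the
    remaining peptides (a peptide with an empty region passes vacuously).
    Pairs whose pass fraction reaches ``coverage_threshold`` are retained
    with the family-wide envelope recorded.  Regions empty in every
    peptide are skipped.  The result is sorted by (region order,
    accession) and is invariant to peptide order.

    By default regions are cut on the raw sequences.  Passing an
    :class:`~ampfam.msa.Alignment` switches to the MSA-preprocessing
    mode: the region layout is computed once on the alignment columns
    and each peptide contributes the degapped residues of its row inside
    each column span, so homologous positions fall in the same region.
    """
    if len(family_peptides) < 3:
        raise ValueError("need at least 3 family peptides")
    props = (
        table.properties if isinstance(table, (PrunedTable, AAIndexTable)) else table
    )
    if alignment is None:
        parts = [partition(len(p), d_N, d_C) for p in family_peptides]
        region_strings: dict[str, list[str]] = {
            r: [
                region_residues(p, part, r)
                for p, part in zip(family_peptides, parts)
            ]
            for r in REGION_NAMES
        }
    else:
        part = partition(alignment.n_columns, d_N, d_C)
        missing = [
            p.id for p in family_peptides if p.id not in alignment.rows
        ]
        if missing:
            raise ValueError(f"peptides absent from the alignment: {missing}")
        region_strings = {
            r: [
                alignment.rows[p.id][slice(*part.span(r))].replace("-", "")
                for p in family_peptides
            ]
            for r in REGION_NAMES
        }

    out: list[RestrictiveProperty] = []
    for region in REGION_NAMES:
        strings = region_strings[region]
        if all(len(s) == 0 for s in strings):
            continue
        for prop in props:
            per_pep = [_property_values(prop, s) for s in strings]
            n_pass = 0
            for i, vals_i in enumerate(per_pep):
                if vals_i.size == 0:
                    n_pass += 1
                    continue
                others = [v for j, v in enumerate(per_pep) if j != i and v.size]
                if not others:
                    continue  # envelope undefined: held-out peptide fails
                rest = np.concatenate(others)
                lo, hi = rest.min(), rest.max()
                if vals_i.min() >= lo and vals_i.max() <= hi:
                    n_pass += 1
            coverage = n_pass / len(per_pep)
            if coverage >= coverage_threshold:
                all_vals = np.concatenate([v for v in per_pep if v.size])
                out.append(
                    RestrictiveProperty(
                        accession=prop.accession,
                        region=region,
                        envelope_min=float(all_vals.min()),
                        envelope_max=float(all_vals.max()),
                        coverage=coverage,
                    )
                )
    return out


def physchem_features(
    peptide: Peptide,
    part: RegionPartition,
    restrictive: list[RestrictiveProperty],
    table: PrunedTable | AAIndexTable,
) -> np.ndarray:
    """Median property value per restrictive (property, region) pair.

    Applied identically to family and non-family peptides; an empty
    region contributes 0.
    """
    lookup = (
        table.retained if isinstance(table, PrunedTable) else table
    )
    out = np.zeros(len(restrictive))
    for k, rp in enumerate(restrictive):
        residues = region_residues(peptide, part, rp.region)
        if not residues:
            continue
        vals = _property_values(lookup[rp.accession], residues)
        out[k] = float(np.median(vals))
    return out


def _physchem_matrix(
    peptides: list[Peptide],
    d_N: int,
    d_C: int,
    restrictive: list[RestrictiveProperty],
    table: PrunedTable | AAIndexTable,
) -> pd.DataFrame:
    columns = [
        FeatureDescriptor(rp.accession, rp.region, "physchem").column
        for rp in restrictive
    ]
    rows = [
        physchem_features(p, partition(len(p), d_N, d_C), restrictive, table)
        for p in peptides
    ]
    return pd.DataFrame(
        np.array(rows).reshape(len(peptides), len(restrictive)),
        index=[p.id for p in peptides],
        columns=columns,
        dtype=float,
    )


def build_family_feature_space(
    target_family: str,
    all_peptides: list[Peptide],
    d_N: int,
    d_C: int,
    table: PrunedTable | AAIndexTable | None = None,
    coverage_threshold: float = 0.9,
    mode: str = "mined",
) -> tuple[FeatureMatrix, list[RestrictiveProperty]]:
    """Encode ALL peptides in the feature space of one target family.

    ``mode`` selects the physicochemical half of the vector:

    * ``"mined"`` (default) — one median feature per restrictive
      (property, region) pair mined from the target family;
    * ``"all"`` — one median feature per (property, region) pair for
      every property in the table (the no-mining baseline; with 294
      properties this yields 184 + 294*6 = 1948 columns);
    * ``"basic"`` — compositional features only (184 columns).
    """
    basic = encode_dataset(all_peptides, d_N, d_C)
    if mode == "basic":
        return basic, []
    if table is None:
        raise ValueError(f"mode {mode!r} requires a property table")
    if mode == "mined":
        family = [p for p in all_peptides if p.family == target_family]
        restrictive = mine_restrictive(
            family, d_N, d_C, table, coverage_threshold
        )
    elif mode == "all":
        props = (
            table.properties
            if isinstance(table, (PrunedTable, AAIndexTable))
            else table
        )
        restrictive = [
            RestrictiveProperty(
                accession=prop.accession,
                region=region,
                envelope_min=min(prop.values.values()),
                envelope_max=max(prop.values.values()),
                coverage=1.0,
            )
            for region in REGION_NAMES
            for prop in props
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    phys = _physchem_matrix(all_peptides, d_N, d_C, restrictive, table)
    data = pd.concat([basic.data, phys], axis=1)
    assert data.shape[1] == N_BASIC_FEATURES + len(restrictive)
    return FeatureMatrix(data=data, labels=basic.labels), restrictive


def write_restrictive_report(
    restrictive: list[RestrictiveProperty], path
) -> None:
    """TSV report: accession, region, coverage, envelope_min, envelope_max."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tregion\tcoverage\tenvelope_min\tenvelope_max\n")
        for rp in restrictive:
            fh.write(
                f"{rp.accession}\t{rp.region}\t{rp.coverage:.6g}\t"
                f"{rp.envelope_min!r}\t{rp.envelope_max!r}\n"
            )
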