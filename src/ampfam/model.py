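"""Model / Results front end for family profiling.

:class:`FamilyProfileModel` bundles the data (labelled peptides plus an
optional property table) and the run parameters; ``fit()`` executes the
whole pipeline — feature-space construction, restrictive-property
mining, preprocessing, and GA feature selection over the (d_N, d_C, K)
grid — and returns a :class:`FamilyProfileResults` carrying the selected
features, the clustering-quality metrics, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .cluster_eval import METRIC_COLUMNS
from .ga_select import (
    DEFAULT_D_C_GRID,
    DEFAULT_D_N_GRID,
    DEFAULT_K_GRID,
    GAConfig,
    SelectionResult,
    select_for_family,
)
from .io_formats import (
    AAIndexTable,
    Peptide,
    attach_families,
    parse_aaindex,
    read_family_table,
    read_fasta,
)
from .physchem import PrunedTable, prune_correlated


class FamilyProfileModel:
    """Profile one peptide family against all other peptides.

    Parameters
    ----------
    peptides
        All peptides, each carrying a family label; the peptides labelled
        ``target_family`` form the target class, everything else the
        non-target class.
    target_family
        Name of the family under study.
    property_table
        Amino-acid property scales; required for the ``"mined"`` and
        ``"all"`` modes.  An un-pruned table is correlation-pruned at
        ``correlation_threshold`` before use.
    mode
        ``"mined"`` (default, restrictive-property features),
        ``"all"`` (every property in every region, no mining) or
        ``"basic"`` (compositional features only).
    """

    def __init__(
        self,
        peptides: list[Peptide],
        target_family: str,
        property_table: AAIndexTable | PrunedTable | None = None,
        mode: str = "mined",
        d_N_grid: tuple[int, ...] = DEFAULT_D_N_GRID,
        d_C_grid: tuple[int, ...] = DEFAULT_D_C_GRID,
        K_grid: tuple[int, ...] = DEFAULT_K_GRID,
        ga_config: GAConfig | None = None,
        coverage_threshold: float = 0.9,
        correlation_threshold: float = 0.9,
        min_family_size: int = 11,
        seed: int = 0,
    ) -> None:
        self.peptides = peptides
        self.target_family = target_family
        self.mode = mode
        self.d_N_grid = tuple(d_N_grid)
        self.d_C_grid = tuple(d_C_grid)
        self.K_grid = tuple(K_grid)
        self.ga_config = ga_config if ga_config is not None else GAConfig(seed=seed)
        self.coverage_threshold = coverage_threshold
        self.min_family_size = min_family_size
        if property_table is None or isinstance(property_table, PrunedTable):
            self.property_table = property_table
        else:
            self.property_table = prune_correlated(
                property_table, threshold=correlation_threshold, seed=seed
            )
        families = {p.family for p in peptides}
        if target_family not in families:
            raise ValueError(
                f"no peptide labelled {target_family!r} in the dataset"
            )

    @classmethod
    def from_files(
        cls,
        fasta_path,
        labels_path,
        target_family: str,
        aaindex_path=None,
        **kwargs,
    ) -> "FamilyProfileModel":
        """Build the model from a FASTA file, a label table and an
        optional AAIndex1 property file."""
        peptides = attach_families(
            read_fasta(fasta_path), read_family_table(labels_path)
        )
        table = parse_aaindex(aaindex_path) if aaindex_path else None
        return cls(peptides, target_family, property_table=table, **kwargs)

    def fit(self) -> "FamilyProfileResults":
        selection = select_for_family(
            self.target_family,
            self.peptides,
            self.property_table,
            d_N_grid=self.d_N_grid,
            d_C_grid=self.d_C_grid,
            K_grid=self.K_grid,
            config=self.ga_config,
            coverage_threshold=self.coverage_threshold,
            mode=self.mode,
            min_family_size=self.min_family_size,
        )
        return FamilyProfileResults(model=self, selection=selection)


@dataclass
class FamilyProfileResults:
    """Fitted profile: selected features plus clustering quality."""

    model: FamilyProfileModel
    selection: SelectionResult

    @property
    def selected_features(self) -> list[str]:
        return self.selection.selected_features

    @property
    def metrics(self):
        return self.selection.metrics

    @property
    def params(self) -> dict:
        """Winning grid parameters, Table-style column names."""
        sel = self.selection
        n_comp = sum(
            1 for f in sel.selected_features if not f.startswith("physchem:")
        )
        return {
            "d_n": sel.d_N,
            "d_c": sel.d_C,
            "NP": int(
                sum(
                    1
                    for p in self.model.peptides
                    if p.family == self.model.target_family
                )
            ),
            "NF": len(sel.feature_names),
            "NSF": sel.n_selected,
            "NC": sel.K,
            "NCF": n_comp,
            "NPF": sel.n_selected - n_comp,
        }

    def summary(self) -> str:
        """Plain-text report of the fit."""
        sel = self.selection
        m = sel.metrics
        lines = [
            "Family profile fit",
            "=" * 60,
            f"target family:        {self.model.target_family}",
            f"representation mode:  {self.model.mode}",
        ]
        p = self.params
        lines += [
            f"terminal lengths:     d_N={p['d_n']}  d_C={p['d_c']}",
            f"clusters (K):         {p['NC']}",
            f"family peptides (NP): {p['NP']}",
            f"candidate features:   {p['NF']}",
            f"selected features:    {p['NSF']} "
            f"({p['NCF']} compositional, {p['NPF']} physicochemical)",
            f"GA fitness:           {sel.fitness:.4f}",
            "-" * 60,
            f"confusion counts:     TP={m.TP} FP={m.FP} FN={m.FN} TN={m.TN}",
        ]
        for name in METRIC_COLUMNS:
            lines.append(f"{name + ':':<22}{getattr(m, name):.4f}")
        lines.append("-" * 60)
        lines.append("selected features:")
        for f in sel.selected_features:
            lines.append(f"  {f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        sel = self.selection
        return {
            "target_family": self.model.target_family,
            "mode": self.model.mode,
            "params": self.params,
            "fitness": sel.fitness,
            "metrics": sel.metrics.as_dict(),
            "selected_features": sel.selected_features,
            "fitness_trace": sel.fitness_trace,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
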