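"""End-to-end composition: records → fingerprints → PCF → RankSVM → CV.

This is the glue the command line and the examples use. The order of
operations mirrors how retention-order models are trained in practice:

1. split RT-annotated records into round-robin subsets;
2. compute counting MIX fingerprints for all training molecules *and* the
   reference panel;
3. fit the PCF transform once on that combined matrix and truncate to k
   components (the same transform is later applied, never refit, to queries
   and database candidates);
4. generate within-subset pairs, add reference-panel pairs to every training
   fold, and run leave-one-subset-out cross-validation over the C grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemio import MoleculeRecord, ReferencePanel, round_robin_split
from .fingerprints import fingerprint_matrix
from .pcf import PCFTransform, fit_pcf, select_components
from .ranking import CVResult, DEFAULT_C_GRID, PairSet, cross_validate, make_pairs

__all__ = ["FingerprintSettings", "OrderWorkflow", "run_order_workflow"]


@dataclass(frozen=True)
class FingerprintSettings:
    family: str = "mix"
    mode: str = "counting"
    hashed_length: int = 1024
    depth: int = 6
    radius: int = 3

    def matrix(self, smiles_list: Sequence[str]) -> np.ndarray:
        return fingerprint_matrix(
            smiles_list,
            family=self.family,
            mode=self.mode,
            hashed_length=self.hashed_length,
            depth=self.depth,
            radius=self.radius,
        )


@dataclass
class OrderWorkflow:
    """Everything produced by one training run."""

    records: list[MoleculeRecord]
    subsets: list[list[MoleculeRecord]]
    settings: FingerprintSettings
    transform: PCFTransform
    scores: dict[str, np.ndarray]          # record id → PCF score vector
    panel_scores: np.ndarray | None        # (n_panel, k) or None
    subset_pairs: list[PairSet]
    cv: CVResult

    @property
    def model(self):
        return self.cv.model

    def project(self, smiles_list: Sequence[str]) -> np.ndarray:
        """PCF scores for new structures under the *fitted* transform."""
        return self.transform.apply(self.settings.matrix(smiles_list))

    def heldout_items(self, fold: int) -> list[tuple[str, np.ndarray, float]]:
        return [
            (r.id, self.scores[r.id], r.rt) for r in self.subsets[fold]
        ]


def run_order_workflow(
    records: Sequence[MoleculeRecord],
    panel: ReferencePanel | None = None,
    n_subsets: int = 5,
    k_components: int = 200,
    settings: FingerprintSettings = FingerprintSettings(),
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    kernel: str = "linear",
    min_delta_rt: float = 0.0,
) -> OrderWorkflow:
    """Train a retention-order model with subset cross-validation.

    The PCF transform is fit on the training molecules plus the reference
    panel (when given); panel pairs join the training side of every CV fold
    but are never scored.
    """
    records = list(records)
    subsets = round_robin_split(records, n_subsets)
    all_smiles = [r.smiles for r in records]
    panel_smiles = list(panel.smiles) if panel is not None else []
    X = settings.matrix(all_smiles + panel_smiles)
    transform = fit_pcf(X)
    if k_components < transform.n_components:
        transform = select_components(transform, k_components)
    scores_all = transform.apply(X)
    scores = {r.id: scores_all[i] for i, r in enumerate(records)}
    panel_scores = scores_all[len(records):] if panel is not None else None

    subset_pairs = [
        make_pairs(
            [(r.id, scores[r.id], r.rt) for r in subset],
            subset_label=f"subset_{i}",
            min_delta_rt=min_delta_rt,
        )
        for i, subset in enumerate(subsets)
    ]
    shared = []
    if panel is not None:
        shared = list(
            make_pairs(
                [
                    (rec.id, panel_scores[i], rec.rt)
                    for i, rec in enumerate(panel.records)
                ],
                subset_label="reference_panel",
                min_delta_rt=min_delta_rt,
            )
        )
    cv = cross_validate(subset_pairs, C_grid=C_grid, kernel=kernel, shared_pairs=shared)
    return OrderWorkflow(
        records=records,
        subsets=subsets,
        settings=settings,
        transform=transform,
        scores=scores,
        panel_scores=panel_scores,
        subset_pairs=subset_pairs,
        cv=cv,
    )
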