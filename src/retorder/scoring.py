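"""Order-relation vectors and the agreement statistics S and S′.

Instead of comparing absolute retention times, a query compound is placed
relative to a panel of n reference compounds with known RTs: its *order
relation vector* holds one entry per reference, −1 if the query elutes before
that reference and +1 if after. The measured vector m comes from the query's
observed RT; the predicted vector p comes from the ranking model.

The prediction accuracy is the fraction of agreeing positions,

    S = (1/n) Σ_i δ(m_i, p_i),    δ(m_i, p_i) = 1 if m_i = p_i else 0,

so S takes only the values k/n. The same statistic computed between a
measured LC/MS feature's order vector and a database candidate's predicted
vector is the match score S′ used for candidate shortlisting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import ReferencePanel

__all__ = [
    "OrderRelationVector",
    "measured_relations",
    "predicted_relations",
    "accuracy_S",
    "evaluate_panel",
    "PanelEvaluation",
]


@dataclass(frozen=True)
class OrderRelationVector:
    """Per-reference before/after relations for one query compound.

    Entry i is −1 when the query elutes before reference i and +1 when it
    elutes after (exact ties resolve to +1).
    """

    relations: np.ndarray
    query_id: str = ""

    def __post_init__(self) -> None:
        rel = np.asarray(self.relations, dtype=int)
        if rel.ndim != 1 or not np.isin(rel, (-1, 1)).all():
            raise ValueError("relations must be a 1-D vector of ±1")
        object.__setattr__(self, "relations", rel)

    @property
    def n(self) -> int:
        return int(self.relations.shape[0])


def measured_relations(query_rt: float, panel: ReferencePanel, query_id: str = "") -> OrderRelationVector:
    """Measured relations m: sign(query_rt − rt_i), exact tie → +1 ("after")."""
    if query_rt < 0:
        raise ValueError(f"query_rt must be >= 0, got {query_rt}")
    rel = np.where(np.asarray(panel.rts) <= query_rt, 1, -1)
    return OrderRelationVector(relations=rel, query_id=query_id)


def predicted_relations(
    model,
    query_pcf: np.ndarray,
    panel_pcfs: np.ndarray,
    query_id: str = "",
) -> OrderRelationVector:
    """Predicted relations p from any pairwise order model.

    Entry i is +1 when the model predicts the query to elute *after*
    reference i, i.e. ``predict_order(panel_i, query) = +1`` (panel_i first).
    """
    panel_pcfs = np.atleast_2d(np.asarray(panel_pcfs, dtype=float))
    query_pcf = np.asarray(query_pcf, dtype=float)
    rel = np.array(
        [model.predict_order(panel_pcfs[i], query_pcf) for i in range(panel_pcfs.shape[0])],
        dtype=int,
    )
    return OrderRelationVector(relations=rel, query_id=query_id)


def accuracy_S(m: OrderRelationVector, p: OrderRelationVector) -> float:
    """Fraction of agreeing positions between measured and predicted vectors."""
    if m.n != p.n:
        raise ValueError(f"relation vectors differ in length: {m.n} vs {p.n}")
    return float(np.mean(m.relations == p.relations))


@dataclass
class PanelEvaluation:
    """Per-query S table plus the unweighted mean."""

    table: pd.DataFrame  # columns: query_id, S
    mean_s: float

    def formatted(self) -> pd.DataFrame:
        """Presentation copy: S to 2 decimals (mean is reported at 3)."""
        out = self.table.copy()
        out["S"] = out["S"].round(2)
        return out


def evaluate_panel(
    model,
    queries: Sequence[tuple[str, np.ndarray, float]],
    panel: ReferencePanel,
    panel_pcfs: np.ndarray,
) -> PanelEvaluation:
    """Score each query's predicted relations against its measured relations.

    ``queries`` is a list of ``(id, pcf_vector, measured_rt)``; returns one S
    per query and the unweighted mean over queries.
    """
    queries = list(queries)
    if not queries:
        raise ValueError("no query compounds to evaluate")
    rows = []
    for qid, pcf_vec, rt in queries:
        if rt is None:
            raise ValueError(f"query {qid!r} has no measured retention time")
        m = measured_relations(rt, panel, query_id=qid)
        p = predicted_relations(model, pcf_vec, panel_pcfs, query_id=qid)
        rows.append({"query_id": qid, "S": accuracy_S(m, p)})
    table = pd.DataFrame(rows)
    return PanelEvaluation(table=table, mean_s=float(table["S"].mean()))
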