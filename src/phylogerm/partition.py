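"""Variance partitioning by complete-vs-incomplete model R2 differencing.

The multi-factor protocol: fit the complete main-effects ANOVA once, then
one "incomplete" model per factor with that factor deleted. The drop in
model R2,

    R2_independent(f) = R2(complete) - R2(complete minus f),

is the share of total variance attributable to factor f independent of all
others. Collinearity between factors makes this smaller than f's Type III
term R2; with mutually orthogonal factors the two coincide and the
independent R2s sum to the complete-model R2.

The same battery of fits yields the association rule: if a factor A's Type
III R2 is larger in the incomplete model lacking B than in the complete
model, the increase signals a correlation or strong interaction between A
and B. A small threshold on the increase (default 0.001 of total SS)
avoids flagging numerical noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .anova import ModelSpec, type3_anova

__all__ = ["PartitionResult", "partition_independent", "detect_associations"]

DEFAULT_ASSOCIATION_THRESHOLD = 1e-3


@dataclass
class PartitionResult:
    """Complete-model table, per-deletion tables, and the per-factor summary."""

    complete: pd.DataFrame
    incompletes: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    associations: pd.DataFrame


def _model_r2(table: pd.DataFrame) -> float:
    return float(table.loc[table["source"] == "Model", "R2"].iloc[0])


def _term_r2(table: pd.DataFrame, term: str) -> float:
    return float(table.loc[table["source"] == term, "R2"].iloc[0])


def partition_independent(data: pd.DataFrame, spec: ModelSpec) -> PartitionResult:
    """Fit the complete model and every leave-one-factor-out model.

    ``spec`` must be a main-effects model with >= 2 factors. The summary has
    one row per factor with its Type III R2 in the complete model
    (``R2_complete_term``) and its independent R2 by model differencing.
    """
    if len(spec.factors) < 2:
        raise ValueError("partitioning needs >= 2 factors")
    if spec.interactions:
        raise ValueError("the complete model is main-effects only")
    complete = type3_anova(data, spec)
    r2_complete = _model_r2(complete)
    incompletes: dict[str, pd.DataFrame] = {}
    rows = []
    for f_name in spec.factors:
        reduced = ModelSpec(
            response=spec.response,
            factors=tuple(f for f in spec.factors if f != f_name),
            data_unit=spec.data_unit,
        )
        table = type3_anova(data, reduced)
        incompletes[f_name] = table
        rows.append({
            "factor": f_name,
            "R2_complete_term": _term_r2(complete, f_name),
            "R2_incomplete_model": _model_r2(table),
            "R2_independent": r2_complete - _model_r2(table),
        })
    summary = pd.DataFrame(rows).sort_values("factor").reset_index(drop=True)
    associations = detect_associations(complete, incompletes)
    return PartitionResult(complete=complete, incompletes=incompletes,
                           summary=summary, associations=associations)


def detect_associations(
    complete: pd.DataFrame,
    incompletes: dict[str, pd.DataFrame],
    threshold: float = DEFAULT_ASSOCIATION_THRESHOLD,
) -> pd.DataFrame:
    """Flag ordered pairs (A, B) where deleting B inflates A's term R2.

    ``delta_R2`` is the increase of A's Type III R2 from the complete model
    to the incomplete model lacking B; pairs with delta above ``threshold``
    (a fraction of total SS) are flagged as associated or strongly
    interacting.
    """
    terms = [s for s in complete["source"] if s not in ("Model", "Residual")]
    rows = []
    for deleted, table in incompletes.items():
        remaining = [s for s in table["source"] if s not in ("Model", "Residual")]
        unknown = set(remaining) - set(terms)
        if unknown:
            raise ValueError(f"incomplete model has unknown term(s) {unknown}")
        for a in remaining:
            delta = _term_r2(table, a) - _term_r2(complete, a)
            rows.append({
                "factor": a, "deleted": deleted, "delta_R2": delta,
                "flagged": bool(delta > threshold),
            })
    out = pd.DataFrame(rows).sort_values(["factor", "deleted"]).reset_index(drop=True)
    return out
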