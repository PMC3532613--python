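"""Clinicopathologic guideline baseline classifier.

Implements the guideline logic used as the comparator for the molecular
rule.  Stage I patients are followed by surveillance alone and are
classified low risk.  Stage II patients are high risk if one or more
high-risk factors for systemic recurrence is present: T4 tumor, grade
3/4, lymphovascular invasion, perineural invasion, bowel obstruction,
localized perforation, fewer than 12 lymph nodes examined, or
close/indeterminate/positive resection margins.  A stage II patient
with no factor present but at least one factor unknown is not
evaluable; not-evaluable patients are excluded from comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GuidelineFactors", "nccn_classify", "nccn_classify_table"]


def _is_missing(x: object) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x is pd.NA


@dataclass(frozen=True)
class GuidelineFactors:
    """Per-patient fields consulted by the guideline classifier.

    Any factor may be ``None`` (unknown).  ``margins_compromised``
    collapses close / indeterminate / positive margins to one boolean.
    """

    stage: str                      # "I" or "II"
    t_class: str | None = None      # "T1".."T4"
    grade: int | None = None        # 1..4
    lvi: bool | None = None
    pni: bool | None = None
    obstruction_perforation: bool | None = None
    n_nodes_examined: int | None = None
    margins_compromised: bool | None = None


def nccn_classify(factors: GuidelineFactors) -> str:
    """Classify one patient as ``high``, ``low`` or ``not_evaluable``.

    A present factor always wins: a stage II patient with any factor
    confirmed present is high risk even if other factors are unknown.
    Monotone in the factors -- adding a risk factor can never turn a
    high-risk call into low.
    """
    if factors.stage == "I":
        return "low"
    if factors.stage != "II":
        raise ValueError(f"unsupported stage {factors.stage!r}")

    checks = [
        None if _is_missing(factors.t_class) else factors.t_class == "T4",
        None if _is_missing(factors.grade) else factors.grade >= 3,
        None if _is_missing(factors.lvi) else bool(factors.lvi),
        None if _is_missing(factors.pni) else bool(factors.pni),
        None
        if _is_missing(factors.obstruction_perforation)
        else bool(factors.obstruction_perforation),
        None
        if _is_missing(factors.n_nodes_examined)
        else factors.n_nodes_examined < 12,
        None
        if _is_missing(factors.margins_compromised)
        else bool(factors.margins_compromised),
    ]
    if any(c is True for c in checks):
        return "high"
    if any(c is None for c in checks):
        return "not_evaluable"
    return "low"


def nccn_classify_table(clinical: pd.DataFrame) -> pd.Series:
    """Vector version over a clinical table.

    Expects the clinical-table dialect written by the cohort generator
    (columns ``stage``, ``t_class``, ``grade``, ``lvi``, ``pni``,
    ``obstruction_perforation``, ``n_nodes_examined``,
    ``margins_clear``).  Returns a Series of high/low/not_evaluable.
    """
    def one(row: pd.Series) -> str:
        margins = row.get("margins_clear")
        return nccn_classify(
            GuidelineFactors(
                stage=str(row["stage"]),
                t_class=None if _is_missing(row["t_class"]) else str(row["t_class"]),
                grade=None if _is_missing(row["grade"]) else int(row["grade"]),
                lvi=None if _is_missing(row["lvi"]) else bool(row["lvi"]),
                pni=None if _is_missing(row["pni"]) else bool(row["pni"]),
                obstruction_perforation=(
                    None
                    if _is_missing(row["obstruction_perforation"])
                    else bool(row["obstruction_perforation"])
                ),
                n_nodes_examined=(
                    None
                    if _is_missing(row["n_nodes_examined"])
                    else int(row["n_nodes_examined"])
                ),
                margins_compromised=None if _is_missing(margins) else not bool(margins),
            )
        )

    return clinical.apply(one, axis=1).rename("nccn_risk")
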