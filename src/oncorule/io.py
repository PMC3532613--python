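"""TSV dialects shared across the pipeline.

All tables are plain tab-separated text with a header row; missing
values are encoded as empty strings; booleans as ``true``/``false``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CtPanel, ExpressionTable, QcReport

__all__ = [
    "write_ct_panel", "read_ct_panel",
    "write_clinical", "read_clinical",
    "write_expression", "read_expression",
    "write_qc_report", "write_calls", "read_calls",
    "write_candidates", "read_candidates",
]

_BOOL_COLS = ("recurred_36mo", "event", "planted_high", "lvi", "pni",
              "obstruction_perforation", "margins_clear")


def _fmt_bool(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in _BOOL_COLS or out[col].dtype == bool or str(out[col].dtype) == "boolean":
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else ("true" if bool(v) else "false")
            )
    return out


def _parse_bool(df: pd.DataFrame, cols: tuple[str, ...] = _BOOL_COLS) -> pd.DataFrame:
    for col in cols:
        if col in df.columns:
            # read_csv may have auto-parsed "true"/"false" into booleans
            df[col] = pd.array(
                [pd.NA if (not isinstance(v, (bool, np.bool_)) and (pd.isna(v) or v == ""))
                 else v in (True, "true", "True")
                 for v in df[col].astype(object)],
                dtype="boolean",
            )
    return df


def write_ct_panel(panel: CtPanel, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``ct.tsv`` (long format) and ``meta.tsv``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ct_path = out_dir / "ct.tsv"
    meta_path = out_dir / "meta.tsv"
    panel.ct.to_csv(ct_path, sep="\t", index=False, na_rep="")
    panel.meta.to_csv(meta_path, sep="\t", na_rep="")
    return ct_path, meta_path


def read_ct_panel(ct_path: str | Path, meta_path: str | Path,
                  hk_genes: tuple[str, ...] | None = None) -> CtPanel:
    ct = pd.read_csv(ct_path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    kwargs = {} if hk_genes is None else {"hk_genes": tuple(hk_genes)}
    return CtPanel(ct=ct, meta=meta, **kwargs)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _fmt_bool(clinical).to_csv(path, sep="\t", na_rep="")
    return path


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str}, keep_default_na=True)
    df = df.set_index("patient_id")
    return _parse_bool(df)


def write_expression(expr: ExpressionTable | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = expr.values if isinstance(expr, ExpressionTable) else expr
    values.rename_axis("sample_id").to_csv(path, sep="\t", na_rep="")
    return path


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")


def write_qc_report(report: QcReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame["passed"] = np.where(frame["passed"], "true", "false")
    frame.to_csv(path, sep="\t", index=False)
    return path


def write_calls(calls: pd.DataFrame, path: str | Path) -> Path:
    """Write per-sample rule calls (sample_id, score, risk)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    calls.rename_axis("sample_id").to_csv(path, sep="\t")
    return path


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "risk": str}).set_index("sample_id")


def write_candidates(candidates, path: str | Path) -> Path:
    """Write a candidate-rule set as JSON lines (one rule per line)."""
    import json

    from .rules import serialize_rule

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for cand in candidates:
            fh.write(json.dumps({
                "rule": json.loads(serialize_rule(cand.rule)),
                "cv_auc": cand.cv_auc,
                "run_id": cand.run_id,
                "set_id": cand.set_id,
            }) + "\n")
    return path


def read_candidates(path: str | Path):
    import json

    from .gp import CandidateRule, CandidateRuleSet
    from .rules import parse_rule

    rules = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            rules.append(CandidateRule(
                rule=parse_rule(json.dumps(doc["rule"])),
                cv_auc=float(doc["cv_auc"]),
                run_id=int(doc["run_id"]),
                set_id=int(doc["set_id"]),
            ))
    return CandidateRuleSet(rules=rules)
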