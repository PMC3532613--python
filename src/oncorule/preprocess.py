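"""qPCR Ct screening and normalization.

Raw input is a :class:`CtPanel`: duplicate cycle-threshold (Ct)
measurements for every (sample, gene) pair plus per-sample RNA quality
metadata.  Samples are screened against five acceptance criteria (RNA
concentration, 260/280 purity ratio, mean housekeeping Ct, maximum
individual Ct, replicate concordance r^2) and, for passing samples,
target-gene Ct values are converted to linear expression units relative
to the mean of five housekeeping (HK) genes::

    value(s, g) = 100 * 2 ** (Ave5HK_Ct(s) - Ct(s, g))

Replicates are averaged on the Ct (log2) scale before normalization.
A gene that failed to amplify is represented by a missing Ct, never a
sentinel cycle number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rules import HOUSEKEEPING_GENES

__all__ = [
    "CtPanel",
    "QcThresholds",
    "QcReport",
    "ExpressionTable",
    "replicate_concordance",
    "qc_screen",
    "normalize_expression",
]

# Canonical order in which failure reasons are reported.
FAILURE_REASONS = (
    "LOW_RNA_CONC",
    "LOW_PURITY_RATIO",
    "HK_MEAN_EXCEEDED",
    "CT_EXCEEDED",
    "LOW_REPLICATE_R2",
    "NO_AMPLIFICATION",
)


@dataclass
class CtPanel:
    """Duplicate Ct measurements plus per-sample RNA QC metadata.

    Attributes
    ----------
    ct
        Long-format DataFrame with columns ``sample_id``, ``gene_id``,
        ``ct_rep1``, ``ct_rep2`` (NaN = no amplification).
    meta
        DataFrame indexed by ``sample_id`` with columns
        ``rna_conc_ng_ul`` and ``a260_280``.
    hk_genes
        The five housekeeping gene symbols.
    """

    ct: pd.DataFrame
    meta: pd.DataFrame
    hk_genes: tuple[str, ...] = HOUSEKEEPING_GENES

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "ct_rep1", "ct_rep2"}
        missing = required - set(self.ct.columns)
        if missing:
            raise ValueError(f"ct table missing columns: {sorted(missing)}")
        if len(self.hk_genes) != 5:
            raise ValueError("exactly 5 housekeeping genes are required")
        present = set(self.ct["gene_id"])
        lost = set(self.hk_genes) - present
        if lost:
            raise ValueError(f"panel lacks housekeeping genes: {sorted(lost)}")

    @property
    def samples(self) -> list[str]:
        return list(self.meta.index)

    @property
    def target_genes(self) -> list[str]:
        hk = set(self.hk_genes)
        return sorted(g for g in self.ct["gene_id"].unique() if g not in hk)

    def ct_mean(self) -> pd.DataFrame:
        """Replicate-averaged Ct as a samples x genes DataFrame.

        With one replicate missing the remaining one is used; with both
        missing the entry is NaN.
        """
        reps = self.ct[["ct_rep1", "ct_rep2"]].mean(axis=1, skipna=True)
        wide = (
            self.ct.assign(_ct=reps)
            .pivot_table(index="sample_id", columns="gene_id", values="_ct",
                         aggfunc="first", dropna=False)
        )
        return wide.reindex(self.samples)


@dataclass(frozen=True)
class QcThresholds:
    """The five minimal acceptance criteria (all bounds inclusive)."""

    min_rna_conc: float = 10.0       # ng/uL
    min_a260_280: float = 1.8
    max_hk_mean_ct: float = 32.0     # cycles
    max_individual_ct: float = 35.0  # cycles
    min_replicate_r2: float = 0.90


@dataclass
class QcReport:
    """Per-sample QC outcome."""

    table: pd.DataFrame  # sample_id (index), passed (bool), reasons (list)
    thresholds: QcThresholds

    @property
    def passed_samples(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    @property
    def failed_samples(self) -> list[str]:
        return list(self.table.index[~self.table["passed"]])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["reasons"] = out["reasons"].map(";".join)
        return out.reset_index()


def replicate_concordance(panel: CtPanel) -> pd.Series:
    """Squared Pearson correlation of replicate Ct vectors per sample.

    For each sample, r^2 is computed between the rep-1 and rep-2 Ct
    values across all genes with both replicates present.  Samples with
    fewer than 3 complete pairs (or zero variance in either replicate)
    get NaN, flagging r^2 as undefined.
    """
    out = {}
    for sid, grp in panel.ct.groupby("sample_id", sort=False):
        both = grp.dropna(subset=["ct_rep1", "ct_rep2"])
        if len(both) < 3:
            out[sid] = np.nan
            continue
        x = both["ct_rep1"].to_numpy(dtype=float)
        y = both["ct_rep2"].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            out[sid] = np.nan
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[sid] = float(r * r)
    return pd.Series(out, name="replicate_r2").reindex(panel.samples)


def qc_screen(
    panel: CtPanel,
    thresholds: QcThresholds | None = None,
    requisite_genes: Sequence[str] | None = None,
) -> QcReport:
    """Screen every sample against the five acceptance criteria.

    ``requisite_genes`` are the genes whose amplification is mandatory
    (default: the HK genes plus all target genes); a requisite gene with
    both replicates missing triggers ``NO_AMPLIFICATION``.  A sample
    passes iff it violates no criterion; boundary values pass (the
    criteria are >= / <= inclusive).
    """
    thr = thresholds or QcThresholds()
    if requisite_genes is None:
        requisite_genes = list(panel.hk_genes) + panel.target_genes
    known = set(panel.ct["gene_id"])
    unknown = set(requisite_genes) - known
    if unknown:
        raise ValueError(f"unknown requisite genes: {sorted(unknown)}")

    ct_mean = panel.ct_mean()
    hk_mean = ct_mean[list(panel.hk_genes)].mean(axis=1)
    r2 = replicate_concordance(panel)

    rep_long = panel.ct.set_index(["sample_id", "gene_id"])
    rows = []
    for sid in panel.samples:
        reasons: list[str] = []
        meta = panel.meta.loc[sid]
        if meta["rna_conc_ng_ul"] < thr.min_rna_conc:
            reasons.append("LOW_RNA_CONC")
        if meta["a260_280"] < thr.min_a260_280:
            reasons.append("LOW_PURITY_RATIO")
        if not (hk_mean.loc[sid] <= thr.max_hk_mean_ct):  # NaN fails too
            reasons.append("HK_MEAN_EXCEEDED")
        sample_reps = rep_long.loc[sid, ["ct_rep1", "ct_rep2"]].to_numpy(dtype=float)
        finite = sample_reps[np.isfinite(sample_reps)]
        if finite.size and finite.max() > thr.max_individual_ct:
            reasons.append("CT_EXCEEDED")
        if not (r2.loc[sid] >= thr.min_replicate_r2):  # NaN (undefined) fails
            reasons.append("LOW_REPLICATE_R2")
        sub = rep_long.loc[sid]
        req = sub.loc[sub.index.intersection(requisite_genes)]
        if req[["ct_rep1", "ct_rep2"]].isna().all(axis=1).any() or (
            len(req) < len(set(requisite_genes))
        ):
            reasons.append("NO_AMPLIFICATION")
        rows.append((sid, not reasons, reasons))

    table = pd.DataFrame(rows, columns=["sample_id", "passed", "reasons"])
    table = table.set_index("sample_id")
    return QcReport(table=table, thresholds=thr)


@dataclass
class ExpressionTable:
    """Normalized linear expression values (samples x genes).

    ``values`` holds 100 * 2**(Ave5HK_Ct - gene Ct); NaN marks genes
    that failed to amplify in both replicates.  ``hk_mean_ct`` records
    the per-sample normalization constant.
    """

    values: pd.DataFrame
    hk_mean_ct: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]


def normalize_expression(panel: CtPanel, samples: Sequence[str] | None = None) -> ExpressionTable:
    """Convert replicate-averaged Ct values to linear expression units.

    For each sample the normalization constant is the mean of the five
    HK genes' replicate-averaged Cts; each target gene's value is
    ``100 * 2**(hk_mean - ct)``.  Restrict to QC-passing samples via
    ``samples``.  A sample with any HK gene entirely unamplified cannot
    be normalized and raises; a *target* gene with both replicates
    missing yields NaN for that entry.
    """
    ct_mean = panel.ct_mean()
    if samples is not None:
        ct_mean = ct_mean.loc[list(samples)]
    hk_cols = list(panel.hk_genes)
    hk = ct_mean[hk_cols]
    bad = hk.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"housekeeping gene missing for samples: {list(ct_mean.index[bad])}"
        )
    hk_mean = hk.mean(axis=1)
    targets = panel.target_genes
    values = 100.0 * np.power(2.0, hk_mean.to_numpy()[:, None] - ct_mean[targets].to_numpy())
    out = pd.DataFrame(values, index=ct_mean.index, columns=targets)
    return ExpressionTable(values=out, hk_mean_ct=hk_mean.rename("hk_mean_ct"))
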