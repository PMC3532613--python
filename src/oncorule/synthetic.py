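"""Synthetic qPCR cohorts with a planted prognostic structure.

Emulates the data layout of an FFPE qPCR recurrence study: duplicate Ct
measurements for 5 housekeeping + ~225 target genes per patient, RNA QC
metadata, and a clinical table (36-month recurrence status,
time-to-event with administrative censoring, and clinicopathologic
covariates with realistic marginals).  A low-complexity algebraic rule
over a small gene subset can be *planted*: patient outcomes then follow
the rule's score through a configurable link, so every downstream stage
(normalization, GP rule recovery, validation statistics) can be tested
against known ground truth.

Outcome links
-------------
``logistic`` (default)
    P(recurrence) is logistic in the standardized planted score; the
    intercept is solved so the cohort hits the target prevalence and
    the slope sets the separability of the planted signal.
``threshold``
    Labels are exactly the planted rule's high/low calls (deterministic
    given the expression values); with zero measurement noise the
    downstream pipeline reproduces the labels perfectly.
``hazard``
    Recurrence is driven purely by a group-wise exponential survival
    model: the planted rule's high/low groups get hazards in the
    configured ratio, the baseline hazard is solved so that the overall
    probability of an event before the follow-up horizon equals the
    target prevalence, and a patient "recurs" iff the event falls
    before the horizon.  This is the link for hazard-ratio recovery
    experiments.

In every link, nonrecurrent patients are censored at the follow-up
horizon (36 months by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .preprocess import CtPanel
from .rules import (
    HOUSEKEEPING_GENES,
    KEY_GENES,
    RuleTree,
    classify_scores,
    evaluate_rule,
    parse_rule,
)

__all__ = ["CohortConfig", "generate_cohort", "inject_qc_failures", "stratified_split",
           "bin_recurrence_time"]

# Marginal distributions for the clinicopathologic covariates,
# approximating an external-validation cohort of node-negative
# colorectal cancers (values are probabilities).
COVARIATE_MARGINALS = {
    "site": {"colon-right": 0.52, "colon-left": 0.43, "rectum": 0.05},
    "t_class_colon": {"T1": 0.03, "T2": 0.14, "T3": 0.55, "T4": 0.28},
    "t_class_rectum": {"T1": 0.15, "T2": 0.85},   # rectal eligibility is stage I only
    "grade": {1: 0.16, 2: 0.71, 3: 0.12, 4: 0.01},
    "female": 0.56,
    "race": {"Caucasian": 0.86, "African American": 0.10, "Asian": 0.02, "Other": 0.02},
    "lvi": 0.31,
    "pni": 0.17,
    "obstruction_perforation": 0.06,
    "age_mean": 65.0,
    "age_sd": 13.0,
}

DEFAULT_MISSINGNESS = {"pni": 0.53, "lvi": 0.04, "obstruction_perforation": 0.12}


@dataclass
class CohortConfig:
    """Everything needed to generate one cohort deterministically."""

    n_patients: int
    n_target_genes: int = 225
    hk_gene_ids: tuple[str, ...] = HOUSEKEEPING_GENES
    planted_rule: RuleTree | None = None
    outcome_link: str = "logistic"          # logistic | threshold | hazard
    recurrence_prevalence: float = 0.35
    planted_hazard_ratio: float = 1.8
    followup_months: float = 36.0
    ct_mean: float = 27.0                   # target-gene baseline Ct
    ct_sd: float = 1.5                      # between-gene spread
    biological_sd: float = 1.25             # between-sample spread per gene
    hk_ct_mean: float = 26.0
    hk_ct_sd: float = 0.5
    hk_sample_sd: float = 0.2
    replicate_sd: float = 0.15              # technical duplicate noise
    link_slope: float = 5.0                 # logistic slope on the standardized score
    base_event_rate: float = 1.0 / 18.0     # per month; logistic/threshold links
    qc_fail_fraction: float = 0.0
    qc_fail_modes: tuple[str, ...] = ("hk_mean", "no_amplification", "low_rna")
    covariate_missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    lvi_recurrence_or: float = 1.0          # confounding hook (odds ratio)
    assay_seed: int = 0                     # fixes per-gene baseline Cts across cohorts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_target_genes < 1:
            raise ValueError("n_patients and n_target_genes must be positive")
        if not (0.0 < self.recurrence_prevalence < 1.0):
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.planted_hazard_ratio <= 0:
            raise ValueError("planted_hazard_ratio must be positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be nonnegative")
        if not (0.0 <= self.qc_fail_fraction < 1.0):
            raise ValueError("qc_fail_fraction must lie in [0, 1)")
        if self.outcome_link not in ("logistic", "threshold", "hazard"):
            raise ValueError(f"unknown outcome link {self.outcome_link!r}")
        if len(set(self.hk_gene_ids)) != 5:
            raise ValueError("exactly 5 distinct housekeeping genes required")

    @property
    def target_gene_ids(self) -> list[str]:
        """Key-gene symbols first, then numbered filler genes."""
        named = [g for g in KEY_GENES if g not in self.hk_gene_ids]
        ids = named[: self.n_target_genes]
        k = len(ids)
        ids += [f"TG{i:03d}" for i in range(k + 1, self.n_target_genes + 1)]
        return ids

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        doc = json.loads(text)
        rule = doc.pop("planted_rule", None)
        if rule is not None:
            rule = parse_rule(json.dumps(rule) if isinstance(rule, dict) else rule)
        for key in ("hk_gene_ids", "qc_fail_modes", "sets"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(planted_rule=rule, **doc)


def _gene_z(gene_id: str, assay_seed: int) -> float:
    """Deterministic standard-normal draw keyed by gene name."""
    import hashlib

    digest = hashlib.sha256(f"{assay_seed}:{gene_id}".encode()).digest()
    entropy = int.from_bytes(digest[:8], "little")
    return float(np.random.default_rng(entropy).standard_normal())


def _solve_intercept(z: np.ndarray, slope: float, prevalence: float) -> float:
    f = lambda a: float(np.mean(expit(a + slope * z))) - prevalence
    return brentq(f, -60.0, 60.0)


def _truncated_exponential(rng: np.random.Generator, rate: np.ndarray, horizon: float) -> np.ndarray:
    u = rng.random(rate.shape)
    return -np.log1p(-u * (1.0 - np.exp(-rate * horizon))) / rate


def generate_cohort(config: CohortConfig) -> tuple[CtPanel, pd.DataFrame]:
    """Generate one cohort; deterministic for a fixed ``config.seed``.

    Returns the Ct panel (duplicate measurements + RNA metadata) and
    the clinical table (indexed by patient id).  With
    ``qc_fail_fraction > 0`` the returned panel already carries the
    injected QC failures.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_patients
    targets = config.target_gene_ids
    hk = list(config.hk_gene_ids)
    if set(hk) & set(targets):
        raise ValueError("housekeeping and target gene ids must be disjoint")
    if config.planted_rule is not None:
        unknown = config.planted_rule.genes - set(targets)
        if unknown:
            raise ValueError(f"planted rule references unknown genes: {sorted(unknown)}")

    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    # -- true (noiseless) Ct values -----------------------------------
    # Per-gene baseline Cts are a property of the assay panel, not of a
    # cohort: they are derived from the gene name (plus assay_seed), so
    # every cohort generated against the same panel sees the same gene
    # baselines and rules transfer across cohorts as they would for a
    # real fixed assay.
    gene_mu = config.ct_mean + config.ct_sd * np.array(
        [_gene_z(g, config.assay_seed) for g in targets]
    )
    ct_true = gene_mu[None, :] + rng.normal(0.0, config.biological_sd, size=(n, len(targets)))
    hk_mu = config.hk_ct_mean + config.hk_ct_sd * np.array(
        [_gene_z(g, config.assay_seed) for g in hk]
    )
    hk_true = hk_mu[None, :] + rng.normal(0.0, config.hk_sample_sd, size=(n, 5))
    # instrument dynamic range: the panel genes were preselected to
    # amplify reliably, so true Cts are truncated well below the
    # acceptance ceiling
    ct_true = np.clip(ct_true, 15.0, 34.0)
    hk_true = np.clip(hk_true, 15.0, 34.0)

    hk_bar = hk_true.mean(axis=1)
    expr_true = 100.0 * np.power(2.0, hk_bar[:, None] - ct_true)
    expr_profile = {g: expr_true[:, j] for j, g in enumerate(targets)}

    # -- outcome ------------------------------------------------------
    if config.planted_rule is not None:
        score = np.asarray(evaluate_rule(config.planted_rule, expr_profile), dtype=float)
        score = np.broadcast_to(score, (n,)).copy()
    else:
        score = np.zeros(n)

    rule = config.planted_rule
    if config.outcome_link == "threshold":
        if rule is None:
            raise ValueError("threshold link requires a planted rule")
        if rule.slice_point is None:
            q = 1.0 - config.recurrence_prevalence
            sp = float(np.quantile(score, q if rule.high_risk_side == "at_or_above" else 1 - q))
            rule = rule.with_threshold(sp, rule.high_risk_side)
            config.planted_rule = rule  # realized slice point, kept for callers
        recurred = classify_scores(score, rule) == "high"
    elif config.outcome_link == "hazard":
        if rule is None:
            raise ValueError("hazard link requires a planted rule")
        if rule.slice_point is None:
            rule = rule.with_threshold(float(np.median(score)), rule.high_risk_side)
            config.planted_rule = rule  # realized slice point, kept for callers
        high = classify_scores(score, rule) == "high"
        q_high = float(high.mean())
        F, h = config.followup_months, config.planted_hazard_ratio

        def prev(lam: float) -> float:
            p_low = 1.0 - np.exp(-lam * F)
            p_high = 1.0 - np.exp(-h * lam * F)
            return q_high * p_high + (1 - q_high) * p_low - config.recurrence_prevalence

        lam_low = brentq(prev, 1e-9, 10.0)
        rate = np.where(high, h * lam_low, lam_low)
        t_event = rng.exponential(1.0, size=n) / rate
        recurred = t_event <= F
    else:  # logistic
        if rule is not None and np.unique(score).size > 1:
            # rank-based normal scores (Blom) rather than raw z-scores:
            # expression values are log-normal-ish so raw rule scores are
            # heavily skewed, which would make separability depend on the
            # realized skew; normal scores give the slope a
            # distribution-free meaning
            from scipy.stats import norm, rankdata

            z = norm.ppf((rankdata(score) - 0.375) / (n + 0.25))
        else:
            z = np.zeros(n)
        a = _solve_intercept(z, config.link_slope if rule is not None else 0.0,
                             config.recurrence_prevalence)
        recurred = rng.random(n) < expit(a + (config.link_slope if rule is not None else 0.0) * z)

    # -- survival times -----------------------------------------------
    F = config.followup_months
    time = np.full(n, F, dtype=float)
    event = recurred.copy()
    if config.outcome_link == "hazard":
        time = np.minimum(t_event, F)
    else:
        if rule is not None and rule.slice_point is not None:
            high = classify_scores(score, rule) == "high"
        elif rule is not None:
            high = score >= np.median(score)
        else:
            high = np.zeros(n, dtype=bool)
        rate = config.base_event_rate * np.where(high, config.planted_hazard_ratio, 1.0)
        t_rec = _truncated_exponential(rng, rate, F)
        time = np.where(recurred, t_rec, F)
    planted_high = high if rule is not None else np.zeros(n, dtype=bool)

    # -- clinicopathologic covariates ---------------------------------
    M = COVARIATE_MARGINALS
    site = rng.choice(list(M["site"]), size=n, p=list(M["site"].values()))
    t_class = np.empty(n, dtype=object)
    colon = site != "rectum"
    t_class[colon] = rng.choice(list(M["t_class_colon"]), size=int(colon.sum()),
                                p=list(M["t_class_colon"].values()))
    t_class[~colon] = rng.choice(list(M["t_class_rectum"]), size=int((~colon).sum()),
                                 p=list(M["t_class_rectum"].values()))
    stage = np.where(np.isin(t_class.astype(str), ["T1", "T2"]), "I", "II")
    grade = rng.choice(list(M["grade"]), size=n, p=list(M["grade"].values()))
    n_nodes = np.clip(np.round(np.exp(rng.normal(np.log(9.0), 0.55, size=n))), 2, 59).astype(int)
    age = np.clip(np.round(rng.normal(M["age_mean"], M["age_sd"], size=n)), 22, 90).astype(int)
    sex = np.where(rng.random(n) < M["female"], "F", "M")
    race = rng.choice(list(M["race"]), size=n, p=list(M["race"].values()))

    if config.lvi_recurrence_or != 1.0:
        # confounding hook: LVI odds shifted for recurrent patients
        base = M["lvi"]
        logit = np.log(base / (1 - base)) + np.log(config.lvi_recurrence_or) * recurred
        lvi = rng.random(n) < expit(logit)
    else:
        lvi = rng.random(n) < M["lvi"]
    pni = rng.random(n) < M["pni"]
    obstruction = rng.random(n) < M["obstruction_perforation"]

    def _with_missing(values: np.ndarray, frac: float) -> pd.array:
        arr = pd.array(values, dtype="boolean")
        if frac > 0:
            arr[rng.random(n) < frac] = pd.NA
        return arr

    miss = config.covariate_missingness
    clinical = pd.DataFrame(
        {
            "recurred_36mo": recurred,
            "time_months": np.round(time, 3),
            "event": event,
            "planted_high": planted_high,   # ground-truth rule group

            "t_class": t_class.astype(str),
            "n_nodes_examined": n_nodes,
            "grade": grade.astype(int),
            "lvi": _with_missing(lvi, miss.get("lvi", 0.0)),
            "pni": _with_missing(pni, miss.get("pni", 0.0)),
            "obstruction_perforation": _with_missing(
                obstruction, miss.get("obstruction_perforation", 0.0)
            ),
            "site": site.astype(str),
            "stage": stage.astype(str),
            "age_years": age,
            "sex": sex.astype(str),
            "race": race.astype(str),
            "margins_clear": True,
        },
        index=pd.Index(ids, name="patient_id"),
    )

    # -- measured Ct duplicates ---------------------------------------
    all_genes = hk + targets
    truth = np.concatenate([hk_true, ct_true], axis=1)
    rep1 = truth + rng.normal(0.0, config.replicate_sd, size=truth.shape)
    rep2 = truth + rng.normal(0.0, config.replicate_sd, size=truth.shape)
    ct = pd.DataFrame(
        {
            "sample_id": np.repeat(ids, len(all_genes)),
            "gene_id": np.tile(all_genes, n),
            "ct_rep1": np.round(rep1.ravel(), 4),
            "ct_rep2": np.round(rep2.ravel(), 4),
        }
    )
    meta = pd.DataFrame(
        {
            "rna_conc_ng_ul": np.round(rng.uniform(20.0, 80.0, size=n), 1),
            "a260_280": np.round(rng.uniform(1.85, 2.05, size=n), 3),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    panel = CtPanel(ct=ct, meta=meta, hk_genes=tuple(hk))
    if config.qc_fail_fraction > 0:
        panel = inject_qc_failures(panel, config)
    return panel, clinical


def inject_qc_failures(panel: CtPanel, config: CohortConfig) -> CtPanel:
    """Corrupt a fraction of samples so each fails exactly one criterion.

    The requested fraction (rounded to a whole count) of samples is
    drawn at random; each is assigned one failure mode uniformly from
    ``config.qc_fail_modes``:

    - ``hk_mean``: housekeeping Cts shifted so the HK mean exceeds 32,
    - ``no_amplification``: one target gene's both replicates removed,
    - ``low_rna``: RNA concentration dropped below 10 ng/uL.

    The mode is recorded in ``meta["injected_failure"]`` (empty for
    untouched samples).  Returns a new panel; the input is unchanged.
    """
    if not (0.0 <= config.qc_fail_fraction < 1.0):
        raise ValueError("qc_fail_fraction must lie in [0, 1)")
    ct = panel.ct.copy()
    meta = panel.meta.copy()
    meta["injected_failure"] = ""
    n_fail = int(round(config.qc_fail_fraction * len(meta)))
    if n_fail == 0:
        return CtPanel(ct=ct, meta=meta, hk_genes=panel.hk_genes)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(97,)))
    victims = rng.choice(meta.index.to_numpy(), size=n_fail, replace=False)
    modes = rng.choice(list(config.qc_fail_modes), size=n_fail)
    targets = panel.target_genes
    for sid, mode in zip(victims, modes):
        if mode == "hk_mean":
            mask = (ct["sample_id"] == sid) & ct["gene_id"].isin(panel.hk_genes)
            current = ct.loc[mask, ["ct_rep1", "ct_rep2"]].to_numpy(dtype=float).mean()
            delta = (32.6 - current) + float(rng.uniform(0.0, 0.8))
            ct.loc[mask, ["ct_rep1", "ct_rep2"]] += delta
        elif mode == "no_amplification":
            gene = targets[int(rng.integers(len(targets)))]
            mask = (ct["sample_id"] == sid) & (ct["gene_id"] == gene)
            ct.loc[mask, ["ct_rep1", "ct_rep2"]] = np.nan
        elif mode == "low_rna":
            meta.loc[sid, "rna_conc_ng_ul"] = float(np.round(rng.uniform(2.0, 9.0), 1))
        else:
            raise ValueError(f"unknown failure mode {mode!r}")
        meta.loc[sid, "injected_failure"] = mode
    return CtPanel(ct=ct, meta=meta, hk_genes=panel.hk_genes)


def bin_recurrence_time(clinical: pd.DataFrame, width_months: float = 12.0) -> pd.Series:
    """Bin recurrent patients' event times for use as a stratum.

    Nonrecurrent patients fall in a single ``"NR"`` bin; recurrent
    patients are binned by ``floor(time / width)``.
    """
    bins = (clinical["time_months"] // width_months).astype(int).astype(str)
    return pd.Series(
        np.where(clinical["recurred_36mo"].to_numpy(dtype=bool), "R" + bins, "NR"),
        index=clinical.index,
        name="time_bin",
    )


def stratified_split(
    clinical: pd.DataFrame,
    strata_keys: Sequence[str],
    ratio: float = 0.5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random split into two id lists, stratified on the given columns.

    The partition is exhaustive and disjoint; within each stratum the
    first group receives ``round(ratio * n)`` members, so at ratio 0.5
    the two sides differ by at most one per stratum.  Deterministic for
    a fixed seed.
    """
    if clinical.empty:
        raise ValueError("empty clinical table")
    missing = [k for k in strata_keys if k not in clinical.columns]
    if missing:
        raise ValueError(f"strata columns not in table: {missing}")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    key = clinical[list(strata_keys)].astype(str).agg("|".join, axis=1) if strata_keys \
        else pd.Series("all", index=clinical.index)
    ids_a: list[str] = []
    ids_b: list[str] = []
    for _, idx in key.groupby(key, sort=True).groups.items():
        members = rng.permutation(np.asarray(idx, dtype=object))
        n_a = int(round(ratio * len(members)))
        ids_a.extend(members[:n_a])
        ids_b.extend(members[n_a:])
    return sorted(ids_a), sorted(ids_b)
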