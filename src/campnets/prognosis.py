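"""Survival analysis of genes and gene sets: per-gene Cox fits, the
combined score, patient stratification, and cross-cancer meta-z.

Per-gene statistics come from univariate Cox proportional-hazards fits on
10-year (120-month) censored overall survival.  A gene set is summarized
per patient t as

    MV_t = sum_j w_j * E_j(t),      w_j = +1 if HR_j >= 1 else -1
    CS_t = MV_t * RC,               RC = -1 iff >= 75% of patients have MV < 0

where E_j is the stored log2 expression.  Sets where 26-74% of patients
have negative MV carry a mixed-sign flag (adverse vs favorable direction
cannot be evaluated).  Patients are stratified at the median CS or by an
auto-selected best cutoff scanned over the observed CS values in the
25-75% band, with the split assessed by the two-group log-rank test and a
Cox fit on the group indicator.  Per-cancer z-scores are combined by
Stouffer's unweighted method; |meta-z| >= 1.96 marks significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io_formats import ExpressionMatrix, SurvivalTable

logger = logging.getLogger("campnets")

#: 10-year horizon in months
HORIZON_MONTHS = 120.0
#: RC flips when at least this fraction of patients has MV < 0
RC_NEGATIVE_FRACTION = 0.75
#: band of negative-MV fractions where the direction is not evaluable
MIXED_SIGN_BAND = (0.26, 0.74)
META_Z_SIGNIFICANT = 1.96


@dataclass
class GeneSurvStats:
    """Univariate Cox statistics for one gene."""

    gene: str
    coef: float | None
    hr: float | None
    hr_ci: tuple[float, float] | None
    z: float | None
    p: float | None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.hr is not None and self.hr <= 0:
            raise ValueError(f"{self.gene}: HR must be positive")


@dataclass
class CombinedScore:
    """Per-patient combined prognostic score for one gene set."""

    values: pd.Series            # patient -> CS_t
    mv: pd.Series                # patient -> MV_t
    rc: int                      # -1 or +1
    mixed_sign: bool
    weights: pd.Series           # gene -> w_j


@dataclass
class StratificationResult:
    """High/low split of patients by combined score."""

    policy: str
    cutoff: float
    groups: pd.Series            # patient -> "high" | "low"
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    z: float


def censor_at_horizon(survival: SurvivalTable,
                      horizon: float = HORIZON_MONTHS) -> pd.DataFrame:
    """Administratively censor follow-up beyond the horizon."""
    t = survival.table.copy()
    beyond = t["months"] > horizon
    t.loc[beyond, "event"] = 0
    t.loc[beyond, "months"] = horizon
    return t


def per_gene_cox(expr: ExpressionMatrix,
                 survival: SurvivalTable,
                 genes: Iterable[str] | None = None,
                 horizon: float = HORIZON_MONTHS) -> dict[str, GeneSurvStats]:
    """Univariate Cox fit per gene on tumor expression (Efron ties).

    Requires at least 10 patients with both expression and clinical data
    and at least one event after horizon censoring.  Constant genes are
    flagged without an estimate.
    """
    clinical = censor_at_horizon(survival, horizon).set_index("patient")
    tumor = expr.tumor()
    patients = [p for p in tumor.columns if p in clinical.index]
    if len(patients) < 10:
        raise ValueError(f"need >= 10 patients with expression + clinical, got {len(patients)}")
    clinical = clinical.loc[patients]
    if clinical["event"].sum() == 0:
        raise ValueError("no events within the horizon; statistics undefined")
    genes = list(genes) if genes is not None else list(tumor.index)
    out: dict[str, GeneSurvStats] = {}
    for gene in genes:
        x = tumor.loc[gene, patients].astype(float)
        if x.std(ddof=0) == 0:
            out[gene] = GeneSurvStats(gene=gene, coef=None, hr=None, hr_ci=None,
                                      z=None, p=None, flagged=True)
            continue
        df = pd.DataFrame({"months": clinical["months"].to_numpy(),
                           "event": clinical["event"].to_numpy(),
                           "x": x.to_numpy()})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="months", event_col="event")
        except Exception as exc:  # convergence failure on degenerate input
            logger.warning("Cox fit failed for %s: %s", gene, exc)
            out[gene] = GeneSurvStats(gene=gene, coef=None, hr=None, hr_ci=None,
                                      z=None, p=None, flagged=True)
            continue
        s = cph.summary.loc["x"]
        out[gene] = GeneSurvStats(
            gene=gene, coef=float(s["coef"]), hr=float(s["exp(coef)"]),
            hr_ci=(float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
            z=float(s["z"]), p=float(s["p"]))
    return out


def combined_score(expr: ExpressionMatrix,
                   gene_stats: Mapping[str, GeneSurvStats],
                   gene_set: Iterable[str]) -> CombinedScore:
    """Combined score CS_t for a gene set over tumor samples.

    Every gene needs expression and an HR estimate.  HR exactly 1 gets
    weight +1.
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("empty gene set")
    tumor = expr.tumor()
    missing = [g for g in genes if g not in tumor.index]
    if missing:
        raise KeyError(f"genes without expression: {missing[:5]}")
    no_stats = [g for g in genes
                if g not in gene_stats or gene_stats[g].hr is None]
    if no_stats:
        raise KeyError(f"genes without survival statistics: {no_stats[:5]}")
    weights = pd.Series({g: (1.0 if gene_stats[g].hr >= 1.0 else -1.0)
                         for g in genes})
    mv = tumor.loc[genes].T.mul(weights, axis=1).sum(axis=1)
    frac_neg = float((mv < 0).mean())
    rc = -1 if frac_neg >= RC_NEGATIVE_FRACTION else 1
    mixed = MIXED_SIGN_BAND[0] <= frac_neg <= MIXED_SIGN_BAND[1]
    return CombinedScore(values=mv * rc, mv=mv, rc=rc,
                         mixed_sign=mixed, weights=weights)


def _group_stats(cs: pd.Series, clinical: pd.DataFrame,
                 cutoff: float) -> tuple[float, pd.Series]:
    high = cs >= cutoff
    if high.all() or (~high).all():
        return 1.0, pd.Series(dtype=object)
    res = logrank_test(clinical.loc[high.values, "months"],
                       clinical.loc[~high.values, "months"],
                       clinical.loc[high.values, "event"],
                       clinical.loc[~high.values, "event"])
    groups = pd.Series(np.where(high, "high", "low"), index=cs.index)
    return float(res.p_value), groups


def stratify(cs: CombinedScore,
             survival: SurvivalTable,
             policy: str = "median",
             horizon: float = HORIZON_MONTHS) -> StratificationResult:
    """Split patients into high/low combined-score groups.

    ``median`` cuts at the 50th percentile of CS; ``best`` scans every
    observed CS value within the interquartile 25-75% band and keeps the
    cutoff minimizing the two-group log-rank p (reported without
    multiplicity correction).  The group hazard ratio comes from a Cox
    fit on the high-group indicator.
    """
    if policy not in ("median", "best"):
        raise ValueError(f"policy must be 'median' or 'best', got {policy!r}")
    clinical = censor_at_horizon(survival, horizon).set_index("patient")
    patients = [p for p in cs.values.index if p in clinical.index]
    if len(patients) < 4:
        raise ValueError(f"need >= 4 patients, got {len(patients)}")
    scores = cs.values.loc[patients]
    clinical = clinical.loc[patients]
    if scores.nunique() == 1:
        raise ValueError("degenerate score: all combined scores identical")

    if policy == "median":
        cutoff = float(scores.median())
        # a median equal to the minimum would put everyone in "high"
        if (scores >= cutoff).all():
            cutoff = float(np.nextafter(cutoff, np.inf))
        logrank_p, groups = _group_stats(scores, clinical, cutoff)
    else:
        lo, hi = scores.quantile([0.25, 0.75])
        candidates = sorted(v for v in scores.unique() if lo <= v <= hi)
        if not candidates:
            candidates = [float(scores.median())]
        best_p, cutoff, groups = np.inf, None, None
        for cand in candidates:
            p, g = _group_stats(scores, clinical, float(cand))
            if len(g) and p < best_p:
                best_p, cutoff, groups = p, float(cand), g
        if cutoff is None:
            raise ValueError("no cutoff produced two non-empty groups")
        logrank_p = best_p

    df = pd.DataFrame({"months": clinical["months"].to_numpy(),
                       "event": clinical["event"].to_numpy(),
                       "high": (groups == "high").astype(float).to_numpy()})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="months", event_col="event")
    s = cph.summary.loc["high"]
    return StratificationResult(
        policy=policy, cutoff=float(cutoff), groups=groups,
        logrank_p=float(logrank_p), hr=float(s["exp(coef)"]),
        hr_ci=(float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
        z=float(s["z"]))


def km_coordinates(cs: CombinedScore, survival: SurvivalTable,
                   strat: StratificationResult,
                   horizon: float = HORIZON_MONTHS) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates for the two groups."""
    from lifelines import KaplanMeierFitter

    clinical = censor_at_horizon(survival, horizon).set_index("patient")
    frames = []
    for label in ("high", "low"):
        patients = strat.groups.index[strat.groups == label]
        sub = clinical.loc[[p for p in patients if p in clinical.index]]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["months"], sub["event"], label=label)
        frame = kmf.survival_function_.reset_index()
        frame.columns = ["months", "survival"]
        frame["group"] = label
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def prognostic_meta_z(z_by_cancer: Mapping[str, float] | Sequence[float]) -> float:
    """Stouffer meta-z of per-cancer prognostic z-scores.

    Positive z means adverse (HR > 1).  |meta-z| >= 1.96 marks a
    significant pan-cancer prognostic association.
    """
    if isinstance(z_by_cancer, Mapping):
        z = np.asarray(list(z_by_cancer.values()), dtype=float)
    else:
        z = np.asarray(z_by_cancer, dtype=float)
    if z.size == 0:
        raise ValueError("empty z vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("z values must be finite")
    return float(z.sum() / np.sqrt(z.size))


def global_prognostic_meta_z(meta_z_values: Sequence[float]) -> float:
    """Combine meta-z values across pathways or communities the same way."""
    return prognostic_meta_z(meta_z_values)
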