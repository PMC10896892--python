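"""Reporting layer: quartile risk stratification with hazard ratios,
model-comparison time-dependent AUCs, confusion matrices with
sensitivity/specificity, and the baseline-characteristics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SurvivalFrame
from .stats_core import TestResult, chi2_2x2_yates, mann_whitney_u, t_test_pooled
from .survival_core import CoxFit, cox_fit, ipcw_auc

__all__ = [
    "RiskGroups",
    "ConfusionReport",
    "stratify_quartiles",
    "group_hazard_ratios",
    "confusion_at_cutoff",
    "youden_cutoff",
    "compare_models",
    "baseline_table",
]


@dataclass
class RiskGroups:
    """Low / intermediate / high risk groups from score quartiles.

    low: score <= Q1; high: score >= Q3; intermediate strictly between.
    Quartiles use linear interpolation between order statistics.
    """

    labels: np.ndarray  # strings in {low, intermediate, high}
    q1: float
    q3: float

    @property
    def sizes(self) -> dict[str, int]:
        return {g: int((self.labels == g).sum())
                for g in ("low", "intermediate", "high")}


def stratify_quartiles(scores: np.ndarray) -> RiskGroups:
    s = np.asarray(scores, float)
    if s.size < 4:
        raise ValueError("need at least 4 samples to form quartile groups")
    if np.ptp(s) == 0:
        raise ValueError("constant scores cannot be stratified")
    q1 = float(np.quantile(s, 0.25))
    q3 = float(np.quantile(s, 0.75))
    labels = np.where(s <= q1, "low", np.where(s >= q3, "high", "intermediate"))
    return RiskGroups(labels=labels, q1=q1, q3=q3)


def group_hazard_ratios(
    frame: SurvivalFrame,
    groups: RiskGroups,
    adjust: list[str] | None = None,
) -> CoxFit:
    """Cox fit with intermediate-vs-low and high-vs-low indicator covariates
    (low risk is the reference group)."""
    for g in ("low", "intermediate", "high"):
        if (groups.labels == g).sum() == 0:
            raise ValueError(f"empty {g} risk group")
    if frame.event[groups.labels == "low"].sum() < 1:
        raise ValueError("no events in the low (reference) group")
    aug = frame.with_columns(
        {
            "grp_intermediate": (groups.labels == "intermediate").astype(float),
            "grp_high": (groups.labels == "high").astype(float),
        }
    )
    cols = ["grp_intermediate", "grp_high"] + list(adjust or [])
    return cox_fit(aug, cols)


@dataclass
class ConfusionReport:
    tn: int
    fn: int
    fp: int
    tp: int
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if min(self.tn, self.fn, self.fp, self.tp) < 0:
            raise ValueError("negative confusion count")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity_pct(self) -> int:
        """Whole-percent display convention."""
        return round(100.0 * self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return round(100.0 * self.specificity)

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp


def confusion_at_cutoff(
    risk_scores: np.ndarray, outcomes: np.ndarray, cutoff: float
) -> ConfusionReport:
    """Predict death when score > cutoff; tabulate against observed 0/1."""
    s = np.asarray(risk_scores, float)
    y = np.asarray(outcomes, int)
    if s.size != y.size:
        raise ValueError("scores and outcomes must align")
    pred = s > cutoff
    return ConfusionReport(
        tn=int(((~pred) & (y == 0)).sum()),
        fn=int(((~pred) & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tp=int((pred & (y == 1)).sum()),
        cutoff=float(cutoff),
    )


def youden_cutoff(risk_scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1."""
    s = np.asarray(risk_scores, float)
    y = np.asarray(outcomes, int)
    best, best_j = float(np.min(s)) - 1.0, -np.inf
    for c in np.unique(s):
        rep = confusion_at_cutoff(s, y, c)
        j = rep.sensitivity + rep.specificity - 1.0
        if j > best_j:
            best, best_j = float(c), j
    return best


def compare_models(
    frame: SurvivalFrame,
    model_score_sets: dict[str, np.ndarray | list[str]],
    horizon: float,
) -> pd.DataFrame:
    """IPCW AUC table for a set of candidate risk models.

    Each entry is either a ready score vector (a single factor or an
    external score) or a list of frame columns, in which case the model's
    score is the linear predictor of a Cox fit on those columns.  Constant
    scores are reported as AUC 0.5 with a degenerate flag.  Sorted by
    descending AUC.
    """
    if len(model_score_sets) < 2:
        raise ValueError("need at least 2 models to compare")
    rows = []
    for name, entry in model_score_sets.items():
        degenerate = False
        if isinstance(entry, (list, tuple)):
            fit = cox_fit(frame, list(entry))
            marker = frame.data[list(entry)].to_numpy(float) @ fit.coef
        else:
            marker = np.asarray(entry, float)
        if np.ptp(marker) == 0:
            auc = 0.5
            degenerate = True
        else:
            auc = ipcw_auc(frame, marker, horizon)
        rows.append((name, auc, degenerate))
    table = pd.DataFrame(rows, columns=["model", "auc", "degenerate"])
    return table.sort_values("auc", ascending=False).reset_index(drop=True)


_TESTS = {
    "t_test_pooled": "continuous",
    "mann_whitney_u": "continuous",
    "chi2_2x2_yates": "categorical",
}


def baseline_table(
    frame: SurvivalFrame,
    continuous_vars: list[str],
    categorical_vars: list[str],
    test_plan: dict[str, str],
) -> pd.DataFrame:
    """Baseline characteristics by vital status with per-variable tests.

    Continuous variables render mean ± SD per group; categorical 0/1
    variables render count (percent).  ``test_plan`` names the test per
    variable (``t_test_pooled``, ``mann_whitney_u`` or ``chi2_2x2_yates``).
    """
    for var, test in test_plan.items():
        if test not in _TESTS:
            raise ValueError(f"unknown test {test!r} for variable {var!r}")
    dead = frame.data[frame.data["event"] == 1]
    alive = frame.data[frame.data["event"] == 0]
    rows = []
    for var in continuous_vars:
        test = test_plan.get(var, "t_test_pooled")
        x, y = dead[var].to_numpy(float), alive[var].to_numpy(float)
        res: TestResult = (
            mann_whitney_u(x, y) if test == "mann_whitney_u"
            else t_test_pooled(x, y)
        )
        rows.append(
            (var,
             f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
             f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
             res.p_value, res.test_name)
        )
    for var in categorical_vars:
        a = int(dead[var].sum())
        b = len(dead) - a
        c = int(alive[var].sum())
        d = len(alive) - c
        res = chi2_2x2_yates(a, b, c, d)
        rows.append(
            (var,
             f"{a} ({100.0 * a / len(dead):.2f})",
             f"{c} ({100.0 * c / len(alive):.2f})",
             res.p_value, res.test_name)
        )
    return pd.DataFrame(
        rows, columns=["variable", "death", "survival", "p_value", "test"]
    )
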