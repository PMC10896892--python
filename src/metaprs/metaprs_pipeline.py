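"""Two-stage metaPRS construction.

Stage one picks, per trait, the P-value threshold whose score best explains
all-cause death in a covariate-adjusted logistic regression (maximum
Nagelkerke R²), then screens the chosen scores with covariate-adjusted Cox
regression at P < 0.1.  Stage two combines the surviving standardized
scores with cross-validated elastic-net Cox regression, selecting the
penalty whose out-of-fold IPCW AUC is maximal, and flattens the trait-level
mixing weights back to a single per-variant weight vector so the deployed
score is one weighted dosage sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel, SurvivalFrame
from .prs_engine import PrsModel, score as prs_score
from .stats_core import genotype_pca, logistic_fit
from .survival_core import CoxFit, CoxnetPath, cox_fit, coxnet_cv

logger = logging.getLogger(__name__)

__all__ = [
    "OptimalPrs",
    "OptimalPrsSet",
    "MetaPrsModel",
    "select_optimal_prs",
    "screen_prs",
    "build_metaprs",
    "apply_metaprs",
]

#: covariates used for both the logistic threshold selection and the Cox
#: screen, when present in the frame
ADJUSTMENT_COVARIATES = ["age", "sex", "PPI", "ACEI", "BB", "CCB"]


@dataclass
class OptimalPrs:
    trait_name: str
    model: PrsModel
    nagelkerke_r2: float
    score: np.ndarray  # standardized on the training panel
    raw_score: np.ndarray
    cox: CoxFit | None = None  # screening fit, attached by screen_prs


@dataclass
class OptimalPrsSet:
    entries: dict[str, OptimalPrs] = field(default_factory=dict)

    def traits(self) -> list[str]:
        return list(self.entries)

    def __getitem__(self, trait: str) -> OptimalPrs:
        return self.entries[trait]


@dataclass
class MetaPrsModel:
    """Trait mixing weights plus the flattened per-variant representation.

    ``components`` holds one row per surviving trait: the elastic-net
    coefficient on its standardized score (``mix_weight``) and the training
    mean/SD of its raw score.  ``weights`` flattens those into per-variant
    combined weights ``sum_t mix_t * beta_tj / sd_t`` (variants shared
    across traits summed), so deployment is a single weighted dosage sum
    z-scored against the stored training ``score_mean``/``score_sd``.
    """

    components: pd.DataFrame
    weights: pd.DataFrame  # variant_id, chromosome, position, effect_allele, weight
    alpha: float
    lambda_: float
    cv_seed: int
    horizon: float
    score_mean: float
    score_sd: float
    path: CoxnetPath | None = None

    @property
    def n_unique_variants(self) -> int:
        return len(self.weights)


def _adjustment_columns(frame: SurvivalFrame) -> list[str]:
    cols = [c for c in ADJUSTMENT_COVARIATES if c in frame.data.columns]
    return cols + list(frame.pc_names)


def attach_pcs(frame: SurvivalFrame, panel: GenotypePanel, k: int = 10) -> SurvivalFrame:
    """Add the top-k genotype principal components as PC1..PCk columns."""
    k = min(k, panel.n_samples - 1, panel.n_variants)
    pcs = genotype_pca(panel, k=k)
    data = frame.align_to(panel.sample_ids).data.copy()
    pc_names = [f"PC{i + 1}" for i in range(k)]
    for i, name in enumerate(pc_names):
        data[name] = pcs[:, i]
    return SurvivalFrame(data, list(frame.covariate_names), pc_names)


def select_optimal_prs(
    series_per_trait: dict[str, list[tuple[PrsModel, np.ndarray]]],
    frame: SurvivalFrame,
    adjust: bool = True,
) -> OptimalPrsSet:
    """Pick each trait's optimal threshold by maximum Nagelkerke R².

    For every threshold model the death indicator is regressed on the
    standardized score (plus age, sex, medications and PCs when ``adjust``);
    the threshold with the highest Nagelkerke R² wins, ties going to the
    smaller threshold (fewer variants).  Identical variant sets at adjacent
    thresholds are fitted once.  Traits whose series is empty are skipped
    with a warning.
    """
    death = frame.event
    Xadj = (
        frame.data[_adjustment_columns(frame)].to_numpy(float)
        if adjust and _adjustment_columns(frame)
        else None
    )
    out = OptimalPrsSet()
    for trait, series in series_per_trait.items():
        if not series:
            logger.warning("select_optimal_prs: trait %s has no models", trait)
            continue
        best = None
        prev_n = -1
        prev_r2 = None
        for model, z in series:
            if model.n_variants == prev_n:
                r2 = prev_r2  # nested grids: identical set => identical fit
            else:
                X = z[:, None] if Xadj is None else np.column_stack([z, Xadj])
                r2 = logistic_fit(death, X).nagelkerke_r2
                prev_n, prev_r2 = model.n_variants, r2
            if best is None or r2 > best[0] + 1e-12:
                best = (r2, model, z)
        r2, model, z = best
        out.entries[trait] = OptimalPrs(
            trait_name=trait, model=model, nagelkerke_r2=r2, score=z,
            raw_score=None,
        )
    return out


def screen_prs(
    optimal: OptimalPrsSet,
    frame: SurvivalFrame,
    p_cut: float = 0.1,
) -> list[str]:
    """Keep traits whose optimal score passes the Cox screen (Wald p < p_cut,
    strict), adjusting for age, sex, medications and genotype PCs."""
    survivors: list[str] = []
    adj = _adjustment_columns(frame)
    for trait, entry in optimal.entries.items():
        aug = frame.with_columns({"_score": entry.score})
        fit = cox_fit(aug, ["_score"] + adj)
        entry.cox = fit
        if fit.p[0] < p_cut:
            survivors.append(trait)
    return survivors


def build_metaprs(
    optimal: OptimalPrsSet,
    survivors: list[str],
    frame: SurvivalFrame,
    panel: GenotypePanel,
    alpha: float = 0.5,
    folds: int = 5,
    seed: int = 0,
    horizon: float | None = None,
    n_lambda: int = 100,
) -> MetaPrsModel:
    """Elastic-net Cox integration of the surviving trait scores.

    Standardized scores enter a coxnet path; the penalty is chosen by
    ``folds``-fold cross-validated IPCW AUC (ties to the larger lambda),
    the model is refit on all data at that penalty, and the trait mixing
    weights are flattened to unique variant weights.
    """
    if len(survivors) < 2:
        raise ValueError(
            "need >= 2 surviving traits to build a metaPRS; "
            "fall back to the single best PRS instead"
        )
    raw = {}
    for trait in survivors:
        entry = optimal[trait]
        raw[trait] = prs_score(panel, entry.model, standardize=False)
    aug = frame.with_columns({f"score_{t}": raw[t] for t in survivors})
    cols = [f"score_{t}" for t in survivors]
    path = coxnet_cv(aug, cols, alpha=alpha, folds=folds, seed=seed,
                     horizon=horizon, n_lambda=n_lambda)
    sel = path.selected_index
    coef_orig = path.coef[:, sel]  # per raw-score unit
    means = path.means
    sds = path.sds
    mix = coef_orig * sds  # per standardized-score unit

    components = pd.DataFrame(
        {"trait": survivors, "mix_weight": mix,
         "score_mean": means, "score_sd": sds}
    )

    # flatten: combined weight per variant = sum_t mix_t * beta_tj / sd_t
    pieces = []
    for trait, m, sd in zip(survivors, mix, sds):
        w = optimal[trait].model.weights.copy()
        w["weight"] = w["beta"] * (m / sd)
        pieces.append(w.drop(columns=["beta"]))
    flat = (
        pd.concat(pieces)
        .groupby(
            ["variant_id", "chromosome", "position", "effect_allele"],
            as_index=False, sort=True,
        )["weight"]
        .sum()
    )
    flat = flat.sort_values(
        ["chromosome", "position", "effect_allele", "variant_id"]
    ).reset_index(drop=True)

    combined_raw = np.zeros(panel.n_samples)
    for trait, m, sd in zip(survivors, mix, sds):
        combined_raw += (m / sd) * raw[trait]
    model = MetaPrsModel(
        components=components,
        weights=flat,
        alpha=alpha,
        lambda_=float(path.selected_lambda),
        cv_seed=seed,
        horizon=float(getattr(path, "cv_horizon", np.nan)),
        score_mean=float(combined_raw.mean()),
        score_sd=float(combined_raw.std()) if combined_raw.std() > 0 else 1.0,
        path=path,
    )
    return model


def apply_metaprs(
    model: MetaPrsModel,
    panel: GenotypePanel,
    allow_missing: bool = False,
) -> np.ndarray:
    """Score a panel with a fitted metaPRS.

    Weighted dosage sum over the flattened variants, z-scored against the
    stored training mean/SD.  Missing variants raise unless
    ``allow_missing``, in which case the raw score is rescaled by the ratio
    of total to present absolute weight before standardization.
    """
    idx = {}
    for j, (vid, ea) in enumerate(
        zip(panel.variants["variant_id"], panel.variants["effect_allele"])
    ):
        idx[(vid, ea)] = j
    cols, weights, missing = [], [], []
    for rec in model.weights.itertuples(index=False):
        key = (rec.variant_id, rec.effect_allele)
        if key in idx:
            cols.append(idx[key])
            weights.append(rec.weight)
        else:
            missing.append(key)
    if missing and not allow_missing:
        raise ValueError(f"metaPRS variants absent from panel: {missing[:10]}")
    if not cols:
        return np.zeros(panel.n_samples)
    raw = panel.dosage[:, cols] @ np.asarray(weights, float)
    if missing:
        total = float(np.abs(model.weights["weight"]).sum())
        present = float(np.abs(np.asarray(weights)).sum())
        if present > 0:
            raw *= total / present
    return (raw - model.score_mean) / model.score_sd
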