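"""Pruning-and-thresholding polygenic score construction.

The P+T recipe: harmonize GWAS summary statistics to the cohort's allele
encoding, greedily clump variants in linkage disequilibrium with stronger
signals (r² > 0.1 within a ±250 kb window by default, computed on the
analysis panel itself), then build one score per P-value threshold on a
log-spaced grid from genome-wide significance (5e-8) up to 0.5.

Raw scores are plain weighted dosage sums; standardized (z-scored) versions
feed every downstream association so effects read "per SD increment".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "PrsModel",
    "ClumpParams",
    "HarmonizeReport",
    "harmonize_alleles",
    "ld_r2",
    "clump",
    "score",
    "threshold_grid",
    "build_prs_series",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PrsModel:
    """Variant weights for one trait at one P-value threshold."""

    trait_name: str
    p_threshold: float
    weights: pd.DataFrame  # variant_id, chromosome, position, effect_allele, beta

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 0.5):
            raise ValueError(f"p_threshold {self.p_threshold} outside (0, 0.5]")
        self.weights = self.weights.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ClumpParams:
    r2_max: float = 0.1
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class HarmonizeReport:
    n_input: int = 0
    n_matched: int = 0
    n_swapped: int = 0
    n_strand_flipped: int = 0
    n_ambiguous_removed: int = 0
    n_unmatched: int = 0


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_alleles(
    stats: SummaryStats,
    panel: GenotypePanel,
    drop_ambiguous: bool = True,
) -> tuple[SummaryStats, HarmonizeReport]:
    """Align summary statistics to the panel's allele orientation.

    Matching is by (chromosome, position).  Effect sizes are re-signed when
    the effect/other alleles are swapped relative to the panel; strand flips
    (A<->T, C<->G complements) are resolved; strand-ambiguous variants (A/T
    and C/G pairs) are removed by default; unmatched variants are dropped.
    The aligned table uses the panel's variant ids and allele columns.
    """
    report = HarmonizeReport(n_input=stats.n_variants)
    panel_by_pos: dict[tuple[str, int], list[int]] = {}
    pv = panel.variants
    for j, (c, pos) in enumerate(
        zip(pv["chromosome"].astype(str), pv["position"].astype(int))
    ):
        panel_by_pos.setdefault((c, pos), []).append(j)

    rows = []
    for rec in stats.table.itertuples(index=False):
        a1, a2 = rec.effect_allele, rec.other_allele
        if drop_ambiguous and _is_ambiguous(a1, a2):
            report.n_ambiguous_removed += 1
            continue
        key = (str(rec.chromosome), int(rec.position))
        beta = None
        for j in panel_by_pos.get(key, []):
            pe = pv["effect_allele"].iat[j]
            po = pv["other_allele"].iat[j]
            f1, f2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
            if (a1, a2) == (pe, po) or (po == "N" and a1 == pe):
                beta = rec.beta
            elif (a2, a1) == (pe, po) or (po == "N" and a2 == pe):
                beta = -rec.beta
                report.n_swapped += 1
            elif (f1, f2) == (pe, po):
                beta = rec.beta
                report.n_strand_flipped += 1
            elif (f2, f1) == (pe, po):
                beta = -rec.beta
                report.n_strand_flipped += 1
                report.n_swapped += 1
            else:
                continue
            rows.append(
                (pv["variant_id"].iat[j], str(rec.chromosome),
                 int(rec.position), pe, po, float(beta),
                 float(rec.se), float(rec.p_value))
            )
            break
        if beta is None:
            report.n_unmatched += 1
    report.n_matched = len(rows)
    if not rows:
        logger.warning(
            "harmonize_alleles(%s): no variants matched the panel",
            stats.trait_name,
        )
    aligned = pd.DataFrame(rows, columns=SummaryStats.REQUIRED)
    return SummaryStats(stats.trait_name, aligned), report


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    A constant vector cannot be in LD with anything: returns 0 with a
    warning rather than NaN.
    """
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("dosage vectors must share length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("ld_r2: constant dosage vector; returning r2 = 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, r * r))


def clump(
    stats: SummaryStats,
    panel: GenotypePanel,
    params: ClumpParams = ClumpParams(),
) -> pd.DataFrame:
    """Greedy LD clumping of panel-aligned summary statistics.

    Repeatedly take the not-yet-removed variant with the smallest P-value
    (ties: chromosome, position, variant id) as an index variant, retain it,
    and remove every other remaining variant on the same chromosome within
    ``window_bp`` of it whose dosage r² with it exceeds ``r2_max``.  Returns
    the retained rows of ``stats.table`` in selection order.
    """
    t = stats.table
    panel_col = {}
    for j, vid in enumerate(panel.variants["variant_id"]):
        panel_col[vid] = j
    missing = [v for v in t["variant_id"] if v not in panel_col]
    if missing:
        raise ValueError(f"stats not aligned to panel; missing {missing[:5]}")

    order = np.lexsort(
        [
            t["variant_id"].to_numpy(),
            t["position"].to_numpy(),
            t["chromosome"].astype(str).to_numpy(),
            t["p_value"].to_numpy(),
        ]
    )
    chrom = t["chromosome"].astype(str).to_numpy()
    pos = t["position"].to_numpy(int)
    cols = np.array([panel_col[v] for v in t["variant_id"]])

    removed = np.zeros(len(t), bool)
    retained: list[int] = []
    for i in order:
        if removed[i]:
            continue
        retained.append(i)
        removed[i] = True
        near = np.nonzero(
            (~removed)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= params.window_bp)
        )[0]
        if near.size:
            di = panel.dosage[:, cols[i]]
            for j in near:
                if ld_r2(di, panel.dosage[:, cols[j]]) > params.r2_max:
                    removed[j] = True
    return t.iloc[retained].reset_index(drop=True)


def score(
    panel: GenotypePanel, model: PrsModel, standardize: bool = False
) -> np.ndarray:
    """Per-sample polygenic score: sum of beta x dosage over model variants.

    With ``standardize`` the scores are z-scored across samples so downstream
    hazard ratios read per SD increment.  Every model variant must be present
    in the panel with a matching effect allele.
    """
    idx = {}
    for j, (vid, ea) in enumerate(
        zip(panel.variants["variant_id"], panel.variants["effect_allele"])
    ):
        idx[(vid, ea)] = j
    cols, betas, missing = [], [], []
    for rec in model.weights.itertuples(index=False):
        key = (rec.variant_id, rec.effect_allele)
        if key in idx:
            cols.append(idx[key])
            betas.append(rec.beta)
        else:
            missing.append(key)
    if missing:
        raise ValueError(f"model variants absent from panel: {missing[:10]}")
    if not cols:
        return np.zeros(panel.n_samples)
    raw = panel.dosage[:, cols] @ np.asarray(betas, float)
    if standardize:
        sd = raw.std()
        if sd == 0:
            raise ValueError("constant score cannot be standardized")
        return (raw - raw.mean()) / sd
    return raw


def threshold_grid(
    p_min: float = 5e-8, p_max: float = 0.5, n_steps: int = 500
) -> np.ndarray:
    """Log-uniformly spaced P-value thresholds, inclusive of both endpoints."""
    if not (0.0 < p_min < p_max <= 1.0):
        raise ValueError(f"invalid bounds ({p_min}, {p_max})")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    grid = np.geomspace(p_min, p_max, n_steps)
    grid[0], grid[-1] = p_min, p_max
    return grid


def build_prs_series(
    stats: SummaryStats,
    panel: GenotypePanel,
    params: ClumpParams = ClumpParams(),
    grid: np.ndarray | None = None,
) -> list[tuple[PrsModel, np.ndarray]]:
    """All threshold models for one trait, with standardized score vectors.

    Clumps once, then for each grid threshold T keeps retained variants with
    p <= T.  Thresholds admitting no variant are skipped with a log entry.
    The variant sets are nested along the grid by construction.
    """
    if grid is None:
        grid = threshold_grid()
    retained = clump(stats, panel, params)
    out: list[tuple[PrsModel, np.ndarray]] = []
    for thr in grid:
        sel = retained.loc[retained["p_value"] <= thr]
        if sel.empty:
            logger.info(
                "build_prs_series(%s): no variant at p <= %g; skipped",
                stats.trait_name, thr,
            )
            continue
        model = PrsModel(
            trait_name=stats.trait_name,
            p_threshold=float(thr),
            weights=sel[
                ["variant_id", "chromosome", "position", "effect_allele", "beta"]
            ].copy(),
        )
        try:
            z = score(panel, model, standardize=True)
        except ValueError:
            logger.info(
                "build_prs_series(%s): constant score at p <= %g; skipped",
                stats.trait_name, thr,
            )
            continue
        out.append((model, z))
    return out
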