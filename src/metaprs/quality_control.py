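"""Sample- and variant-level quality control for genotype panels.

Filters are applied in a fixed, auditable order — sample call rate, variant
call rate, Hardy–Weinberg equilibrium, minor allele frequency, then
imputation quality when the panel carries an ``imputation_r2`` column — with
strictly-less-than removal semantics (a variant with MAF exactly at the
threshold is retained).  Residual missing dosages are mean-imputed per
variant after filtering, since downstream scoring needs a complete matrix.

The HWE test is the exact conditional test on hard-called genotype counts
(dosages rounded to the nearest integer for this test only), not the
chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "compute_maf",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; a unit fails when its statistic is *below* the
    corresponding minimum (or its HWE p is below ``hwe_p_min``)."""

    sample_call_rate_min: float = 0.95
    variant_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    imputation_r2_min: float = 0.3

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Per-step removal counts in application order, plus imputation count."""

    steps: list[tuple[str, str, int]] = field(default_factory=list)
    input_shape: tuple[int, int] = (0, 0)
    output_shape: tuple[int, int] = (0, 0)
    n_imputed_dosages: int = 0

    def add(self, step: str, kind: str, removed: int) -> None:
        self.steps.append((step, kind, int(removed)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "unit", "n_removed"])

    def check_consistency(self) -> None:
        lost_samples = sum(n for _, kind, n in self.steps if kind == "sample")
        lost_variants = sum(n for _, kind, n in self.steps if kind == "variant")
        assert self.input_shape[0] - lost_samples == self.output_shape[0]
        assert self.input_shape[1] - lost_variants == self.output_shape[1]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy–Weinberg proportions.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed configuration.  Returns 1.0 for monomorphic input.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count {counts}")
    n_AA, n_Aa, n_aa = counts
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes choice moot
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant:
    #   log C == lgamma terms; enumerate h with the parity of `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = (2 * n - rare - hets) // 2
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    idx = np.nonzero(hets == n_Aa)[0]
    if idx.size == 0:  # parity mismatch cannot happen with consistent counts
        raise ValueError(f"inconsistent genotype table {counts}")
    p_obs = prob[idx[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from a dosage vector (missing excluded)."""
    d = np.asarray(dosages, float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; MAF undefined")
    f = float(d.mean() / 2.0)
    return min(f, 1.0 - f)


def _hard_calls(column: np.ndarray) -> tuple[int, int, int]:
    """Round non-missing dosages to 0/1/2 genotype counts."""
    d = column[~np.isnan(column)]
    g = np.rint(d).astype(int)
    return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())


def apply_qc(
    panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypePanel, QcReport]:
    """Filter ``panel`` and mean-impute residual missingness.

    Steps, in order: (1) drop samples with call rate < sample minimum;
    (2) drop variants with call rate < variant minimum; (3) drop variants with
    exact HWE p < ``hwe_p_min``; (4) drop variants with MAF < ``maf_min``;
    (5) when ``imputation_r2`` is present, drop variants with R² < minimum
    (missing R² passes).  All removals use strict ``<``.
    """
    report = QcReport(input_shape=(panel.n_samples, panel.n_variants))

    # 1. sample call rate
    obs = ~np.isnan(panel.dosage)
    if panel.n_variants > 0:
        sample_cr = obs.mean(axis=1)
    else:
        sample_cr = np.ones(panel.n_samples)
    keep_s = sample_cr >= thresholds.sample_call_rate_min
    report.add("sample_call_rate", "sample", (~keep_s).sum())
    panel = panel.subset(sample_mask=keep_s)

    # 2. variant call rate
    obs = ~np.isnan(panel.dosage)
    variant_cr = obs.mean(axis=0) if panel.n_samples else np.ones(panel.n_variants)
    keep_v = variant_cr >= thresholds.variant_call_rate_min
    report.add("variant_call_rate", "variant", (~keep_v).sum())
    panel = panel.subset(variant_mask=keep_v)

    # 3. HWE exact test on hard calls
    hwe_p = np.array(
        [hwe_exact_test(*_hard_calls(panel.dosage[:, j]))
         for j in range(panel.n_variants)]
    )
    keep_v = hwe_p >= thresholds.hwe_p_min
    report.add("hwe_exact", "variant", (~keep_v).sum())
    panel = panel.subset(variant_mask=keep_v)

    # 4. MAF
    maf = np.array(
        [compute_maf(panel.dosage[:, j]) for j in range(panel.n_variants)]
    )
    keep_v = maf >= thresholds.maf_min
    report.add("maf", "variant", (~keep_v).sum())
    panel = panel.subset(variant_mask=keep_v)

    # 5. imputation R2 (consumed as metadata; missing values pass)
    r2 = panel.variants["imputation_r2"].to_numpy(float)
    keep_v = ~(r2 < thresholds.imputation_r2_min)
    report.add("imputation_r2", "variant", (~keep_v).sum())
    panel = panel.subset(variant_mask=keep_v)

    # mean-impute residual missingness so scoring sees a complete matrix
    dosage = panel.dosage.copy()
    miss = np.isnan(dosage)
    report.n_imputed_dosages = int(miss.sum())
    if report.n_imputed_dosages:
        col_means = np.nanmean(dosage, axis=0)
        jj = np.nonzero(miss.any(axis=0))[0]
        for j in jj:
            dosage[miss[:, j], j] = col_means[j]
        panel = GenotypePanel(panel.sample_ids, panel.variants, dosage)

    report.output_shape = (panel.n_samples, panel.n_variants)
    report.check_consistency()
    return panel, report
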