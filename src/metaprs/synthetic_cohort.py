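"""Synthetic cohort generator with the statistical structure the pipeline
assumes: LD-blocked genotypes in Hardy–Weinberg proportions, GWAS summary
statistics for partially overlapping correlated traits estimated on
independent external cohorts, baseline covariates, and right-censored
Weibull survival whose log-hazard is partly driven by the true per-trait
genetic scores.

Genotypes follow a Gaussian-copula model: each sample carries two
independent latent "haplotype" Gaussians per LD block with AR(1)
correlation ``within_block_rho`` between adjacent variants; thresholding at
the allele-frequency quantile yields allele indicators, and their sum is the
dosage.  Because the two haplotypes are independent, every variant is in
exact Hardy–Weinberg proportion by construction, while adjacent variants
are in tunable LD.  Defaults mirror the study conditions: 1,776 patients,
15 traits, ~10% death rate over at most 11 years of follow-up.

Everything is deterministic under (config, seed): the seed is split into
independent child streams for genotypes, trait architecture, external GWAS
cohorts and survival, so each component is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenotypePanel, SummaryStats, SurvivalFrame

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_survival",
    "simulate_cohort",
    "simulate_heldout_cohort",
]

_ALLELE_PAIRS = [  # non-complementary pairs only: harmonization keeps all
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate the cohort scale of the analysis this package
    reproduces: 1,776 patients, 15 GWAS traits with overlapping causal sets,
    ~10% observed deaths, follow-up capped at 11 years.
    """

    n_samples: int = 1776
    n_blocks: int = 40
    block_size: int = 10
    within_block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 15
    n_causal_per_trait: int = 30
    trait_overlap_fraction: float = 0.3
    heritability: float = 0.3
    gwas_n: int = 10_000
    hazard_weights: tuple[float, ...] | None = None
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.07, "sex": 0.3, "smoking": 0.4}
    )
    baseline_hazard_shape: float = 1.3
    baseline_hazard_scale: float = 28.0
    censor_rate_target: float = 0.90
    followup_cap: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_blocks", "block_size", "n_traits",
                     "n_causal_per_trait", "gwas_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.trait_overlap_fraction <= 1.0):
            raise ValueError("trait_overlap_fraction must lie in [0, 1]")
        if not (0.0 < self.censor_rate_target < 1.0):
            raise ValueError("censor_rate_target must lie in (0, 1)")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    def resolved_hazard_weights(self) -> np.ndarray:
        """Per-trait log-hazard contribution of the standardized true score.

        Default: the first five traits are causal for death at 0.3 per SD,
        the rest null (the study found a minority of traits driving hazard).
        """
        if self.hazard_weights is not None:
            w = np.asarray(self.hazard_weights, float)
            if w.size != self.n_traits:
                raise ValueError("hazard_weights length must equal n_traits")
            return w
        w = np.zeros(self.n_traits)
        w[: min(5, self.n_traits)] = 0.3
        return w


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery checks."""

    maf: np.ndarray
    causal_sets: list[np.ndarray]  # variant indices per trait
    true_betas: list[np.ndarray]  # aligned with causal_sets
    genetic_scores: np.ndarray | None = None  # (n_samples, n_traits), z-scored
    hazard_weights: np.ndarray | None = None
    covariate_effects: dict | None = None
    censor_horizon: float | None = None


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _block_chol(block_size: int, rho: float) -> np.ndarray:
    idx = np.arange(block_size)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


def _draw_dosages(
    rng: np.random.Generator, n: int, config: SimConfig, maf: np.ndarray
) -> np.ndarray:
    """Two latent AR(1) haplotype Gaussians per block, thresholded at the
    allele-frequency quantile; dosage = sum of the two allele indicators."""
    L = _block_chol(config.block_size, config.within_block_rho)
    thresholds = sps.norm.ppf(maf)
    dosage = np.empty((n, config.n_variants))
    for b in range(config.n_blocks):
        sl = slice(b * config.block_size, (b + 1) * config.block_size)
        h1 = rng.standard_normal((n, config.block_size)) @ L.T
        h2 = rng.standard_normal((n, config.block_size)) @ L.T
        thr = thresholds[sl]
        dosage[:, sl] = (h1 < thr).astype(float) + (h2 < thr).astype(float)
    return dosage


def _variant_table(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    rows = []
    for b in range(config.n_blocks):
        chrom = str((b % 22) + 1)
        base = 1_000_000 + (b // 22) * 10_000_000
        for k in range(config.block_size):
            j = b * config.block_size + k
            ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            rows.append(
                (f"rs{j + 1:06d}", chrom, base + k * 5_000, ea, oa,
                 float(rng.uniform(0.6, 1.0)))
            )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chromosome", "position", "effect_allele",
                 "other_allele", "imputation_r2"],
    )


def simulate_genotypes(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Generate the analysis cohort's genotype panel and start the truth
    record (sampled MAFs and per-trait causal architecture)."""
    rng_geno, rng_arch = _child_seeds(config.seed, 4)[:2]
    maf = rng_geno.uniform(*config.maf_range, size=config.n_variants)
    variants = _variant_table(rng_geno, config)
    dosage = _draw_dosages(rng_geno, config.n_samples, config, maf)
    panel = GenotypePanel(
        [f"s{i + 1:05d}" for i in range(config.n_samples)], variants, dosage
    )
    truth = SimTruth(maf=maf, **_trait_architecture(rng_arch, config, maf))
    truth.hazard_weights = config.resolved_hazard_weights()
    truth.covariate_effects = dict(config.covariate_effects)
    # per-sample true genetic scores on the analysis panel, z-scored
    scores = np.empty((config.n_samples, config.n_traits))
    for t in range(config.n_traits):
        raw = dosage[:, truth.causal_sets[t]] @ truth.true_betas[t]
        sd = raw.std()
        scores[:, t] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    truth.genetic_scores = scores
    return panel, truth


def _trait_architecture(
    rng: np.random.Generator, config: SimConfig, maf: np.ndarray
) -> dict:
    """Causal variant sets with pairwise overlap and shared effect sizes.

    A shared pool of ``round(overlap_fraction * n_causal)`` variants (with a
    single beta each) enters every trait; the remainder is drawn per trait.
    Shared architecture is what makes the resulting PRSs correlate.
    """
    m = config.n_variants
    k = min(config.n_causal_per_trait, m)
    n_shared = int(round(config.trait_overlap_fraction * k))
    shared = rng.choice(m, size=n_shared, replace=False)
    shared_betas = rng.normal(0.0, 1.0, size=n_shared)
    causal_sets, true_betas = [], []
    for _ in range(config.n_traits):
        pool = np.setdiff1d(np.arange(m), shared, assume_unique=False)
        own = rng.choice(pool, size=k - n_shared, replace=False)
        idx = np.concatenate([shared, own]).astype(int)
        beta = np.concatenate(
            [shared_betas, rng.normal(0.0, 1.0, size=k - n_shared)]
        )
        # scale so the causal-score variance matches target heritability
        # against unit phenotype variance: var(G beta) = h2 / (1 - h2) * noise
        var_g = np.sum(2 * maf[idx] * (1 - maf[idx]) * beta ** 2)
        beta *= np.sqrt(config.heritability / max(var_g, 1e-12))
        causal_sets.append(idx)
        true_betas.append(beta)
    return {"causal_sets": causal_sets, "true_betas": true_betas}


def simulate_summary_stats(
    panel: GenotypePanel, truth: SimTruth, config: SimConfig
) -> list[SummaryStats]:
    """Per-trait GWAS summary statistics from independent external cohorts.

    For each trait an external cohort of ``gwas_n`` genotypes is drawn from
    the same generator, a quantitative phenotype is simulated from the
    trait's true betas at the configured heritability, and per-variant
    marginal least-squares regression yields beta, se and p.
    """
    rng_stats = _child_seeds(config.seed, 4)[2]
    out = []
    for t in range(config.n_traits):
        G = _draw_dosages(rng_stats, config.gwas_n, config, truth.maf)
        g_score = G[:, truth.causal_sets[t]] @ truth.true_betas[t]
        noise_sd = np.sqrt(max(1.0 - config.heritability, 1e-9))
        y = g_score + rng_stats.normal(0.0, noise_sd, size=config.gwas_n)
        beta, se, p = _marginal_regression(G, y)
        table = panel.variants.drop(columns=["imputation_r2"]).copy()
        table["beta"] = beta
        table["se"] = se
        table["p_value"] = np.clip(p, np.nextafter(0, 1), 1.0)
        out.append(SummaryStats(f"trait_{t + 1:02d}", table))
    return out


def _marginal_regression(G: np.ndarray, y: np.ndarray):
    """Vectorized per-variant simple linear regression of y on each column."""
    n = y.size
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    sxx = np.where(sxx > 0, sxx, np.nan)
    beta = gc.T @ yc / sxx
    resid_ss = (yc ** 2).sum() - beta ** 2 * sxx
    se = np.sqrt(np.clip(resid_ss / (n - 2), 1e-300, None) / sxx)
    tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    beta = np.nan_to_num(beta, nan=0.0)
    se = np.where(np.isnan(se), 1.0, se)
    p = np.where(np.isnan(p), 1.0, p)
    return beta, se, p


def simulate_survival(
    panel: GenotypePanel, truth: SimTruth, config: SimConfig
) -> SurvivalFrame:
    """Right-censored Weibull survival driven by true genetic scores.

    log-hazard = sum_t hazard_weights[t] * z(score_t) + covariate effects
    (age centred at its mean).  Event times are Weibull by inverse
    transform; censoring is uniform on (0, horizon] with the horizon
    calibrated by bisection so the realized event fraction lands within
    +-1% of ``1 - censor_rate_target``; follow-up is capped at 11 years.
    """
    rng = _child_seeds(config.seed, 4)[3]
    return _survival_from_scores(
        truth.genetic_scores, panel.sample_ids, truth, config, rng
    )


def _survival_from_scores(
    genetic_scores: np.ndarray,
    sample_ids: list[str],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> SurvivalFrame:
    n = len(sample_ids)
    ce = config.covariate_effects
    age = np.clip(rng.normal(62.0, 10.0, size=n), 30.0, 90.0)
    genetic_scores = np.asarray(genetic_scores, float)
    covs = {
        "age": age,
        "sex": rng.binomial(1, 0.80, size=n).astype(float),
        "smoking": rng.binomial(1, 0.30, size=n).astype(float),
        "PPI": rng.binomial(1, 0.54, size=n).astype(float),
        "ACEI": rng.binomial(1, 0.59, size=n).astype(float),
        "BB": rng.binomial(1, 0.88, size=n).astype(float),
        "CCB": rng.binomial(1, 0.27, size=n).astype(float),
    }
    w = truth.hazard_weights
    eta = genetic_scores @ w
    eta += ce.get("age", 0.0) * (age - age.mean())
    eta += ce.get("sex", 0.0) * covs["sex"] + ce.get("smoking", 0.0) * covs["smoking"]

    u = rng.uniform(size=n)
    T = config.baseline_hazard_scale * (-np.log(u) / np.exp(eta)) ** (
        1.0 / config.baseline_hazard_shape
    )
    u_cens = rng.uniform(size=n)

    target = 1.0 - config.censor_rate_target
    cap = config.followup_cap

    def event_fraction(h: float) -> float:
        follow = np.minimum(u_cens * h, cap)
        return float((T <= follow).mean())

    lo, hi = 1e-3, cap / min(np.min(u_cens), 1.0) * 10
    if event_fraction(hi) < target - 0.01:
        raise RuntimeError(
            f"censoring target unattainable: max event fraction "
            f"{event_fraction(hi):.3f} < {target:.3f}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if event_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(event_fraction(mid) - target) <= 0.005:
            break
    horizon = 0.5 * (lo + hi)
    truth.censor_horizon = horizon
    follow = np.minimum(u_cens * horizon, cap)
    event = (T <= follow).astype(int)
    time = np.where(event == 1, T, follow)
    time = np.maximum(time, 1e-6)

    data = pd.DataFrame({"time": time, "event": event, **covs},
                        index=pd.Index(sample_ids, name="sample_id"))
    return SurvivalFrame(data, list(covs.keys()), [])


def simulate_heldout_cohort(
    truth: SimTruth,
    config: SimConfig,
    seed: int,
    n_samples: int | None = None,
) -> tuple[GenotypePanel, SurvivalFrame]:
    """Fresh samples from the identical generating process.

    Re-derives the full (pre-QC) variant table and MAFs deterministically
    from ``config``, keeps the trait architecture in ``truth``, and draws
    new genotypes, covariates and survival under ``seed`` — the held-out
    set for generalization checks of a fitted metaPRS.
    """
    n = n_samples or config.n_samples
    rng_geno = _child_seeds(config.seed, 4)[0]
    maf = rng_geno.uniform(*config.maf_range, size=config.n_variants)
    variants = _variant_table(rng_geno, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 7]))
    dosage = _draw_dosages(rng, n, config, maf)
    new_panel = GenotypePanel(
        [f"h{i + 1:05d}" for i in range(n)], variants, dosage
    )
    scores = np.empty((n, config.n_traits))
    for t in range(config.n_traits):
        raw = dosage[:, truth.causal_sets[t]] @ truth.true_betas[t]
        sd = raw.std()
        scores[:, t] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    frame = _survival_from_scores(scores, new_panel.sample_ids, truth,
                                  config, rng)
    return new_panel, frame


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypePanel, list[SummaryStats], SurvivalFrame, SimTruth]:
    """Genotypes, per-trait summary statistics, survival frame and truth."""
    panel, truth = simulate_genotypes(config)
    stats = simulate_summary_stats(panel, truth, config)
    frame = simulate_survival(panel, truth, config)
    return panel, stats, frame, truth
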