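import numpy as np
import pandas as pd
import pytest

from metaprs.io_formats import GenotypePanel, SummaryStats, SurvivalFrame
from metaprs.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across modules."""
    config = SimConfig(
        n_samples=600, n_blocks=12, block_size=8, n_traits=4,
        n_causal_per_trait=10, trait_overlap_fraction=0.0, gwas_n=4000,
        hazard_weights=(0.8, 0.8, 0.0, 0.0), seed=11,
    )
    panel, stats_list, frame, truth = simulate_cohort(config)
    return {"config": config, "panel": panel, "stats": stats_list,
            "frame": frame, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_panel(dosage, positions=None, chrom="1", effect="A", other="C"):
    """Hand-build a GenotypePanel around a dosage matrix."""
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    positions = positions if positions is not None else 1000 * (np.arange(m) + 1)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chromosome": [chrom] * m if isinstance(chrom, str) else list(chrom),
            "position": positions,
            "effect_allele": [effect] * m if isinstance(effect, str) else list(effect),
            "other_allele": [other] * m if isinstance(other, str) else list(other),
            "imputation_r2": [np.nan] * m,
        }
    )
    return GenotypePanel([f"s{i}" for i in range(n)], variants, dosage)


def make_frame(time, event, **covs):
    time = np.asarray(time, float)
    data = pd.DataFrame(
        {"time": time, "event": np.asarray(event, int), **covs},
        index=pd.Index([f"s{i}" for i in range(time.size)], name="sample_id"),
    )
    return SurvivalFrame(data, list(covs.keys()), [])


def make_stats(trait="t", **cols):
    m = len(cols["position"])
    defaults = {
        "variant_id": [f"v{j}" for j in range(m)],
        "chromosome": ["1"] * m,
        "effect_allele": ["A"] * m,
        "other_allele": ["C"] * m,
        "beta": [0.1] * m,
        "se": [0.05] * m,
        "p_value": [0.01] * m,
    }
    defaults.update(cols)
    return SummaryStats(trait, pd.DataFrame(defaults))
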