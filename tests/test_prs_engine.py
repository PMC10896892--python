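"""P+T engine: harmonization case enumeration, LD r², greedy clumping vs a
literal oracle, scoring linearity and the threshold grid."""

import numpy as np
import pandas as pd
import pytest

from metaprs.io_formats import SummaryStats
from metaprs.prs_engine import (
    ClumpParams,
    PrsModel,
    build_prs_series,
    clump,
    harmonize_alleles,
    ld_r2,
    score,
    threshold_grid,
)

from conftest import make_panel, make_stats


class TestHarmonizeAlleles:
    def _panel(self):
        return make_panel(
            np.tile([0.0, 1.0, 2.0], (4, 1)).T,
            positions=[10, 20, 30, 40],
            effect=["A", "G", "C", "T"],
            other=["G", "A", "T", "C"],
        )

    def test_swapped_alleles_flip_sign(self):
        panel = self._panel()
        stats = make_stats(position=[10], effect_allele=["G"],
                           other_allele=["A"], beta=[0.2])
        aligned, rep = harmonize_alleles(stats, panel)
        assert aligned.table["beta"].iloc[0] == pytest.approx(-0.2)
        assert rep.n_swapped == 1

    def test_ambiguous_pair_removed(self):
        panel = self._panel()
        stats = make_stats(position=[10], effect_allele=["A"],
                           other_allele=["T"], beta=[0.3])
        aligned, rep = harmonize_alleles(stats, panel)
        assert aligned.n_variants == 0 and rep.n_ambiguous_removed == 1

    def test_planted_cases_match_enumeration(self, rng):
        # panel of 500 variants; stats planted per-case: match / swap /
        # strand-flip / flip+swap / ambiguous / unmatched position
        m = 500
        pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
        eff, oth = zip(*[pairs[i % 4] for i in range(m)])
        panel = make_panel(
            rng.binomial(2, 0.3, size=(5, m)).astype(float),
            positions=10 * (np.arange(m) + 1), effect=list(eff),
            other=list(oth),
        )
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        cases, expected = [], []
        for j in range(m):
            pe, po = eff[j], oth[j]
            pos = 10 * (j + 1)
            kind = j % 6
            if kind == 0:
                cases.append((pos, pe, po, 0.1))
                expected.append((f"v{j}", 0.1))
            elif kind == 1:
                cases.append((pos, po, pe, 0.1))
                expected.append((f"v{j}", -0.1))
            elif kind == 2:
                cases.append((pos, comp[pe], comp[po], 0.1))
                expected.append((f"v{j}", 0.1))
            elif kind == 3:
                cases.append((pos, comp[po], comp[pe], 0.1))
                expected.append((f"v{j}", -0.1))
            elif kind == 4:
                cases.append((pos, "A", "T", 0.1))  # ambiguous: dropped
            else:
                cases.append((pos + 5, pe, po, 0.1))  # unmatched: dropped
        stats = make_stats(
            position=[c[0] for c in cases],
            effect_allele=[c[1] for c in cases],
            other_allele=[c[2] for c in cases],
            beta=[c[3] for c in cases],
            variant_id=[f"x{i}" for i in range(len(cases))],
        )
        aligned, rep = harmonize_alleles(stats, panel)
        got = list(zip(aligned.table["variant_id"], aligned.table["beta"]))
        assert sorted(got) == sorted(expected)
        assert rep.n_ambiguous_removed == sum(1 for j in range(m) if j % 6 == 4)
        assert rep.n_unmatched == sum(1 for j in range(m) if j % 6 == 5)


class TestLdR2:
    def test_identical_vectors(self):
        assert ld_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert ld_r2([0, 1, 2, 0], [2, 1, 0, 2]) == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        a, b = rng.uniform(0, 2, 100), rng.uniform(0, 2, 100)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov ** 2 / (a.var() * b.var())
        assert ld_r2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_zero(self):
        assert ld_r2(np.ones(10), np.arange(10.0)) == 0.0


def literal_clump_oracle(table, panel, r2max, window):
    """The greedy definition transcribed naively (set-based, O(n^2))."""
    recs = table.to_dict("records")
    col = {v: j for j, v in enumerate(panel.variants["variant_id"])}
    alive = set(range(len(recs)))
    kept = []
    while alive:
        i = min(alive, key=lambda k: (recs[k]["p_value"],
                                      str(recs[k]["chromosome"]),
                                      recs[k]["position"],
                                      recs[k]["variant_id"]))
        kept.append(recs[i]["variant_id"])
        alive.discard(i)
        for j in list(alive):
            same_chrom = str(recs[j]["chromosome"]) == str(recs[i]["chromosome"])
            close = abs(recs[j]["position"] - recs[i]["position"]) <= window
            if same_chrom and close:
                a = panel.dosage[:, col[recs[i]["variant_id"]]]
                b = panel.dosage[:, col[recs[j]["variant_id"]]]
                if np.ptp(a) > 0 and np.ptp(b) > 0 \
                        and np.corrcoef(a, b)[0, 1] ** 2 > r2max:
                    alive.discard(j)
    return kept


def _random_clump_instance(rng, m=20, n=60):
    pos = np.sort(rng.choice(10 ** 6, m, replace=False))
    chrom = rng.choice(["1", "2"], m)
    dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    for j in range(1, m):
        if rng.uniform() < 0.5:
            dosage[:, j] = dosage[:, j - 1]  # plant perfect LD
    panel = make_panel(dosage, positions=pos, chrom=list(chrom))
    table = panel.variants.drop(columns="imputation_r2").copy()
    table["beta"] = rng.normal(size=m)
    table["se"] = 1.0
    table["p_value"] = rng.choice([1e-6, 1e-4, 1e-2, 0.3], m)  # ties on purpose
    return SummaryStats("t", table), panel


class TestClump:
    def test_single_variant_retained(self, rng):
        panel = make_panel(rng.binomial(2, 0.4, (20, 1)).astype(float))
        stats = make_stats(position=[1000])
        assert len(clump(stats, panel)) == 1

    def test_outside_window_both_retained(self, rng):
        d = rng.binomial(2, 0.4, size=(50, 1)).astype(float)
        dosage = np.column_stack([d, d])  # r2 = 1 but 300 kb apart
        panel = make_panel(dosage, positions=[1_000, 301_000])
        stats = make_stats(position=[1_000, 301_000], p_value=[0.01, 0.02])
        assert len(clump(stats, panel)) == 2

    def test_inside_window_weaker_removed(self, rng):
        d = rng.binomial(2, 0.4, size=(50, 1)).astype(float)
        panel = make_panel(np.column_stack([d, d]), positions=[1_000, 201_000])
        stats = make_stats(position=[1_000, 201_000], p_value=[0.01, 0.02])
        kept = clump(stats, panel)
        assert list(kept["position"]) == [1_000]

    def test_matches_literal_oracle_on_planted_instances(self):
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            stats, panel = _random_clump_instance(rng)
            mine = list(clump(stats, panel)["variant_id"])
            oracle = literal_clump_oracle(stats.table, panel, 0.1, 250_000)
            assert mine == oracle

    def test_row_order_invariance(self, rng):
        stats, panel = _random_clump_instance(rng)
        shuffled = SummaryStats(
            "t", stats.table.sample(frac=1, random_state=3)
        )
        assert list(clump(stats, panel)["variant_id"]) == \
            list(clump(shuffled, panel)["variant_id"])

    def test_retained_set_is_clump_free(self, rng):
        stats, panel = _random_clump_instance(rng)
        kept = clump(stats, panel)
        col = {v: j for j, v in enumerate(panel.variants["variant_id"])}
        rows = kept.to_dict("records")
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                if str(a["chromosome"]) == str(b["chromosome"]) \
                        and abs(a["position"] - b["position"]) <= 250_000:
                    r2 = ld_r2(panel.dosage[:, col[a["variant_id"]]],
                               panel.dosage[:, col[b["variant_id"]]])
                    assert r2 <= 0.1


class TestScore:
    def _model(self, betas):
        return PrsModel("t", 0.5, pd.DataFrame({
            "variant_id": [f"v{j}" for j in range(len(betas))],
            "chromosome": ["1"] * len(betas),
            "position": 1000 * (np.arange(len(betas)) + 1),
            "effect_allele": ["A"] * len(betas),
            "beta": betas,
        }))

    def test_single_variant_linear_in_dosage(self):
        panel = make_panel(np.array([[0.0], [1.0], [2.0]]))
        s = score(panel, self._model([0.5]))
        np.testing.assert_allclose(s, [0.0, 0.5, 1.0])

    def test_zero_betas_zero_scores(self):
        panel = make_panel(np.array([[1.0, 2.0], [0.0, 1.0]]))
        np.testing.assert_array_equal(score(panel, self._model([0.0, 0.0])),
                                      [0.0, 0.0])

    def test_matches_matrix_product_and_standardizes(self, rng):
        dosage = rng.uniform(0, 2, size=(4, 3))
        betas = rng.normal(size=3)
        panel = make_panel(dosage)
        raw = score(panel, self._model(betas))
        np.testing.assert_allclose(raw, dosage @ betas, atol=1e-12)
        z = score(panel, self._model(betas), standardize=True)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_linearity_in_weights(self, rng):
        dosage = rng.uniform(0, 2, size=(6, 4))
        panel = make_panel(dosage)
        b1, b2 = rng.normal(size=4), rng.normal(size=4)
        s = score(panel, self._model(b1 + b2))
        np.testing.assert_allclose(
            s, score(panel, self._model(b1)) + score(panel, self._model(b2)),
            atol=1e-12,
        )

    def test_missing_variant_listed(self, rng):
        panel = make_panel(rng.uniform(0, 2, (3, 1)))
        model = self._model([0.1, 0.2])
        with pytest.raises(ValueError, match="v1"):
            score(panel, model)


class TestThresholdGrid:
    def test_two_steps_are_endpoints(self):
        np.testing.assert_array_equal(threshold_grid(n_steps=2), [5e-8, 0.5])

    def test_three_steps_midpoint_is_geometric_mean(self):
        grid = threshold_grid(n_steps=3)
        assert grid[1] == pytest.approx(np.sqrt(5e-8 * 0.5), rel=1e-6)

    def test_sorted_unique_with_requested_length(self):
        grid = threshold_grid(n_steps=137)
        assert grid.size == 137
        assert np.all(np.diff(grid) > 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            threshold_grid(p_min=0.5, p_max=0.1)


class TestBuildPrsSeries:
    def test_nested_variant_sets_along_grid(self, small_cohort):
        panel = small_cohort["panel"]
        stats = small_cohort["stats"][0]
        aligned, _ = harmonize_alleles(stats, panel)
        series = build_prs_series(aligned, panel,
                                  grid=threshold_grid(n_steps=12))
        assert series, "expected at least one non-empty model"
        prev = set()
        for model, z in series:
            current = set(model.weights["variant_id"])
            assert prev <= current
            prev = current
            assert z.shape == (panel.n_samples,)

    def test_counts_match_filter_oracle(self, rng):
        m = 50
        dosage = rng.binomial(2, rng.uniform(0.1, 0.5, m),
                              size=(80, m)).astype(float)
        # spread variants far apart so clumping keeps everything
        panel = make_panel(dosage, positions=10 ** 6 * (np.arange(m) + 1))
        pvals = 10 ** rng.uniform(-8, -0.4, size=m)
        stats = make_stats(position=10 ** 6 * (np.arange(m) + 1),
                           p_value=pvals, beta=rng.normal(size=m))
        grid = threshold_grid(n_steps=8)
        series = build_prs_series(stats, panel, grid=grid)
        by_threshold = {m_.p_threshold: m_.n_variants for m_, _ in series}
        for thr in grid:
            expected = int((pvals <= thr).sum())
            if expected:
                assert by_threshold[float(thr)] == expected

    def test_no_genomewide_hits_gives_empty_series(self, rng):
        panel = make_panel(rng.binomial(2, 0.3, (30, 3)).astype(float))
        stats = make_stats(position=[1000, 2000, 3000],
                           p_value=[0.01, 0.2, 0.4])
        assert build_prs_series(stats, panel, grid=np.array([5e-8])) == []
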