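"""Spearman profiles, module contrast, top-k list and density export."""

import math

import numpy as np
import pytest

from rarevar.coexpression import (
    ExpressionMatrix,
    density_export,
    module_contrast,
    spearman_profile,
    top_coexpressed,
)
from rarevar.errors import DomainError, LookupMissingError
from rarevar.synthetic import SimulationSpec, gen_expression


@pytest.fixture(scope="module")
def small_matrix():
    rng = np.random.default_rng(0)
    target = rng.normal(size=40)
    rows = {
        "TARGET": target,
        "COPY": target.copy(),
        "MONO_DEC": -np.exp(target),  # strictly decreasing transform
        "MONO_INC": target**3 + 5,  # strictly increasing transform
        "NOISE_A": rng.normal(size=40),
        "NOISE_B": rng.normal(size=40),
    }
    return ExpressionMatrix(
        gene_ids=tuple(rows),
        sample_ids=tuple(f"s{i}" for i in range(40)),
        values=np.vstack(list(rows.values())),
    )


class TestSpearmanProfile:
    def test_identical_gene_is_one(self, small_matrix):
        rhos = spearman_profile(small_matrix, "TARGET", ["COPY"])
        assert rhos["COPY"] == pytest.approx(1.0)

    def test_decreasing_monotone_transform_is_minus_one(self, small_matrix):
        rhos = spearman_profile(small_matrix, "TARGET", ["MONO_DEC"])
        assert rhos["MONO_DEC"] == pytest.approx(-1.0)

    def test_invariant_under_increasing_monotone_transform(self, small_matrix):
        a = spearman_profile(small_matrix, "TARGET", ["NOISE_A"])["NOISE_A"]
        b = spearman_profile(small_matrix, "MONO_INC", ["NOISE_A"])["NOISE_A"]
        assert a == pytest.approx(b)

    def test_absent_genes_skipped_and_countable(self, small_matrix):
        rhos = spearman_profile(small_matrix, "TARGET", ["COPY", "GHOST1", "GHOST2"])
        assert list(rhos.index) == ["COPY"]

    def test_absent_target_raises(self, small_matrix):
        with pytest.raises(LookupMissingError):
            spearman_profile(small_matrix, "GHOST", ["COPY"])

    def test_constant_target_rejected(self):
        m = ExpressionMatrix(("A", "B"), ("s0", "s1", "s2"),
                             np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
        with pytest.raises(DomainError):
            spearman_profile(m, "A", ["B"])

    def test_planted_module_median_rho_near_analytic_value(self):
        """Factor model: target and module share variance
        loading^2 / (loading^2 + noise_sd^2); the Pearson rho between two
        such genes is that ratio, and Spearman tracks it closely."""
        spec = SimulationSpec(seed=21, n_genes=400, n_samples=200,
                              module_size=100, factor_loading=0.8, noise_sd=0.6)
        matrix, module, target = gen_expression(spec)
        rho_expected = 0.8**2 / (0.8**2 + 0.6**2)
        rhos = spearman_profile(matrix, target, module)
        assert np.median(rhos) == pytest.approx(rho_expected, abs=0.1)


class TestModuleContrast:
    def test_module_equal_background_is_null(self, small_matrix):
        res = module_contrast(
            small_matrix, "TARGET",
            module=["NOISE_A", "NOISE_B"],
            background=["NOISE_A", "NOISE_B"],
        )
        assert res.wilcoxon_p > 0.6

    def test_single_gene_each_side_exact_p_one(self, small_matrix):
        res = module_contrast(
            small_matrix, "TARGET", module=["NOISE_A"], background=["NOISE_B"]
        )
        assert res.wilcoxon_p == 1.0

    def test_planted_module_strongly_significant(self):
        spec = SimulationSpec(seed=22, n_genes=2000, n_samples=100,
                              module_size=300, factor_loading=0.8, noise_sd=0.6)
        matrix, module, target = gen_expression(spec)
        res = module_contrast(matrix, target, module)
        assert res.wilcoxon_p < 1e-10
        assert res.median_module > res.median_background

    def test_symmetric_in_module_background_swap(self, small_matrix):
        a = module_contrast(small_matrix, "TARGET", ["NOISE_A", "MONO_DEC"],
                            ["NOISE_B", "COPY"])
        b = module_contrast(small_matrix, "TARGET", ["NOISE_B", "COPY"],
                            ["NOISE_A", "MONO_DEC"])
        assert a.wilcoxon_p == pytest.approx(b.wilcoxon_p)

    def test_empty_module_rejected(self, small_matrix):
        with pytest.raises(DomainError):
            module_contrast(small_matrix, "TARGET", ["GHOST"], ["NOISE_A"])


class TestTopCoexpressed:
    def test_duplicate_of_target_ranks_first(self, small_matrix):
        assert top_coexpressed(small_matrix, "TARGET", 1) == ["COPY"]

    def test_k_of_all_returns_every_other_gene(self, small_matrix):
        got = top_coexpressed(small_matrix, "TARGET", 5)
        assert sorted(got) == sorted(g for g in small_matrix.gene_ids if g != "TARGET")

    def test_planted_module_recall(self):
        spec = SimulationSpec(seed=23, n_genes=1500, n_samples=100,
                              module_size=200, factor_loading=0.8, noise_sd=0.6)
        matrix, module, target = gen_expression(spec)
        top = top_coexpressed(matrix, target, len(module))
        recall = len(set(top) & set(module)) / len(module)
        assert recall > 0.9

    def test_bad_k_rejected(self, small_matrix):
        with pytest.raises(DomainError):
            top_coexpressed(small_matrix, "TARGET", 0)


class TestDensityExport:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(3)
        d = density_export(rng.uniform(-1, 1, 500), bandwidth=0.1)
        assert np.trapezoid(d["density"], d["grid"]) == pytest.approx(1.0, abs=1e-3)

    def test_unimodal_at_repeated_value(self):
        d = density_export([0.5, 0.5001, 0.4999, 0.5], bandwidth=0.1)
        peak = d.loc[d["density"].idxmax(), "grid"]
        assert peak == pytest.approx(0.5, abs=0.01)

    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(4)
        d = density_export(rng.standard_normal(10_000), bandwidth=0.1)
        at_zero = d.loc[(d["grid"]).abs().idxmin(), "density"]
        assert at_zero == pytest.approx(1 / math.sqrt(2 * math.pi), rel=0.05)

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(DomainError):
            density_export([0.1, 0.2], bandwidth=0.0)
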