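import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gbmpanel import concordance as conc
from gbmpanel import synth
from gbmpanel.types import ExprMatrix, ModelType, SampleAnnotation, ScaleTag

from conftest import expr_from_array


def _panel(values, lines_models):
    """Build an ExprMatrix whose samples carry (line, model) annotations."""
    samples = [
        SampleAnnotation(sample_id=f"{line}_{model}", pdx_id=line, model=model)
        for line, model in lines_models
    ]
    genes = [f"g{i}" for i in range(np.asarray(values).shape[0])]
    return ExprMatrix(np.asarray(values, float), genes=genes, samples=samples)


class TestZScore:
    def test_two_sample_values_use_sample_sd(self):
        expr = expr_from_array([[-1.0, 1.0]], genes=["g"])
        z = conc.zscore_by_gene(expr)
        assert np.allclose(z.values.to_numpy(), [[-1 / np.sqrt(2), 1 / np.sqrt(2)]])
        assert z.scale_tag is ScaleTag.ZSCORE

    def test_constant_gene_flagged_and_zeroed(self):
        expr = expr_from_array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], genes=["c", "v"])
        with pytest.warns(UserWarning, match="constant"):
            z = conc.zscore_by_gene(expr)
        assert (z.values.loc["c"] == 0).all()

    def test_rows_centered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        z = conc.zscore_by_gene(expr_from_array(rng.normal(size=(20, 15))))
        assert np.abs(z.values.mean(axis=1)).max() < 1e-12
        assert np.allclose(z.values.std(axis=1, ddof=1), 1.0)


class TestDirectionality:
    def test_sign_of_product_rules(self):
        # one gene; one line with all three models
        lm = [("X1", "cells"), ("X1", "microtumor"), ("X1", "spheroid")]
        expr = _panel([[1.2, 0.5, -0.5]], lm)
        table = conc.pairwise_directionality(expr)
        signs = table.signs.loc["g0"]
        assert signs[("X1", "cells-mt")] == 1.0
        assert signs[("X1", "cells-sph")] == -1.0
        assert signs[("X1", "mt-sph")] == -1.0

    def test_zero_policy_discordant_vs_ignore(self):
        lm = [("X1", "cells"), ("X1", "microtumor")]
        expr = _panel([[0.0, 3.0]], lm)
        z = expr.with_values(expr.values, ScaleTag.ZSCORE)
        strict = conc.pairwise_directionality(z, conc.ConcordanceConfig(zero_policy="discordant"))
        assert strict.signs.loc["g0", ("X1", "cells-mt")] == -1.0
        lax = conc.pairwise_directionality(z, conc.ConcordanceConfig(zero_policy="ignore"))
        assert np.isnan(lax.signs.loc["g0", ("X1", "cells-mt")])

    def test_missing_model_yields_na_not_error(self):
        expr, truth = synth.make_multimodel_panel(
            synth.MultiModelSpec(n_lines=4, missing_spheroid_lines=2, seed=0)
        )
        table = conc.pairwise_directionality(conc.zscore_by_gene(expr))
        missing = truth.extra["missing_spheroid_lines"]
        for line in missing:
            assert table.signs[(line, "cells-sph")].isna().all()
            assert table.signs[(line, "cells-mt")].notna().all()


class TestOverlap:
    def test_fully_concordant_gene_is_core_and_discordant_is_none(self):
        lm = [(l, m) for l in ("X1", "X2") for m in ("cells", "microtumor", "spheroid")]
        core_row = [1.0, 1.2, 0.8, -1.0, -0.7, -1.1]  # same sign within each line
        # a sign product triple can never be all-negative (their product is a
        # square), so "none" needs each pair to agree in under 2/3 of lines:
        # X1 is concordant only on cells-sph, X2 only on cells-mt
        alt_row = [1.0, -1.2, 0.8, -1.0, -0.7, 1.1]
        expr = _panel([core_row, alt_row], lm)
        z = expr.with_values(expr.values, ScaleTag.ZSCORE)
        overlap = conc.classify_overlap(conc.pairwise_directionality(z))
        assert overlap["g0"] == "core"
        assert overlap["g1"] == "none"

    def test_classes_partition_panel(self):
        expr, _ = synth.make_multimodel_panel(synth.MultiModelSpec(seed=1))
        overlap = conc.classify_overlap(
            conc.pairwise_directionality(conc.zscore_by_gene(expr))
        )
        assert len(overlap) == len(expr.genes)
        assert overlap.notna().all()

    def test_planted_core_recovery_bounds(self):
        hits = fps = n_core = n_null = 0
        for seed in range(5):
            expr, truth = synth.make_multimodel_panel(synth.MultiModelSpec(seed=seed))
            overlap = conc.classify_overlap(
                conc.pairwise_directionality(conc.zscore_by_gene(expr))
            )
            called = set(overlap[overlap == "core"].index)
            core = set(truth.genes_with_role("core"))
            null = set(truth.genes_with_role("noise"))
            hits += len(core & called)
            fps += len(null & called)
            n_core += len(core)
            n_null += len(null)
        assert hits / n_core >= 0.9
        assert fps / n_null <= 0.05


class TestPerLineCorrelation:
    def test_identical_and_negated_profiles(self):
        lm = [("X1", "cells"), ("X1", "microtumor"), ("X1", "spheroid")]
        base = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.column_stack([base, base, -base])
        expr = _panel(values, lm)
        r = conc.per_line_model_correlation(expr)
        assert r.loc["X1", "cells-mt"] == pytest.approx(1.0)
        assert r.loc["X1", "cells-sph"] == pytest.approx(-1.0)

    def test_small_gene_subset_rejected(self):
        expr, _ = synth.make_multimodel_panel(
            synth.MultiModelSpec(n_lines=3, missing_spheroid_lines=0, seed=0)
        )
        with pytest.raises(ValueError, match="3 genes"):
            conc.per_line_model_correlation(expr, expr.genes[:2])

    def test_core_genes_correlate_better_than_full_panel(self):
        ok = tot = 0
        for seed in range(5):
            expr, truth = synth.make_multimodel_panel(synth.MultiModelSpec(seed=seed))
            core = sorted(truth.genes_with_role("core"))
            full_r = conc.per_line_model_correlation(expr)
            core_r = conc.per_line_model_correlation(expr, core)
            mask = full_r.notna()
            ok += (core_r[mask] >= full_r[mask]).sum().sum()
            tot += mask.sum().sum()
        assert ok / tot >= 0.95


def _kw_brute_force(groups):
    """Kruskal-Wallis H from the rank formula with tie correction."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        h += len(g) * (r.mean() ** 2)
        idx += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


class TestKruskalWallis:
    def _expr(self, groups):
        vals = np.concatenate(groups)[None, :]
        ids = [f"s{i}" for i in range(vals.shape[1])]
        expr = expr_from_array(vals, genes=["g"], samples=ids)
        mapping = {}
        idx = 0
        for k, g in enumerate(groups):
            mapping[f"grp{k}"] = ids[idx: idx + len(g)]
            idx += len(g)
        return expr, mapping

    def test_identical_groups_give_h_zero_p_one(self):
        expr, groups = self._expr([np.array([1.0, 2, 3])] * 3)
        table = conc.kruskal_by_gene(expr, groups)
        assert table.loc["g", "H"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["g", "p"] == pytest.approx(1.0)

    def test_textbook_three_group_value(self):
        expr, groups = self._expr(
            [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        )
        assert conc.kruskal_by_gene(expr, groups).loc["g", "H"] == pytest.approx(7.2)

    @given(
        st.lists(
            st.lists(st.integers(0, 5).map(float), min_size=2, max_size=4),
            min_size=2,
            max_size=3,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_rank_formula_oracle_on_small_inputs(self, raw_groups):
        groups = [np.array(g) for g in raw_groups]
        pooled = np.concatenate(groups)
        expr, mapping = self._expr(groups)
        table = conc.kruskal_by_gene(expr, mapping)
        if np.ptp(pooled) == 0:
            assert table.loc["g", "H"] == 0.0
        else:
            assert table.loc["g", "H"] == pytest.approx(_kw_brute_force(groups), abs=1e-9)

    def test_model_specific_genes_detected_with_controlled_fpr(self):
        det = n_spec = fp = n_null = 0
        for seed in range(5):
            expr, truth = synth.make_multimodel_panel(synth.MultiModelSpec(seed=seed))
            hits = set(conc.model_specific_genes(expr).index)
            spec_genes = set(truth.genes_with_role("model_specific"))
            null = set(truth.genes_with_role("noise"))
            det += len(spec_genes & hits)
            n_spec += len(spec_genes)
            fp += len(null & hits)
            n_null += len(null)
        assert det / n_spec >= 0.8
        assert fp / n_null <= 0.01 * 3  # small-sample slack over nominal alpha


class TestVarianceFilter:
    def test_top_k_equal_to_all_is_identity_up_to_order(self):
        rng = np.random.default_rng(0)
        expr = expr_from_array(rng.normal(size=(5, 10)))
        out = conc.variance_filter(expr, expr.genes, 5)
        assert sorted(out) == sorted(expr.genes)

    def test_single_dominant_gene_wins(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(0, 1, (4, 30))
        arr[2] *= 10
        expr = expr_from_array(arr)
        assert conc.variance_filter(expr, expr.genes, 1) == ["g2"]

    def test_k_larger_than_pool_rejected(self):
        expr = expr_from_array(np.zeros((2, 4)))
        with pytest.raises(ValueError, match="top_k"):
            conc.variance_filter(expr, expr.genes, 3)

    def test_line_identity_genes_outrank_noise(self):
        wins = 0
        for seed in range(5):
            expr, truth = synth.make_multimodel_panel(synth.MultiModelSpec(seed=seed))
            top = conc.variance_filter(expr, expr.genes, 17)
            core = set(truth.genes_with_role("core"))
            wins += len(core & set(top)) == 17
        assert wins >= 5 * 0.95 - 1  # allow one miss in five seeds


class TestClustering:
    def test_duplicated_sample_groups_split_first(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = -a  # anti-correlated group: far away under correlation distance
        values = np.column_stack([a, a + rng.normal(0, 0.01, 10), b, b + rng.normal(0, 0.01, 10)])
        expr = expr_from_array(values)
        out = conc.hier_cluster(expr)
        labels = conc.cut_clusters(out["sample_linkage"], 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_constant_rows_fall_back_to_euclidean_with_warning(self):
        values = np.vstack([np.ones(4), np.arange(4.0)])
        expr = expr_from_array(values)
        with pytest.warns(UserWarning, match="Euclidean"):
            conc.hier_cluster(expr)

    def test_planted_lines_recovered_with_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        ok = 0
        for seed in range(5):
            expr, truth = synth.make_multimodel_panel(
                synth.MultiModelSpec(n_lines=4, missing_spheroid_lines=0, seed=seed)
            )
            core = truth.genes_with_role("core")
            out = conc.hier_cluster(expr, core)
            labels = conc.cut_clusters(out["sample_linkage"], 4)
            ari = adjusted_rand_score([s.pdx_id for s in expr.samples], labels)
            ok += ari >= 0.9
        assert ok >= 4
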