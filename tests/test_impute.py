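"""Expression transfer onto surfaces, LOO prediction, gradient ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orfish.impute import (
    embed_gene_patterns,
    impute_surface,
    loo_predict_projection,
    make_ob_surface_grid,
    rank_axis_gradients,
)


def impute_oracle(expr, types, positions, surface, radius):
    """Direct O(n*m) neighbourhood scan."""
    e = expr.loc[pd.Series(types).astype(str)].to_numpy(float)
    out = np.full((len(surface), e.shape[1]), np.nan)
    for i, p in enumerate(surface):
        d = np.linalg.norm(positions - p, axis=1)
        idx = d <= radius
        if idx.any():
            out[i] = e[idx].mean(axis=0)
    return out


class TestImputeSurface:
    def test_uniform_expression_normalizes_to_one(self):
        expr = pd.DataFrame({"g": [4.0]}, index=["T"])
        pos = np.random.default_rng(0).uniform(0, 100, (50, 2))
        surf = impute_surface(expr, ["T"] * 50, pos, pos, radius_um=50.0)
        assert np.allclose(surf.values["g"], 1.0)

    def test_two_separated_types_step_pattern(self):
        expr = pd.DataFrame({"g": [0.0, 8.0]}, index=["lo", "hi"])
        pos = np.array([[0.0, 0.0], [500.0, 0.0]])
        surf = impute_surface(expr, ["lo", "hi"], pos, pos, radius_um=50.0)
        assert surf.values["g"].tolist() == [0.0, 1.0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.uniform(0, 10, (5, 7)),
            index=[f"T{i}" for i in range(5)],
            columns=[f"g{j}" for j in range(7)],
        )
        types = rng.choice(expr.index, 80)
        pos = rng.uniform(0, 300, (80, 3))
        grid = rng.uniform(0, 300, (40, 3))
        surf = impute_surface(expr, types, pos, grid, radius_um=60.0, norm_percentile=99)
        want = impute_oracle(expr, types, pos, grid, 60.0)
        defined = surf.n_contributors > 0
        # oracle comparison is on the pre-normalization means
        for j, g in enumerate(expr.columns):
            col = want[defined, j]
            p = np.percentile(col, 99)
            np.testing.assert_allclose(
                surf.values_raw[g].to_numpy()[defined], col / p, rtol=1e-12
            )
        assert (~defined == np.isnan(want[:, 0])).all()

    def test_normalization_percentile_is_exactly_one(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame({"g": rng.uniform(1, 5, 6)}, index=[f"T{i}" for i in range(6)])
        types = rng.choice(expr.index, 200)
        pos = rng.uniform(0, 400, (200, 2))
        surf = impute_surface(expr, types, pos, pos, radius_um=40.0)
        defined = surf.n_contributors > 0
        p99 = np.percentile(surf.values_raw["g"].to_numpy()[defined], 99)
        assert np.isclose(p99, 1.0, rtol=1e-12)
        assert surf.values["g"].max() <= 1.0

    def test_linearity_before_normalization(self):
        rng = np.random.default_rng(4)
        idx = [f"T{i}" for i in range(4)]
        a = pd.DataFrame({"g": rng.uniform(0, 5, 4)}, index=idx)
        b = pd.DataFrame({"g": rng.uniform(0, 5, 4)}, index=idx)
        types = rng.choice(idx, 60)
        pos = rng.uniform(0, 200, (60, 2))
        grid = rng.uniform(0, 200, (25, 2))

        def raw(e):
            s = impute_surface(e, types, pos, grid, radius_um=50.0, norm_percentile=100)
            # undo the max-normalization to recover the raw neighbourhood mean
            defined = s.n_contributors > 0
            return s.values_raw["g"].to_numpy(), defined

        va, da = raw(a)
        vb, _ = raw(b)
        vab, _ = raw(a + b)
        pa = np.percentile(impute_oracle(a, types, pos, grid, 50.0)[da, 0], 100)
        pb = np.percentile(impute_oracle(b, types, pos, grid, 50.0)[da, 0], 100)
        pab = np.percentile(impute_oracle(a + b, types, pos, grid, 50.0)[da, 0], 100)
        np.testing.assert_allclose(vab[da] * pab, va[da] * pa + vb[da] * pb, rtol=1e-9)

    def test_missing_gene_raises(self):
        expr = pd.DataFrame({"g": [1.0]}, index=["T"])
        with pytest.raises(KeyError, match="nope"):
            impute_surface(expr, ["T"], np.zeros((1, 2)), np.zeros((1, 2)),
                           radius_um=10.0, genes=["nope"])


def _gradient_map_and_expr(rng, n=40):
    """Receptors along a DV line; genes are monotone transforms of DV."""
    rows = []
    ys = np.linspace(100, 1900, n)
    for i, y in enumerate(ys):
        rows.append(
            {"receptor": f"r{i}", "hemisphere": "left", "side": "medial",
             "x": 500.0, "y": y, "z": 300.0}
        )
    pm = pd.DataFrame(rows)
    cols = {f"g_pow{k}": (ys / 2000.0) ** q
            for k, q in enumerate(np.linspace(0.3, 3.0, 15))}
    cols["g_dv"] = ys
    for k in range(5):
        cols[f"g_noise{k}"] = rng.uniform(0, 1, n)
    expr = pd.DataFrame(cols, index=[f"r{i}" for i in range(n)])
    return pm, expr


class TestLooPrediction:
    def test_noiseless_gradient_prediction_close(self):
        # leave-one-out leaves a gap at the receptor's own position, so the
        # achievable error scale is the averaging radius, not the grid step
        rng = np.random.default_rng(0)
        pm, expr = _gradient_map_and_expr(rng)
        pred = loo_predict_projection(expr, pm, radius_um=150.0, grid_spacing_um=50.0)
        merged = pred.merge(pm, on="receptor")
        assert pred["error_um"].median() < 150.0
        assert stats.spearmanr(merged["pred_y"], merged["y"]).statistic > 0.85

    def test_own_projections_do_not_leak(self):
        rng = np.random.default_rng(1)
        pm, expr = _gradient_map_and_expr(rng)
        pred1 = loo_predict_projection(expr, pm, radius_um=150.0)
        moved = pm.copy()
        moved.loc[moved["receptor"] == "r20", "y"] = 1.0  # move its glomerulus wildly
        pred2 = loo_predict_projection(expr, moved, radius_um=150.0)
        a = pred1[pred1["receptor"] == "r20"].iloc[0]
        b = pred2[pred2["receptor"] == "r20"].iloc[0]
        # grid changes only marginally; the predicted point must not chase
        # the receptor's own (moved) glomerulus
        assert abs(a["pred_y"] - b["pred_y"]) < 300.0
        assert abs(b["pred_y"] - 1.0) > 500.0

    def test_single_type_map_rejected(self):
        pm = pd.DataFrame(
            [{"receptor": "a", "hemisphere": "left", "side": "medial",
              "x": 0.0, "y": 0.0, "z": 0.0}]
        )
        expr = pd.DataFrame({"g": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            loo_predict_projection(expr, pm)


class TestAxisGradients:
    def test_planted_linear_gradient_tops_ranking(self):
        rng = np.random.default_rng(2)
        pm, expr = _gradient_map_and_expr(rng)
        pos = pm[["x", "y", "z"]].to_numpy()
        grid = make_ob_surface_grid(pos, spacing_um=100.0)
        surf = impute_surface(expr, pm["receptor"], pos, grid, radius_um=300.0)
        ranks = rank_axis_gradients(surf, grid[:, 1])
        assert ranks.iloc[0]["gene"] == "g_dv"
        assert abs(ranks.iloc[0]["r"]) > 0.99
        assert ranks.iloc[0]["r"] > 0  # increases with the axis coordinate

    def test_exchangeable_gene_below_permutation_band(self):
        rng = np.random.default_rng(3)
        n = 40
        pm = pd.DataFrame(
            [{"receptor": f"r{i}", "hemisphere": "left", "side": "medial",
              "x": 0.0, "y": y, "z": 0.0}
             for i, y in enumerate(rng.uniform(0, 2000, n))]
        )
        hits = 0
        n_sim = 20
        for k in range(n_sim):
            expr = pd.DataFrame(
                {"g": rng.uniform(0, 1, n)}, index=[f"r{i}" for i in range(n)]
            )
            pos = pm[["x", "y", "z"]].to_numpy()
            grid = make_ob_surface_grid(pos, spacing_um=100.0)
            surf = impute_surface(expr, pm["receptor"], pos, grid, radius_um=300.0)
            ranks = rank_axis_gradients(surf, grid[:, 1])
            obs = abs(ranks.iloc[0]["r"])
            vals = surf.values["g"].to_numpy()[surf.n_contributors > 0]
            coord = grid[surf.n_contributors > 0, 1]
            null = [
                abs(stats.pearsonr(rng.permutation(vals), coord)[0]) for _ in range(39)
            ]
            if obs <= np.quantile(null, 0.95):
                hits += 1
        # spatial smoothing correlates neighbouring points, so the permutation
        # band is conservative; still, most runs stay inside it
        assert hits >= int(0.5 * n_sim)

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(5)
        pm, expr = _gradient_map_and_expr(rng)
        expr["g_const"] = 2.0
        pos = pm[["x", "y", "z"]].to_numpy()
        grid = make_ob_surface_grid(pos, spacing_um=150.0)
        surf = impute_surface(expr, pm["receptor"], pos, grid, radius_um=300.0)
        ranks = rank_axis_gradients(surf, grid[:, 1])
        assert "g_const" not in set(ranks["gene"])


class TestEmbedGenePatterns:
    @staticmethod
    def _two_family_surface(rng, n_genes=30, n_points=80):
        t = np.linspace(0, 1, n_points)
        genes = {}
        for g in range(n_genes):
            base = t if g < n_genes // 2 else 1 - t
            genes[f"g{g}"] = base + rng.normal(0, 0.05, n_points)
        from orfish.impute import ImputedSurface

        vals = pd.DataFrame(genes).clip(0, 1)
        return ImputedSurface(
            points=np.column_stack([t * 100, np.zeros(n_points)]),
            values=vals, values_raw=vals,
            n_contributors=np.ones(n_points, int),
            radius_um=50.0, norm_percentile=99.0,
        )

    def test_anticorrelated_families_separate(self):
        rng = np.random.default_rng(0)
        surf = self._two_family_surface(rng)
        out = embed_gene_patterns(surf, seed=0)
        fam = out["gene"].str.slice(1).astype(int) < 15
        # majority cluster per family must be pure
        purity = []
        for f in (True, False):
            labs = out.loc[fam == f, "cluster"]
            purity.append(labs.value_counts().iloc[0] / len(labs))
        assert min(purity) >= 0.95
        top_a = out.loc[fam, "cluster"].mode()[0]
        top_b = out.loc[~fam, "cluster"].mode()[0]
        assert top_a != top_b

    def test_duplicate_gene_embeds_identically(self):
        rng = np.random.default_rng(1)
        surf = self._two_family_surface(rng)
        surf.values["g0_twin"] = surf.values["g0"]
        surf.values_raw["g0_twin"] = surf.values_raw["g0"]
        out = embed_gene_patterns(surf, seed=0).set_index("gene")
        d = np.hypot(
            out.loc["g0", "umap_1"] - out.loc["g0_twin", "umap_1"],
            out.loc["g0", "umap_2"] - out.loc["g0_twin", "umap_2"],
        )
        span = np.hypot(np.ptp(out["umap_1"]), np.ptp(out["umap_2"]))
        assert d < 0.15 * span  # twins sit together up to layout jitter
        assert out.loc["g0", "cluster"] == out.loc["g0_twin", "cluster"]

    def test_cluster_labels_stable_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        surf = self._two_family_surface(rng)
        ref = embed_gene_patterns(surf, seed=0)["cluster"]
        for seed in (1, 2, 3, 4):
            cur = embed_gene_patterns(surf, seed=seed)["cluster"]
            assert adjusted_rand_score(ref, cur) > 0.9

    def test_too_few_genes_rejected(self):
        rng = np.random.default_rng(3)
        surf = self._two_family_surface(rng, n_genes=10)
        with pytest.raises(ValueError):
            embed_gene_patterns(surf, seed=0)
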