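"""Overlap matrix, spatial indices, genomic and phylogenetic statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orfish.spatial_atlas import (
    basal_apical_index,
    central_peripheral_index,
    genomic_cluster_analysis,
    ob_axis_coordinates,
    overlap_matrix,
    patristic_distances,
    phylo_association,
    summarize_repertoire,
)


def overlap_oracle(cells, cutoff=200.0):
    """Exhaustive O(n^2) pair scan, averaged over sections with both types."""
    receptors = sorted(cells["receptor"].unique())
    acc = {p: [] for a in receptors for p in [(a, b) for b in receptors]}
    keys = ["animal", "section"] if "animal" in cells else ["section"]
    for _, sec in cells.groupby(keys):
        pts = {r: g[["x", "y"]].to_numpy() for r, g in sec.groupby("receptor")}
        for a in pts:
            for b in pts:
                if a > b:
                    continue
                pa, pb = pts[a], pts[b]
                if a == b:
                    v = 1.0
                else:
                    hit_a = sum(
                        1 for p in pa if any(np.hypot(*(p - q)) <= cutoff for q in pb)
                    )
                    hit_b = sum(
                        1 for q in pb if any(np.hypot(*(q - p)) <= cutoff for p in pa)
                    )
                    v = (hit_a + hit_b) / (len(pa) + len(pb))
                acc[(a, b)].append(v)
                acc[(b, a)].append(v)
    out = pd.DataFrame(np.nan, index=receptors, columns=receptors)
    for (a, b), vals in acc.items():
        if vals:
            out.loc[a, b] = np.mean(vals)
    np.fill_diagonal(out.values, 1.0)
    return out


class TestSummarize:
    def test_single_section_counts(self):
        cells = pd.DataFrame(
            {"section": [0] * 4, "receptor": ["A", "A", "A", "B"],
             "x": range(4), "y": range(4)}
        )
        out = summarize_repertoire(cells)
        assert out.loc["A", "mean_cells_per_section"] == 3
        assert out.loc["B", "mean_cells_per_section"] == 1

    def test_equal_brightness_normalizes_to_one(self):
        cells = pd.DataFrame(
            {"section": [0, 0, 1, 1], "receptor": ["A", "B", "A", "B"],
             "x": range(4), "y": range(4), "brightness": [5.0] * 4}
        )
        out = summarize_repertoire(cells)
        assert np.allclose(out["mean_norm_brightness"], 1.0)

    def test_absent_sections_count_as_zero(self):
        cells = pd.DataFrame(
            {"section": [0, 0, 1], "receptor": ["A", "A", "B"], "x": range(3), "y": range(3)}
        )
        out = summarize_repertoire(cells)
        assert out.loc["A", "mean_cells_per_section"] == 1.0  # (2 + 0) / 2


class TestOverlapMatrix:
    def test_within_cutoff_is_one(self):
        cells = pd.DataFrame(
            {"section": [0, 0], "receptor": ["A", "B"], "x": [0.0, 100.0], "y": [0.0, 0.0]}
        )
        om = overlap_matrix(cells)
        assert om.values.loc["A", "B"] == 1.0

    def test_beyond_cutoff_is_zero(self):
        cells = pd.DataFrame(
            {"section": [0, 0], "receptor": ["A", "B"], "x": [0.0, 300.0], "y": [0.0, 0.0]}
        )
        om = overlap_matrix(cells)
        assert om.values.loc["A", "B"] == 0.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        for sec in range(2):
            for rec in "ABCD":
                n = rng.integers(10, 50)
                for _ in range(n):
                    rows.append(
                        {"section": sec, "receptor": rec,
                         "x": rng.uniform(0, 600), "y": rng.uniform(0, 600)}
                    )
        cells = pd.DataFrame(rows)
        om = overlap_matrix(cells)
        want = overlap_oracle(cells)
        pd.testing.assert_frame_equal(om.values, want, check_exact=False, atol=1e-12)
        assert np.allclose(om.values, om.values.T)

    def test_absent_type_marked_undefined(self):
        cells = pd.DataFrame(
            {"section": [0], "receptor": ["A"], "x": [0.0], "y": [0.0]}
        )
        om = overlap_matrix(cells)
        assert om.undefined == []  # A overlaps itself; no other types exist


class TestCentralPeripheralIndex:
    def test_ring_order_recovered(self, atlas):
        truth = atlas["truth"]
        cp = atlas["cp"]
        main = truth[~truth["unusual"]]
        rho, _ = stats.spearmanr(cp.loc[main.index, "cp_index"], main["ring_radius_um"])
        assert abs(rho) > 0.95

    def test_unusual_zone_flagged_and_excluded(self, atlas):
        truth = atlas["truth"]
        cp = atlas["cp"]
        unusual = truth[truth["unusual"]].index
        assert cp.loc[unusual, "unusual_zone"].all()
        assert cp.loc[unusual, "cp_index"].isna().all()
        main = truth[~truth["unusual"]].index
        assert not cp.loc[main, "unusual_zone"].any()

    def test_endpoints_are_zero_and_one(self, atlas):
        vals = atlas["cp"]["cp_index"].dropna()
        assert vals.min() == 0.0
        assert vals.max() == 1.0

    def test_stable_across_seeds(self, atlas):
        ref = atlas["cp"]["cp_index"].dropna()
        for seed in (1, 2, 3, 4):
            idx, _ = central_peripheral_index(atlas["overlap"], seed=seed)
            cur = idx["cp_index"].dropna()
            rho, _ = stats.spearmanr(ref, cur[ref.index])
            assert abs(rho) > 0.98

    def test_canonical_orientation_with_reference(self, atlas):
        truth = atlas["truth"]
        radius = truth["ring_radius_um"]
        idx, _ = central_peripheral_index(atlas["overlap"], seed=0, central_reference=radius)
        main = truth[~truth["unusual"]]
        r, _ = stats.pearsonr(idx.loc[main.index, "cp_index"], main["ring_radius_um"])
        assert r > 0  # 0 = central (smallest radius)

    def test_degenerate_matrix_rejected(self):
        from orfish.spatial_atlas import OverlapMatrix

        n = 12
        names = [f"r{i}" for i in range(n)]
        vals = pd.DataFrame(0.5, index=names, columns=names)
        om = OverlapMatrix(values=vals, support=vals * 0, undefined=[])
        with pytest.raises(ValueError):
            central_peripheral_index(om, seed=0)


class TestBasalApicalIndex:
    def test_midpoint_surface_and_boundaries(self):
        cells = pd.DataFrame(
            {"receptor": ["A"] * 10 + ["B"] * 10,
             "depth_um": [30.0] * 10 + [0.0] * 10}
        )
        out = basal_apical_index(cells, thickness_um=60.0)
        assert out.loc["A", "ba_index"] == 0.5
        assert out.loc["B", "ba_index"] == 0.0

    def test_outside_ribbon_excluded(self):
        cells = pd.DataFrame(
            {"receptor": ["A"] * 11, "depth_um": [30.0] * 10 + [99.0]}
        )
        out = basal_apical_index(cells, thickness_um=60.0)
        assert out.attrs["n_excluded"] == 1
        assert out.loc["A", "n_cells"] == 10

    def test_planted_offsets_recovered(self, atlas):
        truth, ba = atlas["truth"], atlas["ba"]
        r, _ = stats.pearsonr(ba.loc[truth.index, "ba_index"], truth["depth_offset"])
        assert r > 0.95


class TestObAxisCoordinates:
    def test_bin_edge_belongs_to_lower_bin(self):
        pm = pd.DataFrame(
            [{"receptor": "A", "side": "medial", "x": 0.0, "y": 300.0, "z": 40.0}]
        )
        coords, _ = ob_axis_coordinates(pm, dv_bin_um=150.0)
        assert coords.iloc[0]["dv_um"] == 225.0
        assert coords.iloc[0]["ap_um"] == 40.0

    def test_constant_positions_give_constant_track(self):
        pm = pd.DataFrame(
            [{"receptor": f"r{i}", "side": "medial", "x": 10.0, "y": 100.0, "z": 5.0}
             for i in range(20)]
        )
        cp = pd.Series(np.linspace(0, 1, 20), index=[f"r{i}" for i in range(20)])
        _, tracks = ob_axis_coordinates(pm, cp_index=cp, window=5)
        assert tracks["y_um"].nunique() == 1
        assert tracks["z_um"].nunique() == 1

    def test_planted_monotone_mapping_recovered(self, atlas):
        cp = atlas["cp"]["cp_index"].dropna()
        pm = atlas["maps"]
        coords, _ = ob_axis_coordinates(pm[pm["animal"] == 0], cp_index=cp)
        med = coords[coords["side"] == "medial"].set_index("receptor")
        shared = med.index.intersection(cp.index)
        r, _ = stats.pearsonr(cp[shared], med.loc[shared, "dv_um"])
        assert abs(r) > 0.95


class TestGenomicAnalysis:
    def test_single_linkage_clusters(self):
        meta = pd.DataFrame(
            {"receptor": ["a", "b", "c"], "chrom": ["chr1"] * 3,
             "start": [0, 50_000, 500_000], "end": [1_000, 51_000, 501_000]}
        )
        out = genomic_cluster_analysis(meta)
        cl = out["clusters"].set_index("receptor")["cluster"]
        assert cl["a"] == cl["b"]
        assert cl["c"] != cl["a"]

    def test_enhancer_boost_detected(self):
        rng = np.random.default_rng(0)
        n = 100
        meta = pd.DataFrame(
            {"receptor": [f"r{i}" for i in range(n)], "chrom": "chr1",
             "start": np.arange(n) * 300_000, "end": np.arange(n) * 300_000 + 1000}
        )
        enh = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": np.arange(20) * 300_000 + 30_000})
        abundance = pd.Series(rng.lognormal(2, 0.3, n), index=meta["receptor"])
        abundance.iloc[:20] *= 2.0  # receptors near enhancers are more abundant
        out = genomic_cluster_analysis(meta, abundance=abundance, enhancers=enh)
        assert out["enhancer_test"]["p_value"] < 0.01

    def test_shuffled_enhancers_calibrated(self):
        rng = np.random.default_rng(1)
        n = 100
        meta = pd.DataFrame(
            {"receptor": [f"r{i}" for i in range(n)], "chrom": "chr1",
             "start": np.arange(n) * 300_000, "end": np.arange(n) * 300_000 + 1000}
        )
        abundance = pd.Series(rng.lognormal(2, 0.3, n), index=meta["receptor"])
        ps = []
        for k in range(40):
            pos = rng.choice(n, 20, replace=False) * 300_000 + 30_000
            enh = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": pos})
            out = genomic_cluster_analysis(meta, abundance=abundance, enhancers=enh)
            ps.append(out["enhancer_test"]["p_value"])
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2  # ~nominal false-positive rate

    def test_no_enhancers_skips_test(self):
        meta = pd.DataFrame(
            {"receptor": ["a"], "chrom": ["chr1"], "start": [0], "end": [100]}
        )
        out = genomic_cluster_analysis(meta, abundance=pd.Series([1.0], index=["a"]))
        assert "skipped" in out["enhancer_test"]


def _two_clade_newick(n_per=6, inner=0.1, split=5.0):
    a = ",".join(f"A{i}:{inner}" for i in range(n_per))
    b = ",".join(f"B{i}:{inner}" for i in range(n_per))
    return f"(({a}):{split},({b}):{split});"


class TestPhyloAssociation:
    def test_star_tree_equal_distances(self):
        tips = [f"t{i}" for i in range(8)]
        nwk = "(" + ",".join(f"{t}:1.0" for t in tips) + ");"
        pat = patristic_distances(nwk, tips)
        off = pat.to_numpy()[np.triu_indices(8, k=1)]
        assert np.allclose(off, 2.0)

    def test_clade_set_more_coherent_than_random(self):
        nwk = _two_clade_newick()
        out = phylo_association(nwk, receptor_set=[f"A{i}" for i in range(6)], seed=0)
        assert out["set_test"]["p_value"] < 0.01

    def test_random_set_not_flagged(self):
        nwk = _two_clade_newick()
        rng = np.random.default_rng(3)
        tips = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        ps = [
            phylo_association(
                nwk, receptor_set=list(rng.choice(tips, 6, replace=False)), seed=k
            )["set_test"]["p_value"]
            for k in range(10)
        ]
        assert min(ps) > 0.001 or np.mean(np.asarray(ps) < 0.05) <= 0.3

    def test_patristic_matches_independent_parser(self):
        nwk = "((a:1.5,b:2.5):1.0,(c:0.5,(d:0.25,e:0.75):0.5):2.0);"
        pat = patristic_distances(nwk, ["a", "b", "c", "d", "e"])
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for x in "abcde":
            for y in "abcde":
                if x >= y:
                    continue
                assert np.isclose(pat.loc[x, y], pdm.patristic_distance(taxa[x], taxa[y]))

    def test_missing_tip_dropped_with_count(self):
        nwk = _two_clade_newick()
        out = phylo_association(nwk, receptor_set=["A0", "A1", "not_on_tree"], seed=0)
        assert out["n_dropped_set"] == 1
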