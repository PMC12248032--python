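"""Repertoire summaries and spatial-organization statistics.

The spatial organization of the OR repertoire in the epithelium is
summarized by a pairwise overlap matrix (fraction of cells of one type
with a cell of the other type within 200 um, symmetrized and averaged
over sections), from which a central-peripheral (cp) index in [0, 1] is
derived: receptors are embedded in 2D using 1 - overlap as dissimilarity,
a 1D principal curve is traced through the embedding by k-nearest-
neighbour geodesic ordering with local averaging, and each receptor's
index is its normalized arc-length position along the curve.  Receptors
in a detached component of the overlap graph (the "unusual zone") are
flagged and excluded from the curve.  A basal-apical (ba) index is the
per-receptor mean normalized soma depth between the basal and apical
surfaces.  Genomic clustering (single linkage at 100 kb), an enhancer
proximity rank-sum test (50 kb window) and phylogenetic association
statistics relate the spatial indices to genome position and sequence
similarity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree

__all__ = [
    "OverlapMatrix",
    "summarize_repertoire",
    "overlap_matrix",
    "central_peripheral_index",
    "basal_apical_index",
    "ob_axis_coordinates",
    "genomic_cluster_analysis",
    "phylo_association",
    "patristic_distances",
]


@dataclass
class OverlapMatrix:
    values: pd.DataFrame       # receptor x receptor, [0, 1], diagonal 1
    support: pd.DataFrame      # per-pair supporting cell counts
    undefined: list[str]       # receptors absent everywhere


def summarize_repertoire(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-receptor mean cells/section and mean normalized brightness.

    Counts are averaged over sections within each animal, then over
    animals.  Brightness (if present) is first divided by the mean cell
    brightness of its section, then averaged the same way.
    """
    df = cells.copy()
    if "animal" not in df:
        df["animal"] = 0
    if "brightness" in df:
        sec_mean = df.groupby(["animal", "section"])["brightness"].transform("mean")
        df["norm_brightness"] = df["brightness"] / sec_mean

    per_sec = (
        df.groupby(["animal", "section", "receptor"]).size().rename("n").reset_index()
    )
    # zero-fill sections where a receptor is absent so means are per-section
    sections = df[["animal", "section"]].drop_duplicates()
    receptors = df["receptor"].unique()
    full = sections.merge(pd.DataFrame({"receptor": receptors}), how="cross")
    per_sec = full.merge(per_sec, on=["animal", "section", "receptor"], how="left").fillna({"n": 0})
    per_animal = per_sec.groupby(["animal", "receptor"])["n"].mean().reset_index()
    counts = per_animal.groupby("receptor")["n"].mean().rename("mean_cells_per_section")

    out = counts.to_frame()
    if "brightness" in df:
        ba = df.groupby(["animal", "receptor"])["norm_brightness"].mean().reset_index()
        out["mean_norm_brightness"] = ba.groupby("receptor")["norm_brightness"].mean()
    return out


def overlap_matrix(
    cells: pd.DataFrame,
    cutoff_um: float = 200.0,
    require_both: bool = True,
) -> OverlapMatrix:
    """Pairwise spatial overlap of receptor types, averaged over sections.

    Per section, overlap(A, B) = (#A cells with a B cell within cutoff +
    #B cells with an A cell within cutoff) / (|A| + |B|); sections are
    averaged with equal weight, by default only over sections where both
    types occur.  Diagonal is 1 by convention.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    receptors = sorted(cells["receptor"].unique())
    idx = {r: i for i, r in enumerate(receptors)}
    n = len(receptors)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    support = np.zeros((n, n))
    group_keys = ["animal", "section"] if "animal" in cells else ["section"]
    for _, sec in cells.groupby(group_keys):
        pts = {r: g[["x", "y"]].to_numpy() for r, g in sec.groupby("receptor")}
        trees = {r: cKDTree(p) for r, p in pts.items()}
        present = sorted(pts)
        for ai in range(len(present)):
            for bi in range(ai, len(present)):
                a, b = present[ai], present[bi]
                pa, pb = pts[a], pts[b]
                if a == b:
                    na = nb = len(pa)
                    hit_a = hit_b = len(pa)
                else:
                    da, _ = trees[b].query(pa, k=1, distance_upper_bound=cutoff_um)
                    db, _ = trees[a].query(pb, k=1, distance_upper_bound=cutoff_um)
                    hit_a = int(np.isfinite(da).sum())
                    hit_b = int(np.isfinite(db).sum())
                    na, nb = len(pa), len(pb)
                v = (hit_a + hit_b) / (na + nb)
                i, j = idx[a], idx[b]
                acc[i, j] += v
                acc[j, i] += v if i != j else 0
                cnt[i, j] += 1
                cnt[j, i] += 1 if i != j else 0
                support[i, j] += na + nb
                support[j, i] += na + nb if i != j else 0
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    np.fill_diagonal(vals, 1.0)
    undefined = [r for i, r in enumerate(receptors) if cnt[i].sum() == 0]
    if not require_both:
        # treat never-co-occurring pairs as zero overlap rather than NaN
        vals = np.nan_to_num(vals, nan=0.0)
    values = pd.DataFrame(vals, index=receptors, columns=receptors)
    return OverlapMatrix(
        values=values,
        support=pd.DataFrame(support, index=receptors, columns=receptors),
        undefined=undefined,
    )


def _principal_curve_index(emb: np.ndarray, k: int, window: int) -> np.ndarray:
    """Arc-length position along a curve traced through the embedding."""
    n = len(emb)
    k = min(k, n - 1)
    while True:
        tree = cKDTree(emb)
        d, j = tree.query(emb, k=k + 1)
        rows = np.repeat(np.arange(n), k)
        cols = j[:, 1:].ravel()
        w = d[:, 1:].ravel()
        g = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
        g = g.maximum(g.T)
        ncomp, _ = connected_components(g, directed=False)
        if ncomp == 1 or k >= n - 1:
            break
        k = min(k * 2, n - 1)
    geo = shortest_path(g, directed=False)
    # double sweep: the two mutually farthest points are the curve endpoints
    p0 = int(np.argmax(geo[0]))
    p0 = int(np.argmax(geo[p0]))
    p1 = int(np.argmax(geo[p0]))
    # signed geodesic position between the endpoints is monotone along the
    # filament and less noise-sensitive than distance from one end alone
    s = geo[p0] - geo[p1]
    order = np.argsort(s, kind="stable")
    # principal curve by local averaging along the geodesic ordering
    w = max(3, min(window, n // 4) | 1)
    pad = w // 2
    padded = np.vstack([emb[order][:1]] * pad + [emb[order]] + [emb[order][-1:]] * pad)
    kernel = np.ones(w) / w
    curve = np.column_stack(
        [np.convolve(padded[:, dim], kernel, mode="valid") for dim in range(emb.shape[1])]
    )
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    # project every point onto its nearest curve vertex
    ct = cKDTree(curve)
    _, nearest = ct.query(emb)
    pos = arc[nearest]
    rng_ = pos.max() - pos.min()
    if rng_ <= 0:
        raise ValueError("degenerate embedding: all positions identical")
    return (pos - pos.min()) / rng_


def central_peripheral_index(
    matrix: OverlapMatrix,
    seed: int = 0,
    n_neighbors: int = 10,
    curve_window: int = 9,
    central_reference: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """cp index in [0, 1] from the overlap matrix via manifold embedding.

    Receptors disconnected from the main component of the positive-overlap
    graph are flagged ``unusual_zone`` and excluded from the curve.  With
    ``central_reference`` (e.g. per-receptor mean radial coordinate) the
    orientation is canonicalized so index 0 is the central end; otherwise
    the orientation is deterministic but arbitrary.

    Returns ``(index_table, embedding_table)``.
    """
    import umap

    vals = matrix.values
    receptors = list(vals.index)
    if len(receptors) < 10:
        raise ValueError("cp index needs >= 10 receptors with defined overlap")
    v = np.nan_to_num(vals.to_numpy(), nan=0.0)
    if np.allclose(v, v.flat[0]):
        raise ValueError("degenerate overlap matrix: all entries equal")
    adj = sparse.csr_matrix((v > 0).astype(float) - np.eye(len(v)))
    ncomp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    main = int(np.argmax(sizes))
    in_main = labels == main

    sub = v[np.ix_(in_main, in_main)]
    diss = np.clip(1.0 - sub, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    reducer = umap.UMAP(
        n_components=2,
        metric="precomputed",
        n_neighbors=min(n_neighbors, in_main.sum() - 1),
        min_dist=0.1,
        random_state=seed,
    )
    emb = reducer.fit_transform(diss)
    pos = _principal_curve_index(emb, k=n_neighbors, window=curve_window)

    index = pd.DataFrame(index=receptors)
    index["cp_index"] = np.nan
    index.loc[np.asarray(receptors)[in_main], "cp_index"] = pos
    index["unusual_zone"] = ~in_main
    if central_reference is not None:
        ref = central_reference.reindex(index.index[in_main])
        ok = ref.notna()
        if ok.sum() >= 3:
            r, _ = stats.pearsonr(pos[ok.to_numpy()], ref[ok].to_numpy())
            if r < 0:
                index.loc[in_main, "cp_index"] = 1.0 - index.loc[in_main, "cp_index"]
    emb_table = pd.DataFrame(
        emb, index=np.asarray(receptors)[in_main], columns=["umap_1", "umap_2"]
    )
    return index, emb_table


def basal_apical_index(
    cells: pd.DataFrame,
    thickness_um: float,
    depth_column: str = "depth_um",
    min_support: int = 10,
) -> pd.DataFrame:
    """Per-receptor mean normalized depth between basal (0) and apical (1).

    With the synthetic ribbon's parallel analytic surfaces, a cell's depth
    fraction is d_basal / (d_basal + d_apical) = depth / thickness.  Cells
    outside the ribbon are excluded and counted.
    """
    d = cells[depth_column]
    inside = (d >= 0) & (d <= thickness_um)
    frac = d[inside] / thickness_um
    sub = cells.loc[inside].assign(depth_frac=frac)
    g = sub.groupby("receptor")["depth_frac"]
    out = pd.DataFrame({"ba_index": g.mean(), "n_cells": g.size()})
    out.loc[out["n_cells"] < min_support, "ba_index"] = np.nan
    out.attrs["n_excluded"] = int((~inside).sum())
    return out


def ob_axis_coordinates(
    projection_map: pd.DataFrame,
    cp_index: pd.Series | None = None,
    dv_bin_um: float = 150.0,
    window: int = 70,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-receptor DV/AP coordinates and sliding-window position tracks.

    DV = center of the half-open ``dv_bin_um`` bin holding the glomerulus
    y coordinate (averaged over a receptor's glomeruli per side); AP = the
    mean z.  With a cp index, receptors are ordered by it and the track of
    mean 3D positions over sliding windows of ``window`` receptors is
    returned per side.
    """
    df = projection_map.copy()
    # right-closed bins ((k-1)b, kb]: a glomerulus sitting exactly on a bin
    # edge belongs to the lower bin (y = 300 with 150 um bins -> center 225)
    idx = np.maximum(np.ceil(df["y"] / dv_bin_um) - 1, 0)
    df["dv_bin_center"] = (idx + 0.5) * dv_bin_um
    coords = (
        df.groupby(["receptor", "side"])
        .agg(dv_um=("dv_bin_center", "mean"), ap_um=("z", "mean"),
             x_um=("x", "mean"), y_um=("y", "mean"))
        .reset_index()
    )
    tracks = None
    if cp_index is not None:
        rows = []
        for side, grp in coords.groupby("side"):
            grp = grp.assign(cp=cp_index.reindex(grp["receptor"]).to_numpy())
            grp = grp.dropna(subset=["cp"]).sort_values("cp")
            w = min(window, len(grp))
            if w < 1:
                continue
            arr = grp[["x_um", "y_um", "ap_um"]].to_numpy()
            for i in range(len(grp) - w + 1):
                m = arr[i:i + w].mean(axis=0)
                rows.append({"side": side, "window_start": i,
                             "x_um": m[0], "y_um": m[1], "z_um": m[2]})
        tracks = pd.DataFrame(rows)
    return coords, tracks


def genomic_cluster_analysis(
    metadata: pd.DataFrame,
    overlap: OverlapMatrix | None = None,
    abundance: pd.Series | None = None,
    enhancers: pd.DataFrame | None = None,
    cluster_gap_bp: int = 100_000,
    enhancer_window_bp: int = 50_000,
    distance_bins_bp: tuple = (0, 100_000, 1_000_000, 10_000_000, np.inf),
) -> dict:
    """Genomic clustering, overlap-vs-distance curve, enhancer proximity test.

    ``metadata`` needs columns receptor, chrom, start, end.  Clusters are
    single-linkage at midpoint gap <= ``cluster_gap_bp`` per chromosome.
    The proximity test is a two-sided rank-sum comparing ``abundance`` of
    receptors within ``enhancer_window_bp`` of any enhancer vs the rest.
    """
    meta = metadata.copy()
    meta["mid"] = (meta["start"] + meta["end"]) / 2.0
    meta = meta.sort_values(["chrom", "mid"]).reset_index(drop=True)
    cluster_ids = np.zeros(len(meta), dtype=int)
    cid = 0
    for _, grp in meta.groupby("chrom", sort=False):
        prev_mid = None
        for i in grp.index:
            if prev_mid is not None and meta.loc[i, "mid"] - prev_mid <= cluster_gap_bp:
                cluster_ids[i] = cid
            else:
                cid += 1
                cluster_ids[i] = cid
            prev_mid = meta.loc[i, "mid"]
    meta["cluster"] = cluster_ids

    curve = None
    if overlap is not None:
        pairs = []
        byrec = meta.set_index("receptor")
        recs = [r for r in overlap.values.index if r in byrec.index]
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                if byrec.loc[a, "chrom"] != byrec.loc[b, "chrom"]:
                    continue
                dist = abs(byrec.loc[a, "mid"] - byrec.loc[b, "mid"])
                ov = overlap.values.loc[a, b]
                if np.isfinite(ov):
                    pairs.append((dist, ov))
        if pairs:
            pf = pd.DataFrame(pairs, columns=["distance_bp", "overlap"])
            pf["bin"] = pd.cut(pf["distance_bp"], bins=list(distance_bins_bp))
            curve = pf.groupby("bin", observed=True)["overlap"].agg(["mean", "count"])

    test = None
    if enhancers is None or len(enhancers) == 0:
        test = {"skipped": "no enhancers supplied"}
    elif abundance is not None:
        near = []
        for _, row in meta.iterrows():
            e = enhancers[enhancers["chrom"] == row["chrom"]]
            near.append(
                bool(len(e)) and bool((np.abs(e["pos"] - row["mid"]) <= enhancer_window_bp).any())
            )
        meta["near_enhancer"] = near
        a = abundance.reindex(meta.loc[meta["near_enhancer"], "receptor"]).dropna()
        b = abundance.reindex(meta.loc[~meta["near_enhancer"], "receptor"]).dropna()
        if len(a) and len(b):
            stat, p = stats.ranksums(a, b)
            test = {"statistic": float(stat), "p_value": float(p),
                    "n_near": int(len(a)), "n_far": int(len(b))}
        else:
            test = {"skipped": "one group empty"}
    return {"clusters": meta, "overlap_vs_distance": curve, "enhancer_test": test}


def patristic_distances(tree, receptors: list[str]) -> pd.DataFrame:
    """All-pairs patristic (branch-length path) distances between tips."""
    from Bio import Phylo

    if isinstance(tree, (str, io.IOBase)):
        handle = io.StringIO(tree) if isinstance(tree, str) else tree
        tree = Phylo.read(handle, "newick")
    tips = {t.name: t for t in tree.get_terminals()}
    present = [r for r in receptors if r in tips]
    # depths from root, then d(a,b) = depth(a) + depth(b) - 2*depth(mrca)
    depths = tree.depths()
    n = len(present)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.common_ancestor([tips[present[i]], tips[present[j]]])
            d = depths[tips[present[i]]] + depths[tips[present[j]]] - 2 * depths[mrca]
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=present, columns=present)


def phylo_association(
    tree,
    overlap: OverlapMatrix | None = None,
    receptor_set: list[str] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    n_bins: int = 4,
) -> dict:
    """Phylogenetic distance vs spatial overlap, or set-coherence test.

    Mode A (``overlap``): pairwise overlap binned by patristic-distance
    quantile, with quartile summaries per bin.  Mode B (``receptor_set``):
    the observed mean within-set patristic distance is ranked against
    ``n_resamples`` size-matched random tip sets; the reported p-value is
    the resampling rank probability that a random set is at least as
    coherent (one-sided, smaller = set more similar than chance).
    """
    out: dict = {}
    if overlap is not None:
        recs = list(overlap.values.index)
        pat = patristic_distances(tree, recs)
        recs = list(pat.index)
        iu = np.triu_indices(len(recs), k=1)
        d = pat.to_numpy()[iu]
        ov = overlap.values.loc[recs, recs].to_numpy()[iu]
        keep = np.isfinite(ov)
        df = pd.DataFrame({"patristic": d[keep], "overlap": ov[keep]})
        if df["patristic"].nunique() > 1:
            df["bin"] = pd.qcut(df["patristic"], q=n_bins, duplicates="drop")
            out["bins"] = df.groupby("bin", observed=True)["overlap"].describe()
        else:
            out["bins"] = None
        out["pairs"] = df
        n_missing = len(overlap.values.index) - len(recs)
        out["n_dropped_tips"] = n_missing
    if receptor_set is not None:
        rng = np.random.default_rng(seed)
        from Bio import Phylo

        if isinstance(tree, str):
            tree_obj = Phylo.read(io.StringIO(tree), "newick")
        else:
            tree_obj = tree
        all_tips = [t.name for t in tree_obj.get_terminals()]
        in_set = [r for r in receptor_set if r in all_tips]
        out["n_dropped_set"] = len(receptor_set) - len(in_set)
        if len(in_set) < 2:
            out["set_test"] = {"skipped": "fewer than 2 set members on the tree"}
            return out
        pat_all = patristic_distances(tree_obj, all_tips)

        def mean_within(members):
            sub = pat_all.loc[members, members].to_numpy()
            iu_ = np.triu_indices(len(members), k=1)
            return float(sub[iu_].mean())

        observed = mean_within(in_set)
        null = np.array([
            mean_within(list(rng.choice(all_tips, size=len(in_set), replace=False)))
            for _ in range(n_resamples)
        ])
        p = (1 + np.sum(null <= observed)) / (n_resamples + 1)
        out["set_test"] = {
            "observed_mean_patristic": observed,
            "null_mean": float(null.mean()),
            "p_value": float(p),
        }
    return out
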