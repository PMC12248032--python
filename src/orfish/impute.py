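"""Transfer of OSN-type-averaged expression onto spatial coordinates.

Type-averaged gene expression from scRNAseq is assigned to each decoded
soma (epithelium) or glomerular projection (bulb) of that type, then
smoothed by averaging within a radius around every surface point (50 um
in the epithelium, 400 um in the bulb) and normalized per gene by the
99th percentile of the surface signal.  Leave-one-out prediction of a
receptor's glomerular position correlates its own expression profile with
the surfaces imputed from all other receptors; gene patterns are ranked
by their gradient along the bulb axes and clustered by pattern
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "ImputedSurface",
    "make_ob_surface_grid",
    "impute_surface",
    "loo_predict_projection",
    "rank_axis_gradients",
    "embed_gene_patterns",
]


@dataclass
class ImputedSurface:
    """Imputed per-gene values over a surface point cloud.

    ``values`` (points x genes) is normalized to [0, 1] per gene;
    ``values_raw`` holds the same values before the clip at 1 so the
    normalization invariant (the chosen percentile of defined values is
    exactly 1) stays checkable.  ``n_contributors`` counts the entities
    within the averaging radius; points with zero contributors are
    undefined (NaN).
    """

    points: np.ndarray
    values: pd.DataFrame
    values_raw: pd.DataFrame
    n_contributors: np.ndarray
    radius_um: float
    norm_percentile: float


def make_ob_surface_grid(
    positions: np.ndarray,
    spacing_um: float = 50.0,
) -> np.ndarray:
    """Uniform 2D/3D grid over the convex region of the given positions."""
    positions = np.asarray(positions, dtype=float)
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    axes = [np.arange(l, h + spacing_um, spacing_um) for l, h in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)
    if len(positions) > positions.shape[1] + 1:
        try:
            hull = Delaunay(positions)
            grid = grid[hull.find_simplex(grid) >= 0]
        except Exception:  # degenerate geometry: keep the box grid
            pass
    return grid


def impute_surface(
    expr: pd.DataFrame,
    entity_types: pd.Series | np.ndarray,
    entity_positions: np.ndarray,
    surface_points: np.ndarray,
    radius_um: float = 50.0,
    norm_percentile: float = 99.0,
    genes: list[str] | None = None,
) -> ImputedSurface:
    """Average transferred type expression within a radius of each point.

    ``expr`` is types x genes; each entity (soma or projection) carries the
    expression row of its type.  Value at a surface point = mean over
    entities within ``radius_um``; per gene the surface is divided by its
    ``norm_percentile`` over defined points and clipped to 1.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if not 0 < norm_percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if genes is not None:
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        expr = expr[genes]
    types = pd.Series(entity_types).astype(str)
    unknown = set(types) - set(expr.index.astype(str))
    if unknown:
        raise KeyError(f"entity types absent from expression matrix: {sorted(unknown)[:5]}")
    e_vals = expr.loc[types].to_numpy(dtype=float)  # (n_entities, n_genes)
    pts = np.asarray(entity_positions, dtype=float)
    surf = np.asarray(surface_points, dtype=float)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(surf, r=radius_um)
    n_genes = e_vals.shape[1]
    raw = np.full((len(surf), n_genes), np.nan)
    counts = np.zeros(len(surf), dtype=int)
    for i, idx in enumerate(neighbors):
        counts[i] = len(idx)
        if idx:
            raw[i] = e_vals[idx].mean(axis=0)
    defined = counts > 0
    scaled = raw.copy()
    for g in range(n_genes):
        col = raw[defined, g]
        if len(col) == 0:
            continue
        p = np.percentile(col, norm_percentile)
        if p > 0:
            scaled[:, g] = raw[:, g] / p
    clipped = np.clip(scaled, None, 1.0)
    cols = list(expr.columns)
    return ImputedSurface(
        points=surf,
        values=pd.DataFrame(clipped, columns=cols),
        values_raw=pd.DataFrame(scaled, columns=cols),
        n_contributors=counts,
        radius_um=radius_um,
        norm_percentile=norm_percentile,
    )


def loo_predict_projection(
    expr: pd.DataFrame,
    projection_map: pd.DataFrame,
    radius_um: float = 400.0,
    grid_spacing_um: float = 50.0,
    regions: tuple[str, ...] = ("medial", "lateral"),
    standardize: bool = True,
) -> pd.DataFrame:
    """Leave-one-out prediction of glomerular positions from expression.

    For each receptor, surfaces are imputed per region (medial/lateral,
    within each hemisphere) from all *other* receptors' projections; the
    predicted position is the surface point whose gene vector correlates
    best (Pearson, over genes) with the receptor's own profile, and the
    error is the distance to the receptor's true glomerulus centroid in
    that region.  With ``standardize`` genes are z-scored across types
    first, so between-gene baseline differences (shared by every profile)
    do not dominate the correlation.
    """
    from scipy import sparse

    receptors = [r for r in projection_map["receptor"].unique() if r in expr.index]
    if projection_map["receptor"].nunique() < 2:
        raise ValueError("need at least 2 receptor types in the map")
    if standardize:
        sd = expr.std(axis=0)
        keep_g = sd > 0
        expr = (expr.loc[:, keep_g] - expr.loc[:, keep_g].mean(axis=0)) / sd[keep_g]
    rows = []
    if "hemisphere" in projection_map.columns:
        region_iter = [
            (f"{h}_{s}", projection_map[(projection_map["hemisphere"] == h)
                                        & (projection_map["side"] == s)])
            for h in projection_map["hemisphere"].unique()
            for s in regions
        ]
    else:
        region_iter = [(s, projection_map[projection_map["side"] == s]) for s in regions]
    for region, reg in region_iter:
        if reg.empty:
            continue
        cent = reg.groupby("receptor")[["x", "y", "z"]].mean()
        ents = reg[reg["receptor"].isin(expr.index)]
        pos = ents[["x", "y", "z"]].to_numpy(dtype=float)
        types = ents["receptor"].to_numpy()
        e_vals = expr.loc[types].to_numpy(dtype=float)
        grid = make_ob_surface_grid(pos, spacing_um=grid_spacing_um)
        tree = cKDTree(pos)
        neighbors = tree.query_ball_point(grid, r=radius_um)
        # sparse point x entity membership -> neighbourhood sums in one pass
        rows_idx = np.repeat(np.arange(len(grid)), [len(n) for n in neighbors])
        cols_idx = np.concatenate([np.asarray(n, dtype=int) for n in neighbors]) \
            if len(rows_idx) else np.array([], dtype=int)
        w = sparse.csr_matrix(
            (np.ones(len(rows_idx)), (rows_idx, cols_idx)),
            shape=(len(grid), len(pos)),
        )
        total = np.asarray(w @ e_vals)                # (points, genes)
        n_all = np.asarray(w.sum(axis=1)).ravel()
        for rec in receptors:
            if rec not in cent.index:
                continue
            profile = expr.loc[rec].to_numpy(dtype=float)
            if profile.std() == 0:
                continue
            own = (types == rec).astype(float)
            c_r = np.asarray(w @ own).ravel()          # own entities per point
            n_loo = n_all - c_r
            valid = n_loo > 0
            if not valid.any():
                continue
            m = (total[valid] - np.outer(c_r[valid], profile)) / n_loo[valid, None]
            # rowwise Pearson with the receptor's own profile
            mc = m - m.mean(axis=1, keepdims=True)
            pc = profile - profile.mean()
            denom = np.linalg.norm(mc, axis=1) * np.linalg.norm(pc)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (mc @ pc) / denom
            r[~np.isfinite(r)] = -np.inf
            gi = int(np.argmax(r))
            best_pt = grid[valid][gi]
            err = float(np.linalg.norm(best_pt - cent.loc[rec].to_numpy()))
            rows.append(
                {"receptor": rec, "region": region, "pred_x": best_pt[0],
                 "pred_y": best_pt[1], "pred_z": best_pt[2],
                 "correlation": float(r[gi]), "error_um": err}
            )
    return pd.DataFrame(rows)


def rank_axis_gradients(
    surface: ImputedSurface,
    axis_coord: np.ndarray,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank genes by |Pearson r| between imputed value and an axis coordinate.

    Genes constant over the defined surface are excluded (r undefined).
    The sign convention follows the axis coordinate as given: a gene
    increasing with the coordinate gets positive r.
    """
    coord = np.asarray(axis_coord, dtype=float)
    defined = surface.n_contributors > 0
    rows = []
    for g in surface.values.columns:
        v = surface.values[g].to_numpy()[defined]
        c = coord[defined]
        if len(v) < 3 or np.std(v) == 0:
            continue
        r, p = stats.pearsonr(v, c)
        rows.append({"gene": g, "r": float(r), "p_value": float(p)})
    out = pd.DataFrame(rows).sort_values("r", key=np.abs, ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["top_positive"] = out[out["r"] > 0].head(top_k)["gene"].tolist()
    out.attrs["top_negative"] = out[out["r"] < 0].head(top_k)["gene"].tolist()
    return out.reset_index(drop=True)


def embed_gene_patterns(
    surface: ImputedSurface,
    seed: int = 0,
    n_neighbors: int = 15,
    resolution: float = 1.0,
) -> pd.DataFrame:
    """2D embedding + community clustering of genes by pattern correlation.

    Dissimilarity between genes = 1 - Pearson r of their surface patterns
    over defined points; UMAP for the embedding and Leiden on a
    k-nearest-neighbour graph for clusters.  Seed-deterministic.
    """
    import igraph
    import leidenalg
    import umap

    defined = surface.n_contributors > 0
    vals = surface.values.loc[defined.nonzero()[0]]
    keep = [g for g in vals.columns if vals[g].std() > 0]
    if len(keep) < 20:
        raise ValueError("need >= 20 genes with defined, non-constant surfaces")
    mat = vals[keep].to_numpy().T  # genes x points
    corr = np.corrcoef(mat)
    diss = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(diss, 0.0)

    k = min(n_neighbors, len(keep) - 1)
    order = np.argsort(diss, axis=1, kind="stable")
    edges = set()
    for i in range(len(keep)):
        for j in order[i, 1:k + 1]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=len(keep), edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed,
    )
    labels = np.asarray(part.membership)

    reducer = umap.UMAP(
        n_components=2, metric="precomputed",
        n_neighbors=k, min_dist=0.1, random_state=seed,
    )
    emb = reducer.fit_transform(diss)
    return pd.DataFrame(
        {"gene": keep, "umap_1": emb[:, 0], "umap_2": emb[:, 1], "cluster": labels}
    )
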