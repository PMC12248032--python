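"""Egr1-based odor-response catalogs across the OR repertoire.

A sensory neuron is scored active when it carries more than 5 Egr1
transcripts; the response of an OR type to a cue is the fraction of its
OSNs that are active, averaged across animals.  Responses are classified
as strong (>50%), partial (>10%) or none; cue-selective receptor sets,
concentration-dependent shifts beyond replicate variation (90% band),
mother-selective types (response >0.05 and >2x the virgin response) and
differentially expressed genes in selected types (two-sided rank-sum,
raw p < 0.01) follow the same counting rules.  Responses are mapped back
onto the epithelium and bulb atlases with 200 um axis binning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "response_fractions",
    "classify_responses",
    "compare_cues",
    "concentration_shift",
    "mother_selective_types",
    "differential_genes",
    "map_responses_to_atlas",
]


def response_fractions(
    cells: pd.DataFrame,
    egr1_threshold: int = 5,
    min_cells: int = 10,
    pooled: bool = False,
    per_animal: bool = False,
) -> pd.DataFrame:
    """Per-receptor (x condition) fraction of cells with count > threshold.

    The activity rule is strict: a cell with exactly ``egr1_threshold``
    transcripts is inactive.  The cross-animal value is the unweighted mean
    of per-animal fractions (``pooled=True`` switches to the pooled-cell
    fraction); ``per_animal=True`` returns the per-animal replicate table
    instead.  Fractions are undefined (NaN) below ``min_cells`` pooled
    cells.
    """
    df = cells.copy()
    if "condition" not in df:
        df["condition"] = "all"
    if "animal" not in df:
        df["animal"] = 0
    df["active"] = df["egr1_count"] > egr1_threshold
    animal_table = (
        df.groupby(["receptor", "condition", "animal"])["active"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "fraction", "size": "n_cells"})
        .reset_index()
    )
    if per_animal:
        return animal_table
    if pooled:
        agg = (
            df.groupby(["receptor", "condition"])["active"]
            .agg(["mean", "size"])
            .rename(columns={"mean": "fraction", "size": "n_cells"})
        )
    else:
        agg = animal_table.groupby(["receptor", "condition"]).agg(
            fraction=("fraction", "mean"), n_cells=("n_cells", "sum")
        )
    agg = agg.reset_index()
    agg.loc[agg["n_cells"] < min_cells, "fraction"] = np.nan
    return agg


def classify_responses(
    catalog: pd.DataFrame,
    partial_threshold: float = 0.10,
    strong_threshold: float = 0.50,
) -> pd.DataFrame:
    """Strong if fraction > 0.5, partial if 0.1 < fraction <= 0.5, else none."""
    out = catalog.copy()
    f = out["fraction"]
    out["response_class"] = np.select(
        [f > strong_threshold, f > partial_threshold],
        ["strong", "partial"],
        default="none",
    )
    out.loc[f.isna(), "response_class"] = "undefined"
    return out


def compare_cues(
    catalog: pd.DataFrame,
    responding_threshold: float = 0.10,
    shared_metric: str = "conditional",
) -> dict:
    """Responding sets per cue, pairwise shared fractions, selectivity classes.

    The responding set of a cue is {receptors with fraction > 0.1}.  The
    shared-responder statistic between cues A and B defaults to
    |A∩B| / |A| (row-conditional, so the matrix is asymmetric);
    ``shared_metric="jaccard"`` switches to |A∩B| / |A∪B|.  Pairwise
    selectivity (e.g. male- vs female-selective) follows: selective for A
    over B iff fraction_A > threshold and fraction_B < threshold.
    """
    if catalog["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    wide = catalog.pivot_table(index="receptor", columns="condition", values="fraction")
    conditions = list(wide.columns)
    responding = {
        c: set(wide.index[wide[c] > responding_threshold].tolist()) for c in conditions
    }
    shared = pd.DataFrame(index=conditions, columns=conditions, dtype=float)
    for a in conditions:
        for b in conditions:
            inter = len(responding[a] & responding[b])
            if shared_metric == "jaccard":
                denom = len(responding[a] | responding[b])
            else:
                denom = len(responding[a])
            shared.loc[a, b] = inter / denom if denom else np.nan
    selective = {}
    for a in conditions:
        for b in conditions:
            if a == b:
                continue
            both = wide[[a, b]].dropna()
            sel = set(
                both.index[
                    (both[a] > responding_threshold) & (both[b] < responding_threshold)
                ]
            )
            selective[(a, b)] = sel
    return {
        "responding": responding,
        "shared": shared,
        "selective": selective,
        "n_shared_receptors": int(wide.dropna().shape[0]),
    }


def concentration_shift(
    catalog_high: pd.DataFrame,
    catalog_low: pd.DataFrame,
    replicate_pairs: pd.DataFrame,
    band: float = 0.90,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Receptors whose high-low response difference exceeds replicate variation.

    The replicate band is the empirical (1-band)/2 .. (1+band)/2 percentile
    range of replicate-pair differences, estimated in ``n_bins`` equal-count
    bins of mean response; a receptor is flagged when (high - low) exceeds
    the upper band at its mean response.  ``replicate_pairs`` has columns
    receptor, rep_a, rep_b (fractions of two replicates under the same
    condition).
    """
    if len(replicate_pairs) < n_bins * 2:
        raise ValueError("not enough replicate pairs to estimate the band")
    rp = replicate_pairs.copy()
    rp["mean"] = (rp["rep_a"] + rp["rep_b"]) / 2.0
    rp["diff"] = rp["rep_a"] - rp["rep_b"]
    rp = rp.dropna(subset=["mean", "diff"]).sort_values("mean").reset_index(drop=True)
    edges = np.quantile(rp["mean"], np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-12
    hi_q = (1 + band) / 2.0
    bin_upper, bin_centers = [], []
    for k in range(n_bins):
        sel = (rp["mean"] > edges[k]) & (rp["mean"] <= edges[k + 1])
        if sel.sum() == 0:
            continue
        bin_upper.append(float(np.quantile(rp.loc[sel, "diff"], hi_q)))
        bin_centers.append(float(rp.loc[sel, "mean"].mean()))

    def upper_at(m):
        if len(bin_centers) == 1:
            return bin_upper[0]
        return float(np.interp(m, bin_centers, bin_upper))

    merged = catalog_high.merge(
        catalog_low, on=["receptor"], suffixes=("_high", "_low")
    ).dropna(subset=["fraction_high", "fraction_low"])
    merged["delta"] = merged["fraction_high"] - merged["fraction_low"]
    merged["mean_response"] = (merged["fraction_high"] + merged["fraction_low"]) / 2.0
    merged["band_upper"] = merged["mean_response"].map(upper_at)
    merged["increased"] = merged["delta"] > merged["band_upper"]
    return merged[
        ["receptor", "fraction_high", "fraction_low", "delta",
         "mean_response", "band_upper", "increased"]
    ]


def mother_selective_types(
    catalog_mother: pd.DataFrame,
    catalog_virgin: pd.DataFrame,
    floor: float = 0.05,
    fold: float = 2.0,
) -> set[str]:
    """Receptors with mother response > floor and > fold x virgin response."""
    m = catalog_mother.set_index("receptor")["fraction"]
    v = catalog_virgin.set_index("receptor")["fraction"]
    shared = m.index.intersection(v.index)
    m, v = m[shared], v[shared]
    sel = (m > floor) & (m > fold * v)
    return set(shared[sel.fillna(False)])


def differential_genes(
    cell_expr: pd.DataFrame,
    type_labels: pd.Series,
    selected_types: set[str],
    p_threshold: float = 0.01,
    sex_labels: pd.Series | None = None,
    y_marker: pd.Series | None = None,
    x_marker: pd.Series | None = None,
    x_min: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum differential expression in selected types vs all others.

    Cells not from female animals are removed first: either via explicit
    ``sex_labels`` or by marker expression (any Y-linked marker expression
    above zero, or X-linked marker below ``x_min``, excludes the cell).
    Per gene a two-sided Wilcoxon rank-sum test compares selected-type
    cells to the rest; ``significant`` flags raw p < threshold, and the
    reported up-list additionally requires a higher median in the selected
    group.  A Benjamini-Hochberg column is included alongside the raw p.
    """
    labels = pd.Series(type_labels).reset_index(drop=True)
    expr = cell_expr.reset_index(drop=True)
    keep = np.ones(len(expr), dtype=bool)
    if sex_labels is not None:
        keep &= (pd.Series(sex_labels).reset_index(drop=True) == "F").to_numpy()
    if y_marker is not None:
        keep &= (pd.Series(y_marker).reset_index(drop=True) <= 0).to_numpy()
    if x_marker is not None:
        keep &= (pd.Series(x_marker).reset_index(drop=True) >= x_min).to_numpy()
    expr = expr.loc[keep]
    labels = labels.loc[keep]
    in_sel = labels.isin(selected_types).to_numpy()
    if in_sel.sum() < 2 or (~in_sel).sum() < 2:
        raise ValueError("need >= 2 cells per group after filtering")
    rows = []
    for gene in expr.columns:
        a = expr.loc[in_sel, gene].to_numpy(dtype=float)
        b = expr.loc[~in_sel, gene].to_numpy(dtype=float)
        stat, p = stats.ranksums(a, b)
        rows.append(
            {"gene": gene, "statistic": float(stat), "p_value": float(p),
             "median_selected": float(np.median(a)), "median_other": float(np.median(b))}
        )
    out = pd.DataFrame(rows)
    out["up_in_selected"] = out["median_selected"] > out["median_other"]
    out["significant"] = out["p_value"] < p_threshold
    m = len(out)
    order = np.argsort(out["p_value"].to_numpy(), kind="stable")
    bh = np.empty(m)
    ranked = out["p_value"].to_numpy()[order] * m / np.arange(1, m + 1)
    bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    out["p_bh"] = np.clip(bh, 0, 1)
    out.attrs["up_genes"] = out.loc[
        out["significant"] & out["up_in_selected"], "gene"
    ].tolist()
    out.attrs["n_cells_selected"] = int(in_sel.sum())
    return out


def map_responses_to_atlas(
    catalog: pd.DataFrame,
    spatial_index: pd.DataFrame | None = None,
    projection_map: pd.DataFrame | None = None,
    axis_bin_um: float = 200.0,
    responding_threshold: float = 0.10,
) -> dict:
    """Map per-OR responses onto the MOE index and OB projection map.

    Per-cell / per-glomerulus weight is the receptor's responding
    fraction; the DV and AP densities are the sums of responding-receptor
    projection weights per ``axis_bin_um`` bin, normalized to unit area.
    Receptors absent from an atlas are dropped and counted.
    """
    frac = catalog.set_index("receptor")["fraction"]
    out: dict = {"n_dropped_moe": 0, "n_dropped_ob": 0}
    if spatial_index is not None:
        joined = spatial_index.join(frac.rename("response"), how="left")
        out["n_dropped_moe"] = int(
            len(frac.index.difference(spatial_index.index))
        )
        out["moe"] = joined
    if projection_map is not None:
        pm = projection_map.copy()
        pm["response"] = frac.reindex(pm["receptor"]).to_numpy()
        out["n_dropped_ob"] = int(len(frac.index.difference(set(pm["receptor"]))))
        pm = pm.dropna(subset=["response"])
        out["ob"] = pm
        resp = pm[pm["response"] > responding_threshold]
        densities = {}
        for axis, col in (("dv", "y"), ("ap", "z")):
            if resp.empty:
                densities[axis] = pd.DataFrame(columns=["bin_center", "density"])
                continue
            bins = np.floor(resp[col] / axis_bin_um).astype(int)
            w = resp.groupby(bins)["response"].sum()
            area = w.sum() * axis_bin_um
            densities[axis] = pd.DataFrame(
                {"bin_center": (w.index + 0.5) * axis_bin_um,
                 "density": w.to_numpy() / area}
            )
        out["densities"] = densities
    return out
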