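"""Transcript-level decoding in the olfactory bulb glomerular layer.

OR transcripts in axon terminals are decoded molecule by molecule: single
spots are localized as 3D local maxima in each readout image, spots that
colocalize within ~160 nm per axis in at least 4 of the 15 bits form a
molecule (keeping the 4 brightest bits when more colocalize), a brightness
threshold separating targeted from untargeted barcodes removes dim noise
molecules, and each segmented glomerulus is assigned the identity of its
most enriched OR when the count exceeds 10 and is more than 10x the
largest count of that OR in any other glomerulus of the section.  Counts
between 5 and 10 are rescued by a relaxed consensus rule when the same OR
appears within 500 um across multiple bulbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Spot",
    "Molecule",
    "detect_spots",
    "colocalize",
    "fit_brightness_threshold",
    "count_molecules_per_glomerulus",
    "assign_glomerulus_identity",
    "relaxed_consensus",
]


@dataclass(frozen=True)
class Spot:
    bit: int
    position_um: tuple[float, float, float]  # z, y, x
    brightness: float

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")


@dataclass(frozen=True)
class Molecule:
    position_um: tuple[float, float, float]
    bits: tuple[int, ...]
    brightness: float
    receptor_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.bits) != 4 or len(set(self.bits)) != 4:
            raise ValueError("a molecule has exactly 4 distinct member bits")


def detect_spots(
    image: np.ndarray,
    bit: int,
    intensity_threshold: float,
    pixel_size_um: tuple[float, float, float] = (1.0, 0.1, 0.1),
) -> list[Spot]:
    """Strict 3D local maxima above threshold, subpixel by local mass center.

    A voxel is a spot when it strictly exceeds its 26 neighbours and the
    intensity threshold; its position is refined by the intensity-weighted
    center of mass of the 3x3x3 neighbourhood, converted to um.
    """
    if intensity_threshold < 0:
        raise ValueError("threshold must be >= 0")
    img = np.asarray(image, dtype=float)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant")
    peaks = np.argwhere((img > neigh_max) & (img > intensity_threshold))
    spots = []
    pixel = np.asarray(pixel_size_um)
    for p in peaks:
        lo = np.maximum(p - 1, 0)
        hi = np.minimum(p + 2, img.shape)
        sub = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        grids = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
        w = sub - sub.min()
        if w.sum() <= 0:
            com = p.astype(float)
        else:
            com = np.array([(g * w).sum() / w.sum() for g in grids])
        pos = tuple((com + 0.5) * pixel)
        spots.append(Spot(bit=bit, position_um=pos, brightness=float(img[tuple(p)])))
    return spots


def colocalize(
    spots: list[Spot],
    radius_um: float = 0.160,
    min_bits: int = 4,
) -> list[Molecule]:
    """Group cross-bit colocalizing spots into molecules.

    The radius applies per axis (a box, matching the per-axis wording of
    the colocalization criterion).  Conflicts are resolved greedily by
    descending seed-spot brightness: the brightest unused spot seeds a
    candidate group of all unused spots within the box; if the group spans
    at least ``min_bits`` distinct bits, the brightest spot per bit is
    taken and the 4 brightest of those bits form the molecule.  Every spot
    joins at most one molecule.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if not spots:
        return []
    order = sorted(range(len(spots)), key=lambda i: (-spots[i].brightness, i))
    pos = np.array([s.position_um for s in spots])
    tree = cKDTree(pos)
    used = np.zeros(len(spots), dtype=bool)
    molecules: list[Molecule] = []
    for i in order:
        if used[i]:
            continue
        # Chebyshev (p=inf) ball == per-axis box
        idx = tree.query_ball_point(pos[i], r=radius_um, p=np.inf)
        idx = [j for j in idx if not used[j]]
        best_per_bit: dict[int, int] = {}
        for j in idx:
            b = spots[j].bit
            if b not in best_per_bit or spots[j].brightness > spots[best_per_bit[b]].brightness:
                best_per_bit[b] = j
        if len(best_per_bit) < min_bits:
            continue
        members = sorted(
            best_per_bit.values(), key=lambda j: (-spots[j].brightness, j)
        )[:4]
        used[members] = True
        mpos = pos[members].mean(axis=0)
        molecules.append(
            Molecule(
                position_um=tuple(mpos),
                bits=tuple(sorted(spots[j].bit for j in members)),
                brightness=float(np.mean([spots[j].brightness for j in members])),
            )
        )
    return molecules


def fit_brightness_threshold(
    brightness: np.ndarray,
    targeted: np.ndarray,
) -> tuple[float | None, np.ndarray]:
    """1-D optimal split between targeted and untargeted brightness.

    Returns the threshold minimizing total misclassification (targeted
    below + untargeted at/above) and a keep mask removing molecules dimmer
    than the threshold.  With one population empty a warning is emitted and
    nothing is filtered.
    """
    brightness = np.asarray(brightness, dtype=float)
    targeted = np.asarray(targeted, dtype=bool)
    if targeted.all() or (~targeted).all():
        warnings.warn("one brightness population empty; threshold undefined, no filtering")
        return None, np.ones(len(brightness), dtype=bool)
    order = np.argsort(brightness, kind="stable")
    b_sorted = brightness[order]
    t_sorted = targeted[order].astype(int)
    n_t = t_sorted.sum()
    # candidate thresholds: below the smallest and between consecutive values;
    # cum_t[k] targeted among the k dimmest
    cum_t = np.concatenate([[0], np.cumsum(t_sorted)])
    cum_u = np.arange(len(b_sorted) + 1) - cum_t
    n_u = len(b_sorted) - n_t
    # classify >= threshold as targeted: errors = targeted below + untargeted at/above
    errors = cum_t + (n_u - cum_u)
    k = int(np.argmin(errors))
    if k == 0:
        thr = b_sorted[0] - 1e-12
    else:
        thr = (b_sorted[k - 1] + b_sorted[min(k, len(b_sorted) - 1)]) / 2.0
    keep = brightness >= thr
    return float(thr), keep


def count_molecules_per_glomerulus(
    molecules: pd.DataFrame,
    masks: np.ndarray,
    mask_pixel_um: float,
) -> pd.DataFrame:
    """Per-glomerulus per-receptor molecule counts from section label masks.

    ``molecules`` needs columns section, y, x (um) and receptor; ``masks``
    is (n_sections, H, W) integer labels.  Molecules outside any
    glomerulus are dropped.
    """
    rows = []
    for s, grp in molecules.groupby("section"):
        mask = masks[int(s)]
        iy = np.clip((grp["y"].to_numpy() / mask_pixel_um).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip((grp["x"].to_numpy() / mask_pixel_um).astype(int), 0, mask.shape[1] - 1)
        labs = mask[iy, ix]
        sub = grp.assign(glomerulus=labs)
        sub = sub[sub["glomerulus"] > 0]
        counted = sub.groupby(["glomerulus", "receptor"]).size().rename("count").reset_index()
        counted["section"] = int(s)
        rows.append(counted)
    if not rows:
        return pd.DataFrame(columns=["glomerulus", "receptor", "count", "section"])
    return pd.concat(rows, ignore_index=True)


def assign_glomerulus_identity(
    counts: pd.DataFrame,
    min_count: int = 10,
    enrichment: float = 10.0,
) -> pd.DataFrame:
    """Strict per-section assignment rule.

    A glomerulus is assigned its maximum-count OR iff that count is
    strictly greater than ``min_count`` AND strictly greater than
    ``enrichment`` times the largest count of the same OR in any *other*
    glomerulus of the same section (an OR seen nowhere else counts as 1 in
    the denominator).  ``counts`` has columns glomerulus, section,
    receptor, count.  Returns one row per glomerulus with assigned
    receptor (or None) and tier in {"strict", "none"}.
    """
    out = []
    for s, sec in counts.groupby("section"):
        per_glom = sec.groupby("glomerulus")
        # max count of each receptor per glomerulus in this section
        pivot = sec.pivot_table(index="glomerulus", columns="receptor",
                                values="count", aggfunc="sum", fill_value=0)
        for g, grp in per_glom:
            row = pivot.loc[g]
            top = row.idxmax()
            top_count = int(row[top])
            others = pivot.drop(index=g)[top] if len(pivot) > 1 else pd.Series(dtype=float)
            denom = float(others.max()) if len(others) and others.max() > 0 else 1.0
            ok = top_count > min_count and top_count > enrichment * denom
            out.append(
                {
                    "glomerulus": g, "section": s,
                    "receptor": top if ok else None,
                    "top_receptor": top, "top_count": top_count,
                    "tier": "strict" if ok else "none",
                }
            )
    return pd.DataFrame(out)


def relaxed_consensus(
    maps: list[pd.DataFrame],
    relaxed_min: int = 5,
    consensus_radius_um: float = 500.0,
) -> pd.DataFrame:
    """Rescue sub-threshold glomeruli consistent in position across bulbs.

    Each map is an aligned glomerulus table with columns receptor (the
    candidate identity, possibly unassigned by the strict rule),
    top_receptor, top_count, x, y, z, tier.  A glomerulus with
    ``tier == "none"`` and ``top_count > relaxed_min`` is assigned its top
    OR if at least one other bulb holds a glomerulus with the same top OR
    (strict or relaxed candidate) within ``consensus_radius_um``; rescued
    entries get tier "relaxed" and their position replaced by the
    cross-bulb mean over the consenting glomeruli.
    """
    if len(maps) < 2:
        warnings.warn("fewer than 2 bulbs: consensus impossible, strict-only output")
        return pd.concat(maps, ignore_index=True) if maps else pd.DataFrame()
    tagged = []
    for bi, m in enumerate(maps):
        m = m.copy()
        m["bulb"] = bi
        tagged.append(m)
    allg = pd.concat(tagged, ignore_index=True)
    result = allg.copy()
    cand = allg[(allg["tier"] == "none") & (allg["top_count"] > relaxed_min)]
    support = allg[(allg["tier"] == "strict") | (allg["top_count"] > relaxed_min)]
    for i, row in cand.iterrows():
        peers = support[
            (support["top_receptor"] == row["top_receptor"])
            & (support["bulb"] != row["bulb"])
        ]
        if peers.empty:
            continue
        d = np.sqrt(
            (peers["x"] - row["x"]) ** 2
            + (peers["y"] - row["y"]) ** 2
            + (peers["z"] - row["z"]) ** 2
        )
        near = peers[d <= consensus_radius_um]
        if near.empty:
            continue
        group = pd.concat([near, row.to_frame().T])
        result.loc[i, "receptor"] = row["top_receptor"]
        result.loc[i, "tier"] = "relaxed"
        result.loc[i, ["x", "y", "z"]] = group[["x", "y", "z"]].astype(float).mean().to_numpy()
    return result
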