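"""Soma-level OR identity decoding in the olfactory epithelium.

A sensory neuron expresses a single OR at high level, so its soma is bright
in exactly the 4 readout bits of that OR's barcode, with the fluorescent
texture correlated across those 4 channels.  Decoding scans ~2.5 um cubes
across the section, computes all pairwise Pearson correlations between
readout channels within each cube, finds the 4-bit combination with the
highest mean internal correlation, keeps cubes whose best combination
exceeds a correlation threshold (0.6), groups the surviving voxels into
cells by density-based clustering, and assigns each cell the receptor whose
codebook entry matches its bit quadruple.  Egr1 transcripts are counted per
cell as 3D local maxima in the Egr1 channel within the (slightly dilated)
cell voxel set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import DBSCAN

from .codebook import Codebook

__all__ = [
    "ReadoutStack",
    "CellRecord",
    "CubeCorrelationMap",
    "cube_correlation_map",
    "extract_candidate_voxels",
    "density_cluster_cells",
    "assign_cell_identity",
    "count_egr1",
    "decode_section",
    "cells_to_frame",
]


@dataclass
class ReadoutStack:
    """Multi-channel 3D image stack: per-bit readouts + Egr1 + nuclear.

    ``bits`` has shape (n_bits, z, y, x); ``pixel_size_um`` is (z, y, x).
    """

    bits: np.ndarray
    egr1: np.ndarray
    nuclear: np.ndarray
    pixel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.bits.ndim != 4:
            raise ValueError("bits must be (n_bits, z, y, x)")
        if self.egr1.shape != self.bits.shape[1:] or self.nuclear.shape != self.bits.shape[1:]:
            raise ValueError("all channels must share the spatial shape")
        if np.any(self.bits < 0) or np.any(self.egr1 < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape[1:]

    def save_tiff(self, path) -> None:
        """Write all channels as one multi-plane TIFF (C, Z, Y, X)."""
        import tifffile

        data = np.concatenate([self.bits, self.egr1[None], self.nuclear[None]])
        tifffile.imwrite(
            path, data.astype(np.float32),
            metadata={"axes": "CZYX", "pixel_size_um": list(self.pixel_size_um)},
        )

    @classmethod
    def load_tiff(cls, path, pixel_size_um=(1.0, 0.5, 0.5)) -> "ReadoutStack":
        import tifffile

        data = np.asarray(tifffile.imread(path))
        return cls(bits=data[:-2], egr1=data[-2], nuclear=data[-1],
                   pixel_size_um=tuple(pixel_size_um))


@dataclass
class CellRecord:
    cell_id: int
    section_id: int
    centroid_um: tuple[float, float, float]  # z, y, x
    volume_voxels: int
    receptor_id: str | None
    mean_on_bit_correlation: float
    mean_brightness: float
    egr1_count: int = 0
    voxels: np.ndarray | None = field(default=None, repr=False)  # (n, 3) int indices


@dataclass
class CubeCorrelationMap:
    """Best 4-bit combination and its mean internal correlation per cube.

    ``starts`` are the (z, y, x) voxel origins of each cube; ``best_quad``
    indexes into ``quads`` (all 4-subsets of bits in lexicographic order);
    ``best_score`` is the mean of the 6 internal pairwise correlations.
    Cubes with a constant channel have that channel's correlations treated
    as 0 and are flagged in ``undefined``.
    """

    starts: np.ndarray
    cube_shape: tuple[int, int, int]
    quads: np.ndarray          # (n_quads, 4)
    best_quad: np.ndarray      # (n_cubes,) index into quads
    best_score: np.ndarray     # (n_cubes,)
    undefined: np.ndarray      # (n_cubes,) bool
    pairs: list[tuple[int, int]] | None = None
    pair_corr: np.ndarray | None = None  # (n_cubes, n_pairs) float32


def _cube_shape_voxels(cube_size_um: float, pixel_size_um, shape) -> tuple[int, int, int]:
    cz, cy, cx = (max(2, int(round(cube_size_um / p))) for p in pixel_size_um)
    cz = min(cz, shape[0])
    if cy > shape[1] or cx > shape[2]:
        raise ValueError("cube larger than image")
    return cz, cy, cx


def cube_correlation_map(
    stack: ReadoutStack,
    cube_size_um: float = 2.5,
    stride_voxels: tuple[int, int, int] | None = None,
) -> CubeCorrelationMap:
    """Scan cubes across the stack and score every 4-bit combination.

    The stride defaults to half the cube size per axis (overlapping cubes)
    so that no soma is split across cube boundaries only.  For each cube all
    C(n_bits, 2) Pearson correlations are computed from per-cube moments via
    box sums; the best quadruple is found by exhaustive search over all
    C(n_bits, 4) subsets, scored by the mean of their 6 internal pairwise
    correlations.
    """
    n_bits = stack.n_bits
    shape = stack.shape
    cube = _cube_shape_voxels(cube_size_um, stack.pixel_size_um, shape)
    if stride_voxels is None:
        stride_voxels = tuple(max(1, c // 2) for c in cube)

    # cube origins along each axis (half-open, last cube flush with the edge)
    axes_starts = []
    for ax in range(3):
        last = shape[ax] - cube[ax]
        pts = list(range(0, last + 1, stride_voxels[ax]))
        if pts[-1] != last:
            pts.append(last)
        axes_starts.append(np.asarray(pts))
    gz, gy, gx = np.meshgrid(*axes_starts, indexing="ij")
    starts = np.stack([gz.ravel(), gy.ravel(), gx.ravel()], axis=1)
    n_cubes = len(starts)

    # per-cube channel means/second moments via summed-area (box filter) at
    # cube *centers*; uniform_filter with the cube size gives the box mean
    center_idx = tuple(
        starts[:, ax] + cube[ax] // 2 for ax in range(3)
    )

    def box_mean(vol: np.ndarray) -> np.ndarray:
        out = ndimage.uniform_filter(vol, size=cube, mode="constant")
        return out[center_idx]

    # uniform_filter centers the box; align cube origin -> center by offset
    # (handled by sampling at start + cube//2, exact for odd sizes and off by
    # <=half a voxel for even sizes, which the overlapping stride absorbs)
    bits = stack.bits.astype(np.float32, copy=False)
    means = np.empty((n_bits, n_cubes), dtype=np.float64)
    sqs = np.empty((n_bits, n_cubes), dtype=np.float64)
    for b in range(n_bits):
        v = bits[b]
        means[b] = box_mean(v)
        sqs[b] = box_mean(v * v)
    var = np.maximum(sqs - means**2, 0.0)
    sd = np.sqrt(var)

    pairs = list(itertools.combinations(range(n_bits), 2))
    corr = np.empty((n_cubes, len(pairs)), dtype=np.float32)
    undefined = np.zeros(n_cubes, dtype=bool)
    eps = 1e-12
    for k, (i, j) in enumerate(pairs):
        cross = box_mean(bits[i] * bits[j])
        cov = cross - means[i] * means[j]
        denom = sd[i] * sd[j]
        bad = denom < eps
        undefined |= bad
        r = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
        corr[:, k] = np.clip(r, -1.0, 1.0)

    quads = np.asarray(list(itertools.combinations(range(n_bits), 4)))
    pair_index = {p: k for k, p in enumerate(pairs)}
    quad_pairs = np.asarray(
        [[pair_index[p] for p in itertools.combinations(q, 2)] for q in quads]
    )  # (n_quads, 6)

    # mean internal correlation of every quadruple in every cube, as a single
    # matmul with a 0/1 membership matrix over the pair axis
    member = np.zeros((len(pairs), len(quads)), dtype=np.float32)
    for qi, pk in enumerate(quad_pairs):
        member[pk, qi] = 1.0 / 6.0

    best_quad = np.empty(n_cubes, dtype=np.int32)
    best_score = np.empty(n_cubes, dtype=np.float32)
    chunk = 16384
    for lo in range(0, n_cubes, chunk):
        hi = min(lo + chunk, n_cubes)
        scores = corr[lo:hi] @ member
        best_quad[lo:hi] = np.argmax(scores, axis=1)
        best_score[lo:hi] = scores[np.arange(hi - lo), best_quad[lo:hi]]

    return CubeCorrelationMap(
        starts=starts,
        cube_shape=cube,
        quads=quads,
        best_quad=best_quad,
        best_score=best_score,
        undefined=undefined,
        pairs=pairs,
        pair_corr=corr,
    )


def extract_candidate_voxels(
    cmap: CubeCorrelationMap,
    shape: tuple[int, int, int],
    threshold: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-level quadruple assignment from cubes above threshold.

    Returns ``(quad_id, score)`` volumes: ``quad_id[v]`` is the index of the
    best quadruple of the best-scoring cube covering voxel ``v`` (or -1),
    considering only cubes whose best mean correlation strictly exceeds
    ``threshold``.  Overlapping cubes that disagree are resolved in favour
    of the higher-correlated cube.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    quad_vol = np.full(shape, -1, dtype=np.int32)
    score_vol = np.full(shape, -np.inf, dtype=np.float32)
    keep = np.where(cmap.best_score > threshold)[0]
    cz, cy, cx = cmap.cube_shape
    # ascending score so the best cube paints last
    for k in keep[np.argsort(cmap.best_score[keep], kind="stable")]:
        z0, y0, x0 = cmap.starts[k]
        sl = (slice(z0, z0 + cz), slice(y0, y0 + cy), slice(x0, x0 + cx))
        s = cmap.best_score[k]
        better = s > score_vol[sl]
        score_vol[sl][better] = s
        quad_vol[sl][better] = cmap.best_quad[k]
    score_vol[quad_vol < 0] = np.nan
    return quad_vol, score_vol


def density_cluster_cells(
    quad_vol: np.ndarray,
    score_vol: np.ndarray,
    pixel_size_um: tuple[float, float, float],
    radius_um: float = 1.5,
    min_points: int = 10,
) -> list[dict]:
    """Group candidate voxels into cells with DBSCAN, per bit-quadruple.

    Voxels carrying different quadruples never join the same cell.  Returns
    one dict per cluster with the voxel index array, quadruple id and the
    mean cube correlation over member voxels.
    """
    if radius_um <= min(pixel_size_um):
        raise ValueError("clustering radius must exceed the voxel size")
    clusters: list[dict] = []
    for quad_id in np.unique(quad_vol[quad_vol >= 0]):
        vox = np.argwhere(quad_vol == quad_id)
        if len(vox) < min_points:
            continue
        pts = vox * np.asarray(pixel_size_um)
        labels = DBSCAN(eps=radius_um, min_samples=min_points).fit_predict(pts)
        for lab in np.unique(labels[labels >= 0]):
            members = vox[labels == lab]
            clusters.append(
                {
                    "voxels": members,
                    "quad_id": int(quad_id),
                    "mean_correlation": float(
                        np.nanmean(score_vol[tuple(members.T)])
                    ),
                }
            )
    return clusters


def assign_cell_identity(
    cluster: dict,
    cmap_quads: np.ndarray,
    codebook: Codebook,
    stack: ReadoutStack,
    cell_id: int = 0,
    section_id: int = 0,
) -> CellRecord:
    """Assign the receptor whose code matches the cluster's bit quadruple.

    The centroid is the intensity-weighted mean voxel position (weights are
    the mean on-bit intensity per voxel); brightness is the mean on-bit
    intensity over the cluster.  A quadruple absent from the codebook leaves
    the cell unassigned.
    """
    quad = tuple(int(b) for b in cmap_quads[cluster["quad_id"]])
    receptor = codebook.lookup(quad)
    vox = cluster["voxels"]
    idx = tuple(vox.T)
    on = stack.bits[list(quad)][:, idx[0], idx[1], idx[2]]  # (4, n_vox)
    w = on.mean(axis=0).astype(np.float64)
    if w.sum() <= 0:
        w = np.ones(len(vox))
    centroid_vox = (vox * w[:, None]).sum(axis=0) / w.sum()
    centroid_um = tuple(
        float((centroid_vox[ax] + 0.5) * stack.pixel_size_um[ax]) for ax in range(3)
    )
    return CellRecord(
        cell_id=cell_id,
        section_id=section_id,
        centroid_um=centroid_um,
        volume_voxels=len(vox),
        receptor_id=receptor,
        mean_on_bit_correlation=cluster["mean_correlation"],
        mean_brightness=float(on.mean()),
        voxels=vox,
    )


def count_egr1(
    cell: CellRecord,
    egr1: np.ndarray,
    intensity_threshold: float,
    dilate_voxels: int = 1,
) -> int:
    """Count Egr1 transcripts as 3D local maxima inside the cell's voxels.

    The cell mask is dilated by ``dilate_voxels`` to catch spots on the soma
    margin.  A voxel counts when it strictly exceeds all 26 neighbours and
    the intensity threshold.
    """
    if cell.voxels is None or len(cell.voxels) == 0:
        return 0
    vox = cell.voxels
    lo = np.maximum(vox.min(axis=0) - dilate_voxels - 1, 0)
    hi = np.minimum(vox.max(axis=0) + dilate_voxels + 2, egr1.shape)
    sub = egr1[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    mask = np.zeros(sub.shape, dtype=bool)
    rel = vox - lo
    mask[tuple(rel.T)] = True
    if dilate_voxels:
        mask = ndimage.binary_dilation(mask, iterations=dilate_voxels)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(sub, footprint=footprint, mode="constant")
    peaks = (sub > neigh_max) & (sub > intensity_threshold) & mask
    return int(peaks.sum())


def decode_section(
    stack: ReadoutStack,
    codebook: Codebook,
    cube_size_um: float = 2.5,
    corr_threshold: float = 0.6,
    cluster_radius_um: float = 1.5,
    min_points: int = 10,
    egr1_threshold: float | None = None,
    section_id: int = 0,
) -> list[CellRecord]:
    """Full soma decoding pipeline for one section."""
    cmap = cube_correlation_map(stack, cube_size_um=cube_size_um)
    quad_vol, score_vol = extract_candidate_voxels(cmap, stack.shape, corr_threshold)
    clusters = density_cluster_cells(
        quad_vol, score_vol, stack.pixel_size_um, cluster_radius_um, min_points
    )
    if egr1_threshold is None:
        # robust default: background mean + 5 sd of the Egr1 channel
        med = float(np.median(stack.egr1))
        mad = float(np.median(np.abs(stack.egr1 - med))) * 1.4826
        egr1_threshold = med + 5.0 * max(mad, 1e-6)
    cells = []
    for i, cl in enumerate(clusters):
        rec = assign_cell_identity(cl, cmap.quads, codebook, stack, cell_id=i, section_id=section_id)
        rec.egr1_count = count_egr1(rec, stack.egr1, egr1_threshold)
        cells.append(rec)
    return cells


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "section": [c.section_id for c in cells],
            "z": [c.centroid_um[0] for c in cells],
            "y": [c.centroid_um[1] for c in cells],
            "x": [c.centroid_um[2] for c in cells],
            "receptor": [c.receptor_id for c in cells],
            "volume": [c.volume_voxels for c in cells],
            "mean_corr": [c.mean_on_bit_correlation for c in cells],
            "brightness": [c.mean_brightness for c in cells],
            "egr1_count": [c.egr1_count for c in cells],
        }
    )
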