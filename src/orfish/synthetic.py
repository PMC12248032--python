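"""Synthetic data generators emulating the study's signal structure.

Every pipeline input can be generated here with known ground truth:

* MOE sections as multi-bit image stacks in which each soma carries
  correlated signal in exactly the 4 on-bit channels of its OR's barcode,
  an Egr1 channel with per-cell transcript spots, and a nuclear channel.
* Atlas-scale MOE cell tables with concentric ring-structured OR zones, a
  basal-apical depth sub-gradient across the epithelium thickness, and a
  detached "unusual zone" patch.
* Olfactory-bulb projection maps and per-section molecule tables with one
  dominant OR per glomerulus, mirror-symmetric medial/lateral placements
  and background molecules.
* Serial-section deformations (rigid + smooth bandlimited field) with the
  exact inverse stored for round-trip checks.
* OSN-type x gene expression matrices with a planted fraction of genes
  graded along a spatial coordinate.
* Per-cell Egr1 count tables with planted per-OR x cue response fractions.

All generators are deterministic given their seed, and the returned ground
truth suffices to recompute every downstream quantity by independent
counting/geometry oracles.

The epithelium is modelled as a flat ribbon: section-plane coordinates
(x, y) in um carry the ring structure, and a depth coordinate in
[0, thickness] runs from the basal lamina (0) to the apical surface, so
both surfaces are analytic parallel planes and the depth ground truth is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codebook import Codebook
from .moe_decode import ReadoutStack

__all__ = [
    "SyntheticConfig",
    "MoeSectionTruth",
    "simulate_moe_section",
    "simulate_moe_cells",
    "simulate_ob_maps",
    "simulate_ob_series",
    "rasterize_spots",
    "apply_known_deformation",
    "deform_points",
    "invert_deformation",
    "simulate_nuclei_image",
    "simulate_scrnaseq",
    "simulate_egr1_cells",
]


@dataclass
class SyntheticConfig:
    """Study-condition parameters for all generators (lengths in um)."""

    # imaging grid (z, y, x); the synthetic grid is coarser than the
    # instrument's 0.1 um decoding scale so a full section decodes in
    # minutes; all signal statistics are set relative to this grid
    shape: tuple[int, int, int] = (10, 448, 448)
    pixel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    n_cells: int = 200
    n_receptors: int = 50
    soma_radius_um: float = 3.0
    min_separation_um: float = 6.5
    max_placement_tries: int = 20000
    signal_amplitude: float = 30.0
    background_level: float = 2.0
    noise_sd: float = 2.0
    egr1_spot_amplitude: float = 80.0
    egr1_spot_sigma_um: float = 0.5
    nuclear_sigma_um: float = 1.5
    # ring-zone geometry (atlas scale)
    ring_radius_min_um: float = 150.0
    ring_radius_max_um: float = 1400.0
    ring_width_um: float = 40.0
    unusual_zone_center_um: tuple[float, float] = (1950.0, 0.0)
    unusual_zone_sigma_um: float = 25.0
    n_unusual: int = 4
    epithelium_thickness_um: float = 60.0
    depth_offset_range: tuple[float, float] = (0.2, 0.8)
    depth_sigma: float = 0.08
    # olfactory bulb
    ob_extent_um: tuple[float, float, float] = (2600.0, 2000.0, 3000.0)  # z(AP), y(DV), x(ML)
    glomerulus_radius_um: float = 50.0
    glomerulus_jitter_um: float = 30.0
    dominant_count: int = 30
    background_rate: float = 0.5  # stray molecules per glomerulus
    n_sections: int = 24
    section_z_um: float = 16.0
    # Egr1 response model: responders are 6 + Poisson(lambda_high) so every
    # responder clears the >5 transcript threshold; non-responders are
    # Poisson(lambda_low)
    egr1_lambda_high: float = 9.0
    egr1_lambda_low: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("soma_radius_um", "min_separation_um", "ring_width_um",
                     "epithelium_thickness_um", "glomerulus_radius_um", "section_z_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MoeSectionTruth:
    """Planted ground truth for one simulated MOE section."""

    cells: pd.DataFrame           # cell_id, receptor, z/y/x um, egr1_count, responder
    cell_labels: np.ndarray       # voxel label volume, 0 = background
    proportions: pd.Series        # planted per-OR multinomial proportions
    response_fractions: pd.Series  # per-OR planted responder fraction


def _receptor_ids(n: int) -> list[str]:
    return [f"Olfr{i:04d}" for i in range(n)]


def _place_centers(rng, n, lo, hi, min_sep, max_tries):
    centers = []
    tries = 0
    while len(centers) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} somas at min separation {min_sep} um"
            )
        tries += 1
        c = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(c - p) >= min_sep for p in centers):
            centers.append(c)
    return np.asarray(centers)


def simulate_moe_section(
    config: SyntheticConfig,
    codebook: Codebook,
    seed: int | None = None,
    response_fractions: pd.Series | None = None,
) -> tuple[ReadoutStack, MoeSectionTruth]:
    """Simulate one MOE section as a ReadoutStack with ground truth.

    Each soma is a sphere whose 4 on-bit channels share a common multiplied
    texture (hence high pairwise correlation), off-bits carry background
    and noise only.  Egr1 counts are drawn from the planted response model
    and rendered as well-separated Gaussian spots inside the soma.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nz, ny, nx = config.shape
    pz, py, px = config.pixel_size_um
    n_bits = codebook.n_bits
    receptors = codebook.receptors[: config.n_receptors]
    if len(receptors) < config.n_receptors:
        raise ValueError("codebook has fewer receptors than requested")

    extent = np.array([nz * pz, ny * py, nx * px])
    r = config.soma_radius_um
    lo = np.array([min(r, extent[0] / 2), r, r])
    hi = extent - lo
    centers = _place_centers(
        rng, config.n_cells, lo, hi, config.min_separation_um, config.max_placement_tries
    )

    # planted multinomial over receptors (mildly non-uniform, Dirichlet)
    props = rng.dirichlet(np.full(len(receptors), 5.0))
    proportions = pd.Series(props, index=receptors)
    labels = rng.choice(len(receptors), size=config.n_cells, p=props)

    if response_fractions is None:
        response_fractions = pd.Series(
            rng.uniform(0.0, 0.4, size=len(receptors)), index=receptors
        )

    bits = np.zeros((n_bits, nz, ny, nx), dtype=np.float32)
    egr1 = np.zeros((nz, ny, nx), dtype=np.float32)
    nuclear = np.zeros((nz, ny, nx), dtype=np.float32)
    cell_labels = np.zeros((nz, ny, nx), dtype=np.int32)
    pixel = np.array([pz, py, px])

    rows = []
    for cid, (c, li) in enumerate(zip(centers, labels), start=1):
        receptor = receptors[li]
        code = codebook.code_of(receptor)
        # bounding box in voxels
        vlo = np.maximum(np.floor((c - r) / pixel).astype(int), 0)
        vhi = np.minimum(np.ceil((c + r) / pixel).astype(int) + 1, [nz, ny, nx])
        zz, yy, xx = np.meshgrid(
            *(np.arange(vlo[a], vhi[a]) for a in range(3)), indexing="ij"
        )
        pos = np.stack([zz, yy, xx], axis=-1) * pixel + pixel / 2
        d2 = ((pos - c) ** 2).sum(axis=-1)
        inside = d2 <= r * r
        if not inside.any():
            continue
        profile = np.clip(1.0 - d2 / (r * r), 0.0, None)
        texture = rng.gamma(shape=4.0, scale=0.25, size=profile.shape)
        soma = (config.signal_amplitude * profile * texture).astype(np.float32)
        gains = rng.uniform(0.7, 1.3, size=len(code))
        sl = tuple(slice(vlo[a], vhi[a]) for a in range(3))
        for g, b in zip(gains, code):
            bits[b][sl][inside] += (g * soma)[inside]
        cell_labels[sl][inside] = cid

        # nuclear blob
        nuclear[sl] += (
            60.0 * np.exp(-d2 / (2 * config.nuclear_sigma_um**2))
        ).astype(np.float32)

        # Egr1 spots
        responder = rng.random() < response_fractions[receptor]
        if responder:
            count = 6 + rng.poisson(config.egr1_lambda_high - 6.0)
        else:
            count = rng.poisson(config.egr1_lambda_low)
        placed = _spot_positions(rng, c, r * 0.85, count, min_sep=1.6)
        for p in placed:
            _render_gaussian(egr1, p, config.egr1_spot_sigma_um,
                             config.egr1_spot_amplitude * rng.uniform(0.8, 1.2), pixel)
        rows.append(
            {
                "cell_id": cid,
                "receptor": receptor,
                "z": c[0], "y": c[1], "x": c[2],
                "egr1_count": len(placed),
                "responder": bool(responder),
            }
        )

    for chan in (bits, egr1[None], nuclear[None]):
        chan += config.background_level
        chan += rng.normal(0.0, config.noise_sd, size=chan.shape).astype(np.float32)
        np.clip(chan, 0.0, None, out=chan)

    stack = ReadoutStack(bits=bits, egr1=egr1, nuclear=nuclear,
                         pixel_size_um=config.pixel_size_um)
    truth = MoeSectionTruth(
        cells=pd.DataFrame(rows),
        cell_labels=cell_labels,
        proportions=proportions,
        response_fractions=response_fractions,
    )
    return stack, truth


def _spot_positions(rng, center, radius, count, min_sep, max_tries=400):
    placed: list[np.ndarray] = []
    tries = 0
    sep = min_sep
    while len(placed) < count:
        tries += 1
        if tries > max_tries:
            sep *= 0.8  # soma too crowded at this spacing; relax gradually
            tries = 0
            if sep < 0.2:
                break
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = center + u * radius * rng.random() ** (1 / 3)
        if all(np.linalg.norm(p - q) >= sep for q in placed):
            placed.append(p)
    return placed


def _render_gaussian(vol, center_um, sigma_um, amplitude, pixel):
    half = 3.0 * sigma_um
    vlo = np.maximum(np.floor((center_um - half) / pixel).astype(int), 0)
    vhi = np.minimum(np.ceil((center_um + half) / pixel).astype(int) + 1, vol.shape)
    if np.any(vhi <= vlo):
        return
    zz, yy, xx = np.meshgrid(*(np.arange(vlo[a], vhi[a]) for a in range(3)), indexing="ij")
    pos = np.stack([zz, yy, xx], axis=-1) * pixel + pixel / 2
    d2 = ((pos - center_um) ** 2).sum(axis=-1)
    sl = tuple(slice(vlo[a], vhi[a]) for a in range(3))
    vol[sl] += (amplitude * np.exp(-d2 / (2 * sigma_um**2))).astype(np.float32)


# ---------------------------------------------------------------------------
# Atlas-scale MOE cell tables (ring zones + basal-apical gradient)
# ---------------------------------------------------------------------------

def simulate_moe_cells(
    config: SyntheticConfig,
    n_receptors: int | None = None,
    n_sections: int = 4,
    cells_per_or_per_section: float = 20.0,
    n_animals: int = 1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell tables with concentric ring zones and a depth sub-gradient.

    Each OR is planted on a ring of radius evenly spaced between
    ``ring_radius_min_um`` and ``ring_radius_max_um`` (width
    ``ring_width_um``), with a per-OR depth offset in (0, 1) across the
    epithelium thickness.  ``n_unusual`` additional ORs are confined to a
    compact off-ring patch detached (> 200 um) from every ring.

    Returns ``(cells, truth)``: cells has columns cell_id, animal, section,
    receptor, x, y (section plane, um), depth_um; truth is per-receptor with
    ring_radius_um (NaN for unusual), depth_offset, unusual flag and the
    planted cp order.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_rec = config.n_receptors if n_receptors is None else n_receptors
    receptors = _receptor_ids(n_rec)
    unusual = [f"OlfrU{i:02d}" for i in range(config.n_unusual)]

    radii = np.linspace(config.ring_radius_min_um, config.ring_radius_max_um, n_rec)
    d0, d1 = config.depth_offset_range
    depth_offsets = rng.uniform(d0, d1, size=n_rec + config.n_unusual)

    truth = pd.DataFrame(
        {
            "receptor": receptors + unusual,
            "ring_radius_um": np.concatenate([radii, np.full(config.n_unusual, np.nan)]),
            "depth_offset": depth_offsets,
            "unusual": [False] * n_rec + [True] * config.n_unusual,
        }
    ).set_index("receptor")
    truth["cp_rank"] = truth["ring_radius_um"].rank() - 1  # NaN for unusual

    T = config.epithelium_thickness_um
    ux, uy = config.unusual_zone_center_um
    rows = []
    cid = 0
    for animal in range(n_animals):
        for section in range(n_sections):
            for rec in truth.index:
                n_c = rng.poisson(cells_per_or_per_section)
                if n_c == 0:
                    continue
                if truth.loc[rec, "unusual"]:
                    # truncate at 3 sigma so the patch stays detached
                    sig = config.unusual_zone_sigma_um
                    x = ux + np.clip(rng.normal(0, sig, n_c), -3 * sig, 3 * sig)
                    y = uy + np.clip(rng.normal(0, sig, n_c), -3 * sig, 3 * sig)
                else:
                    w = config.ring_width_um
                    rr = truth.loc[rec, "ring_radius_um"] + np.clip(
                        rng.normal(0, w, n_c), -2.5 * w, 2.5 * w
                    )
                    th = rng.uniform(0, 2 * np.pi, n_c)
                    x = rr * np.cos(th)
                    y = rr * np.sin(th)
                depth = np.clip(
                    rng.normal(truth.loc[rec, "depth_offset"], config.depth_sigma, n_c), 0, 1
                ) * T
                for k in range(n_c):
                    rows.append((cid + k, animal, section, rec, x[k], y[k], depth[k]))
                cid += n_c
    cells = pd.DataFrame(
        rows, columns=["cell_id", "animal", "section", "receptor", "x", "y", "depth_um"]
    )
    return cells, truth


# ---------------------------------------------------------------------------
# Olfactory bulb maps and serial-section molecule tables
# ---------------------------------------------------------------------------

def simulate_ob_maps(
    truth: pd.DataFrame,
    config: SyntheticConfig,
    n_animals: int = 2,
    seed: int | None = None,
    jitter_um: float | None = None,
) -> pd.DataFrame:
    """Planted 3D glomerular projection maps tied to the MOE ground truth.

    The DV (y) position of each OR's glomeruli is a monotone function of its
    planted cp order; the AP (z) position is monotone in its basal-apical
    depth offset.  Each OR gets one medial and one lateral glomerulus per
    hemisphere, mirror-symmetric about the midline, jittered isotropically.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    jit = config.glomerulus_jitter_um if jitter_um is None else jitter_um
    ez, ey, ex = config.ob_extent_um
    mid = ex / 2
    main = truth[~truth["unusual"]]
    cp = main["cp_rank"] / max(len(main) - 1, 1)
    ba = (main["depth_offset"] - main["depth_offset"].min()) / max(
        main["depth_offset"].max() - main["depth_offset"].min(), 1e-9
    )
    y0 = 0.1 * ey + 0.8 * ey * cp
    z0 = 0.1 * ez + 0.8 * ez * ba
    offsets = {"medial": 400.0, "lateral": 1200.0}
    rows = []
    for animal in range(n_animals):
        for rec in main.index:
            for hemi, sign in (("left", -1), ("right", +1)):
                for side, off in offsets.items():
                    p = np.array([z0[rec], y0[rec], mid + sign * off])
                    p = p + rng.normal(0, jit, 3)
                    rows.append(
                        {
                            "receptor": rec, "animal": animal, "hemisphere": hemi,
                            "side": side, "x": p[2], "y": p[1], "z": p[0],
                            "count": config.dominant_count, "tier": "truth",
                        }
                    )
    return pd.DataFrame(rows)


def simulate_ob_series(
    config: SyntheticConfig,
    codebook: Codebook,
    seed: int | None = None,
    n_glomeruli: int = 40,
    section_shape: tuple[int, int] = (256, 384),
    mask_pixel_um: float = 8.0,
    half_panel_alternating: bool = False,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Per-section molecule tables plus glomerulus label masks.

    Glomeruli are non-overlapping circles in each section; each carries
    Poisson(``dominant_count``) molecules of its dominant OR plus
    Poisson(``background_rate``) stray molecules of random other ORs.  With
    ``half_panel_alternating`` odd sections only carry molecules of the
    second half of the receptor panel and even sections the first half
    (emulating split probe pools).

    Returns ``(molecules, masks, glomeruli)``: molecules has section, x, y
    (um within section), z (um within stack), receptor, brightness;
    ``masks`` is (n_sections, H, W) int labels; ``glomeruli`` is the truth
    table (glomerulus id, section, center, dominant receptor, planted count).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    receptors = codebook.receptors
    H, W = section_shape
    ext_y, ext_x = H * mask_pixel_um, W * mask_pixel_um
    gr = config.glomerulus_radius_um
    n_sections = config.n_sections

    glom_rows = []
    mol_rows = []
    masks = np.zeros((n_sections, H, W), dtype=np.int32)
    gid = 0
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    half = len(receptors) // 2
    for s in range(n_sections):
        if half_panel_alternating:
            panel = receptors[:half] if s % 2 == 0 else receptors[half:]
        else:
            panel = receptors
        centers: list[np.ndarray] = []
        tries = 0
        per_section = max(1, n_glomeruli // n_sections)
        while len(centers) < per_section and tries < 5000:
            tries += 1
            c = np.array([rng.uniform(gr, ext_y - gr), rng.uniform(gr, ext_x - gr)])
            if all(np.linalg.norm(c - p) >= 2.2 * gr for p in centers):
                centers.append(c)
        if len(centers) < per_section:
            raise RuntimeError("could not place glomeruli without overlap")
        for c in centers:
            gid += 1
            dom = panel[rng.integers(len(panel))]
            d2 = (yy * mask_pixel_um - c[0]) ** 2 + (xx * mask_pixel_um - c[1]) ** 2
            masks[s][d2 <= gr * gr] = gid
            n_dom = rng.poisson(config.dominant_count)
            n_bg = rng.poisson(config.background_rate)
            glom_rows.append(
                {
                    "glomerulus": gid, "section": s, "cy": c[0], "cx": c[1],
                    "dominant_receptor": dom, "planted_count": n_dom,
                }
            )
            for k in range(n_dom + n_bg):
                rec = dom if k < n_dom else panel[rng.integers(len(panel))]
                rho = gr * np.sqrt(rng.random())
                th = rng.uniform(0, 2 * np.pi)
                mol_rows.append(
                    {
                        "section": s,
                        "y": c[0] + rho * np.sin(th),
                        "x": c[1] + rho * np.cos(th),
                        "z": s * config.section_z_um + rng.uniform(0, config.section_z_um),
                        "receptor": rec,
                        "brightness": rng.lognormal(2.0, 0.3),
                    }
                )
    molecules = pd.DataFrame(mol_rows)
    glomeruli = pd.DataFrame(glom_rows)
    return molecules, masks, glomeruli


def rasterize_spots(
    positions_um: np.ndarray,
    bit_sets: list[tuple[int, ...]],
    brightnesses: np.ndarray,
    n_bits: int,
    shape: tuple[int, int, int],
    pixel_size_um: tuple[float, float, float],
    sigma_um: float = 0.3,
    background: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Render molecules as Gaussian spots into per-bit 3D images."""
    rng = np.random.default_rng(seed)
    vols = np.zeros((n_bits,) + shape, dtype=np.float32)
    pixel = np.asarray(pixel_size_um)
    for p, bset, amp in zip(positions_um, bit_sets, brightnesses):
        for b in bset:
            _render_gaussian(vols[b], np.asarray(p, dtype=float), sigma_um, amp, pixel)
    vols += background
    vols += rng.normal(0, noise_sd, vols.shape).astype(np.float32)
    np.clip(vols, 0, None, out=vols)
    return vols


# ---------------------------------------------------------------------------
# Known deformations for registration testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothField:
    """Bandlimited sinusoidal displacement field d(p) in um/px units."""

    amplitude: tuple[float, float] = (0.0, 0.0)   # (dy, dx)
    period: tuple[float, float] = (400.0, 400.0)
    phase: tuple[float, float] = (0.0, 0.0)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        y, x = pts[..., 0], pts[..., 1]
        ay, ax = self.amplitude
        py_, px_ = self.period
        fy, fx = self.phase
        dy = ay * np.sin(2 * np.pi * x / px_ + fy)
        dx = ax * np.sin(2 * np.pi * y / py_ + fx)
        return np.stack([dy, dx], axis=-1)


def deform_points(pts: np.ndarray, angle_deg: float, translation, field: SmoothField,
                  center=(0.0, 0.0)) -> np.ndarray:
    """Forward map q = R(p + d(p) - c) + c + t (rigid after smooth)."""
    pts = np.asarray(pts, dtype=float)
    c = np.asarray(center, dtype=float)
    t = np.asarray(translation, dtype=float)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = pts + field(pts)
    return (moved - c) @ rot.T + c + t


def invert_deformation(q: np.ndarray, angle_deg: float, translation, field: SmoothField,
                       center=(0.0, 0.0), n_iter: int = 60, tol: float = 1e-9) -> np.ndarray:
    """Invert the forward map by fixed-point iteration (field is small)."""
    q = np.asarray(q, dtype=float)
    c = np.asarray(center, dtype=float)
    t = np.asarray(translation, dtype=float)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    base = (q - c - t) @ rot + c  # rigid inverse
    p = base.copy()
    for _ in range(n_iter):
        new = base - field(p)
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return p


def apply_known_deformation(
    sections: list[np.ndarray],
    rigid_params: list[tuple[float, tuple[float, float]]],
    field_params: list[SmoothField] | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[dict]]:
    """Deform each section image by rigid-after-smooth with known truth.

    ``rigid_params[i]`` is (angle_deg, (ty, tx)) in pixels; displacement
    amplitudes beyond half the section extent are rejected.  Returns
    deformed images and per-section truth dicts holding the parameters and
    callable inverse.
    """
    from scipy import ndimage as ndi

    if field_params is None:
        field_params = [SmoothField() for _ in sections]
    out_imgs, out_truth = [], []
    for img, (angle, t), fld in zip(sections, rigid_params, field_params):
        h, w = img.shape
        if max(abs(np.asarray(fld.amplitude)).max(), np.abs(t).max()) > min(h, w) / 2:
            raise ValueError("displacement exceeds half the section extent")
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        grid = np.stack([yy, xx], axis=-1).astype(float)
        src = invert_deformation(grid.reshape(-1, 2), angle, t, fld, center=center)
        src = src.reshape(h, w, 2)
        warped = ndi.map_coordinates(
            img.astype(float), [src[..., 0], src[..., 1]], order=1, mode="constant"
        )
        out_imgs.append(warped)
        out_truth.append(
            {"angle_deg": angle, "translation": tuple(np.asarray(t, dtype=float)),
             "field": fld, "center": center}
        )
    return out_imgs, out_truth


def simulate_nuclei_image(
    shape: tuple[int, int] = (512, 512),
    n_blobs: int = 600,
    sigma_px: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """A nuclei-like 2D image: random Gaussian blobs on low background."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    h, w = shape
    ys = rng.uniform(0, h, n_blobs)
    xs = rng.uniform(0, w, n_blobs)
    amps = rng.uniform(0.5, 1.5, n_blobs)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    half = int(4 * sigma_px)
    for y0, x0, a in zip(ys, xs, amps):
        iy, ix = int(y0), int(x0)
        sl = (slice(max(iy - half, 0), min(iy + half + 1, h)),
              slice(max(ix - half, 0), min(ix + half + 1, w)))
        d2 = (yy[sl] - y0) ** 2 + (xx[sl] - x0) ** 2
        img[sl] += a * np.exp(-d2 / (2 * sigma_px**2))
    img += rng.normal(0, 0.02, shape)
    return img


# ---------------------------------------------------------------------------
# scRNAseq-like expression and Egr1 response tables
# ---------------------------------------------------------------------------

def simulate_scrnaseq(
    n_types: int = 50,
    n_genes: int = 100,
    gradient_fraction: float = 0.3,
    noise: float = 0.1,
    seed: int = 0,
    coords: np.ndarray | None = None,
    per_cell: bool = False,
    cells_per_type: int = 50,
):
    """OSN-type x gene expression with a planted fraction of graded genes.

    A ``gradient_fraction`` of genes have mean expression monotone in the
    type's planted coordinate (slope sign random); the rest are exchangeable
    across types.  Returns ``(matrix, truth)`` where matrix is a DataFrame
    (types x genes) and truth holds the coordinate, per-gene gradient flag
    and slope.  With ``per_cell`` a third element is returned: a cell-level
    DataFrame with Poisson counts whose per-type averages converge to the
    type means.
    """
    if not 0.0 <= gradient_fraction <= 1.0:
        raise ValueError("gradient_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    types = _receptor_ids(n_types)
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    coord = rng.uniform(0, 1, n_types) if coords is None else np.asarray(coords, dtype=float)
    n_grad = int(round(gradient_fraction * n_genes))
    is_grad = np.zeros(n_genes, dtype=bool)
    is_grad[:n_grad] = True
    base = rng.uniform(2.0, 10.0, n_genes)
    slope = np.where(
        is_grad, rng.choice([-1.0, 1.0], n_genes) * rng.uniform(0.8, 1.6, n_genes), 0.0
    )
    mean = base[None, :] * (1.0 + slope[None, :] * (coord[:, None] - 0.5))
    mean = np.clip(mean, 0.05, None)
    mat = mean * (1.0 + noise * rng.normal(size=mean.shape))
    mat = np.clip(mat, 0.0, None)
    matrix = pd.DataFrame(mat, index=types, columns=genes)
    truth = {
        "coord": pd.Series(coord, index=types),
        "gradient": pd.Series(is_grad, index=genes),
        "slope": pd.Series(slope, index=genes),
    }
    if not per_cell:
        return matrix, truth
    cells = []
    for ti, t in enumerate(types):
        counts = rng.poisson(np.maximum(mean[ti], 0.0), size=(cells_per_type, n_genes))
        df = pd.DataFrame(counts, columns=genes)
        df.insert(0, "type", t)
        cells.append(df)
    return matrix, truth, pd.concat(cells, ignore_index=True)


def simulate_egr1_cells(
    receptors: list[str],
    conditions: list[str],
    planted_fractions: pd.DataFrame,
    cells_per_or: int = 100,
    n_animals: int = 2,
    lambda_high: float = 9.0,
    lambda_low: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell Egr1 counts with planted per-OR x cue response fractions.

    ``planted_fractions`` is receptors x conditions in [0, 1].  Responders
    draw 6 + Poisson(lambda_high - 6) transcripts (always above the >5
    threshold); non-responders draw Poisson(lambda_low).
    """
    rng = np.random.default_rng(seed)
    if ((planted_fractions.values < 0) | (planted_fractions.values > 1)).any():
        raise ValueError("response fractions must be in [0, 1]")
    rows = []
    per_animal = max(1, cells_per_or // n_animals)
    for cond in conditions:
        for rec in receptors:
            f = float(planted_fractions.loc[rec, cond])
            for animal in range(n_animals):
                resp = rng.random(per_animal) < f
                counts = np.where(
                    resp,
                    6 + rng.poisson(max(lambda_high - 6.0, 0.0), per_animal),
                    rng.poisson(lambda_low, per_animal),
                )
                for c, is_r in zip(counts, resp):
                    rows.append((rec, cond, animal, int(c), bool(is_r)))
    return pd.DataFrame(
        rows, columns=["receptor", "condition", "animal", "egr1_count", "responder"]
    )
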