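"""Seeded synthetic phantoms emulating an OCT tissue-screening run.

The generators in this module stand in for the physical instrument: a webcam
photographing a culture well, an OCT scanner recording a volume of B-scans of
a retinal explant resting above its supporting membrane, a Z-motor sweep used
to find the optimal imaging depth, and a whole screen of treated/untreated
samples. Every generator returns its output together with exact ground truth
so downstream detection, segmentation, morphometry and QC code can be tested
without any acquired data.

Conventions
-----------
* Well images: 2-D uint8 grayscale, row = y, column = x, mm origin at the
  top-left corner, pixel centers at ``(index + 0.5) * mm_per_pixel``.
* OCT volumes: uint16 arrays of shape ``(n_bscans, axial_px, n_alines)``;
  depth increases downward within a B-scan.
* All randomness flows through one ``numpy.random.default_rng(seed)`` per
  call; identical (spec, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .depth_sweep import DepthStack
from .errors import ParameterError

# Intensity model constants (fractions of full scale).
WELL_BACKGROUND = 0.25
WELL_TISSUE = 0.65
WELL_NOISE_SD = 0.02
OCT_BACKGROUND = 0.05
OCT_TISSUE_REFLECTANCE = 0.50
OCT_ADDITIVE_NOISE_FRAC = 0.05  # additive noise sd = this * speckle_sd
UINT16_MAX = 65535


@dataclass
class PhantomSpec:
    """Full generative description of a synthetic well / volume / sweep.

    Defaults reproduce the acquisition geometry of the screening instrument:
    a 30x30 mm well field of view for the webcam, a 6x6 mm OCT field sampled
    at 500 A-lines x 2 repeats x 500 B-scans, and artifact levels (speckle,
    reflectance drift, saturated specular columns) representative of explant
    imaging over a bright supporting membrane.
    """

    image_size_px: tuple[int, int] = (600, 600)
    well_fov_mm: float = 30.0
    oct_fov_mm: float = 6.0
    n_alines: int = 500
    n_bscans: int = 500
    n_repeats: int = 2
    axial_px: int = 512
    dz_um: float = 2.0
    tissue_center_mm: tuple[float, float] = (15.0, 15.0)
    tissue_radii_mm: tuple[float, float] = (4.0, 3.0)
    thickness_profile: str = "uniform"
    profile_params: dict = field(
        default_factory=lambda: {"thickness_um": 180.0}
    )
    membrane_thickness_um: float = 10.0
    membrane_brightness: float = 0.9
    membrane_gap_um: float = 20.0
    membrane_top_um: Optional[float] = None  # default: 70% of the axial range
    speckle_sd: float = 0.3
    reflectance_drift: float = 0.2
    specular_column_rate: float = 0.02
    occupancy: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_size_px
        if rows <= 0 or cols <= 0:
            raise ParameterError("image_size_px must be positive")
        for name in ("well_fov_mm", "oct_fov_mm", "dz_um",
                     "membrane_thickness_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.n_alines < 1 or self.n_bscans < 1 or self.axial_px < 1:
            raise ParameterError("sampling grid sizes must be >= 1")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")
        if min(self.tissue_radii_mm) <= 0:
            raise ParameterError("tissue_radii_mm must be strictly positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ParameterError("occupancy must lie in [0, 1]")
        if not 0.0 <= self.specular_column_rate <= 1.0:
            raise ParameterError("specular_column_rate must lie in [0, 1]")
        if self.speckle_sd < 0 or self.reflectance_drift < 0:
            raise ParameterError("noise levels must be non-negative")
        if self.thickness_profile not in ("uniform", "dome", "bimodal"):
            raise ParameterError(
                f"unknown thickness_profile {self.thickness_profile!r}"
            )
        if self.membrane_gap_um < 0:
            raise ParameterError("membrane_gap_um must be non-negative")

    # -- derived geometry ---------------------------------------------------

    @property
    def mm_per_pixel(self) -> tuple[float, float]:
        """(row, col) well-image scale in mm per pixel."""
        rows, cols = self.image_size_px
        return self.well_fov_mm / rows, self.well_fov_mm / cols

    def membrane_top_px(self) -> int:
        depth_um = self.axial_px * self.dz_um
        top = self.membrane_top_um if self.membrane_top_um is not None \
            else 0.7 * depth_um
        return int(round(top / self.dz_um))

    def max_profile_um(self) -> float:
        p = self.profile_params
        if self.thickness_profile == "uniform":
            return float(p["thickness_um"])
        if self.thickness_profile == "dome":
            return float(max(p["peak_um"], p["edge_um"]))
        return float(max(p["left_um"], p["right_um"]))


@dataclass
class GroundTruth:
    """Exact ground truth travelling with every phantom output.

    ``analytic`` is True when area/volume/central thickness are closed-form
    values (uniform or dome profile with the footprint fully inside the OCT
    field); otherwise they are exact reductions of the discrete thickness
    map.
    """

    has_tissue: bool = False
    bbox_px: Optional[tuple[int, int, int, int]] = None  # x0, y0, x1, y1
    centroid_mm: Optional[tuple[float, float]] = None
    mask: Optional[np.ndarray] = None
    thickness_map_um: Optional[np.ndarray] = None
    area_mm2: Optional[float] = None
    volume_mm3: Optional[float] = None
    central_thickness_um: Optional[float] = None
    optimal_z_index: Optional[int] = None
    analytic: bool = False


# ---------------------------------------------------------------------------
# Well images (webcam stage)
# ---------------------------------------------------------------------------

def make_well_image(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Render a plate-view well image as the webcam would capture it.

    An occupied well (probability ``spec.occupancy``) contains one bright
    elliptical explant on a darker uniform background with additive Gaussian
    noise; an empty well is background only. Ground truth carries the exact
    half-open bounding box (pixels) and centroid (mm) of the rasterized
    ellipse.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows, cols = spec.image_size_px
    has_tissue = bool(rng.random() < spec.occupancy)

    img = np.full((rows, cols), WELL_BACKGROUND, dtype=np.float64)
    gt = GroundTruth(has_tissue=has_tissue)
    if has_tissue:
        sy, sx = spec.mm_per_pixel
        y_mm = (np.arange(rows) + 0.5) * sy
        x_mm = (np.arange(cols) + 0.5) * sx
        cx, cy = spec.tissue_center_mm
        a, b = spec.tissue_radii_mm
        footprint = (((x_mm[None, :] - cx) / a) ** 2
                     + ((y_mm[:, None] - cy) / b) ** 2) <= 1.0
        if not footprint.any():
            raise ParameterError("tissue ellipse lies outside the well image")
        img[footprint] = WELL_TISSUE
        rr, cc = np.nonzero(footprint)
        gt.bbox_px = (int(cc.min()), int(rr.min()),
                      int(cc.max()) + 1, int(rr.max()) + 1)
        gt.centroid_mm = (float(cx), float(cy))
        gt.mask = footprint.astype(np.uint8)

    img += rng.normal(0.0, WELL_NOISE_SD, size=img.shape)
    img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img, gt


# ---------------------------------------------------------------------------
# OCT volumes
# ---------------------------------------------------------------------------

def _profile_thickness_um(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (n_bscans, n_alines) thickness in um and footprint mask."""
    dx = spec.oct_fov_mm / spec.n_alines
    dy = spec.oct_fov_mm / spec.n_bscans
    x_mm = (np.arange(spec.n_alines) + 0.5) * dx
    y_mm = (np.arange(spec.n_bscans) + 0.5) * dy
    cx = cy = spec.oct_fov_mm / 2.0
    a, b = spec.tissue_radii_mm
    rho2 = (((x_mm[None, :] - cx) / a) ** 2
            + ((y_mm[:, None] - cy) / b) ** 2)
    footprint = rho2 <= 1.0

    p = spec.profile_params
    t = np.zeros_like(rho2)
    if spec.thickness_profile == "uniform":
        t[footprint] = float(p["thickness_um"])
    elif spec.thickness_profile == "dome":
        peak, edge = float(p["peak_um"]), float(p["edge_um"])
        t[footprint] = edge + (peak - edge) * (1.0 - rho2[footprint])
    else:  # bimodal: left/right halves of the footprint
        left = x_mm[None, :] < cx
        t[footprint & left] = float(p["left_um"])
        t[footprint & ~left] = float(p["right_um"])
    return t, footprint


def _footprint_inside_fov(spec: PhantomSpec) -> bool:
    a, b = spec.tissue_radii_mm
    c = spec.oct_fov_mm / 2.0
    return a <= c and b <= c


def _analytic_readouts(spec: PhantomSpec) -> Optional[tuple[float, float, float]]:
    """Closed-form (area mm^2, volume mm^3, central thickness um), if available.

    For the dome profile t = edge + (peak-edge)(1-rho^2), thickness is
    uniformly distributed over [edge, peak] with respect to footprint area,
    so the median is (edge+peak)/2 and the mean of the upper half is
    (edge + 3*peak)/4.
    """
    if not _footprint_inside_fov(spec):
        return None
    a, b = spec.tissue_radii_mm
    area = np.pi * a * b
    p = spec.profile_params
    if spec.thickness_profile == "uniform":
        t0 = float(p["thickness_um"])
        return area, area * t0 * 1e-3, t0
    if spec.thickness_profile == "dome":
        peak, edge = float(p["peak_um"]), float(p["edge_um"])
        vol = area * 0.5 * (peak + edge) * 1e-3
        return area, vol, (edge + 3.0 * peak) / 4.0
    return None


def _map_readouts(t_map_um: np.ndarray, dx_um: float, dy_um: float
                  ) -> tuple[float, float, float]:
    """Exact reductions of a discrete thickness map (area, volume, central)."""
    support = t_map_um > 0
    area = float(support.sum()) * dx_um * dy_um * 1e-6
    vol = float(t_map_um.sum()) * dx_um * dy_um * 1e-9
    if not support.any():
        return area, vol, 0.0
    vals = t_map_um[support]
    med = float(np.median(vals))
    central = float(vals[vals >= med].mean())
    return area, vol, central


def _geometry(spec: PhantomSpec) -> dict:
    """Shared discrete geometry for volume and depth-stack rendering."""
    t_um, footprint = _profile_thickness_um(spec)
    n_vox = np.round(t_um / spec.dz_um).astype(np.int64)
    n_vox[~footprint] = 0
    mem_top = spec.membrane_top_px()
    mem_px = max(1, int(round(spec.membrane_thickness_um / spec.dz_um)))
    gap_px = int(round(spec.membrane_gap_um / spec.dz_um))
    z_bot = mem_top - gap_px  # tissue occupies [z_bot - n_vox, z_bot)
    if mem_top + mem_px > spec.axial_px:
        raise ParameterError("membrane does not fit in the axial range")
    if n_vox.max(initial=0) > z_bot:
        raise ParameterError(
            "thickness profile exceeds the axial range above the membrane"
        )
    return {
        "t_um": t_um, "footprint": footprint, "n_vox": n_vox,
        "mem_top": mem_top, "mem_px": mem_px, "z_bot": z_bot,
        "thickness_map_um": n_vox.astype(np.float64) * spec.dz_um,
    }


def _drift_field(spec: PhantomSpec, rng: np.random.Generator,
                 shape: tuple[int, int]) -> np.ndarray:
    """Smooth multiplicative reflectance-inhomogeneity field, 1 +- drift."""
    if spec.reflectance_drift == 0:
        return np.ones(shape)
    coarse = rng.standard_normal((6, 6))
    fine = ndimage.zoom(coarse, (shape[0] / 6.0, shape[1] / 6.0), order=3)
    fine = fine[: shape[0], : shape[1]]
    peak = np.abs(fine).max()
    if peak > 0:
        fine = fine / peak
    return 1.0 + spec.reflectance_drift * fine


def _render_bscan_float(spec: PhantomSpec, geo: dict, y: int,
                        drift_row: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """One noise-averaged B-scan as float in [0, 1] (no specular columns)."""
    axial, n_al = spec.axial_px, spec.n_alines
    base = np.full((axial, n_al), OCT_BACKGROUND, dtype=np.float64)
    n_vox = geo["n_vox"][y]
    z_bot = geo["z_bot"]
    cols = np.nonzero(n_vox > 0)[0]
    for c in cols:
        base[z_bot - n_vox[c]: z_bot, c] = (
            OCT_TISSUE_REFLECTANCE * drift_row[c]
        )
    base[geo["mem_top"]: geo["mem_top"] + geo["mem_px"], :] = \
        spec.membrane_brightness

    if spec.speckle_sd == 0:
        return np.clip(base, 0.0, 1.0)
    acc = np.zeros_like(base)
    sd = spec.speckle_sd
    for _ in range(spec.n_repeats):
        speckle = np.exp(rng.normal(-0.5 * sd * sd, sd, size=base.shape))
        additive = rng.normal(0.0, OCT_ADDITIVE_NOISE_FRAC * sd,
                              size=base.shape)
        acc += base * speckle + additive
    return np.clip(acc / spec.n_repeats, 0.0, 1.0)


def make_oct_volume(spec: PhantomSpec, seed: int
                    ) -> tuple[np.ndarray, GroundTruth]:
    """Render a full OCT volume of a curved tissue slab over its membrane.

    Returns a uint16 array of shape ``(n_bscans, axial_px, n_alines)`` and a
    :class:`GroundTruth` whose binary mask marks tissue voxels only (never
    the membrane). ``n_repeats`` noisy realizations are averaged into each
    stored B-scan; a seeded fraction ``specular_column_rate`` of (B-scan,
    A-line) columns is fully saturated afterwards, emulating specular
    reflections.
    """
    spec.validate()
    geo = _geometry(spec)
    rng = np.random.default_rng(seed)
    drift = _drift_field(spec, rng, (spec.n_bscans, spec.n_alines))
    specular = rng.random((spec.n_bscans, spec.n_alines)) < \
        spec.specular_column_rate

    vol = np.empty((spec.n_bscans, spec.axial_px, spec.n_alines),
                   dtype=np.uint16)
    mask = np.zeros_like(vol, dtype=np.uint8)
    z_bot = geo["z_bot"]
    for y in range(spec.n_bscans):
        frame = _render_bscan_float(spec, geo, y, drift[y], rng)
        frame[:, specular[y]] = 1.0
        vol[y] = np.round(frame * UINT16_MAX).astype(np.uint16)
        n_vox = geo["n_vox"][y]
        for c in np.nonzero(n_vox > 0)[0]:
            mask[y, z_bot - n_vox[c]: z_bot, c] = 1

    dx_um = spec.oct_fov_mm * 1000.0 / spec.n_alines
    dy_um = spec.oct_fov_mm * 1000.0 / spec.n_bscans
    closed = _analytic_readouts(spec)
    area, volume, central = closed if closed is not None else \
        _map_readouts(geo["thickness_map_um"], dx_um, dy_um)
    gt = GroundTruth(
        has_tissue=bool(geo["footprint"].any()),
        mask=mask,
        thickness_map_um=geo["thickness_map_um"],
        area_mm2=area,
        volume_mm3=volume,
        central_thickness_um=central,
        analytic=closed is not None,
    )
    return vol, gt


def make_ground_truth(spec: PhantomSpec, with_mask: bool = False) -> GroundTruth:
    """Ground truth for a volume without rendering intensities (fast path)."""
    spec.validate()
    geo = _geometry(spec)
    dx_um = spec.oct_fov_mm * 1000.0 / spec.n_alines
    dy_um = spec.oct_fov_mm * 1000.0 / spec.n_bscans
    closed = _analytic_readouts(spec)
    area, volume, central = closed if closed is not None else \
        _map_readouts(geo["thickness_map_um"], dx_um, dy_um)
    mask = None
    if with_mask:
        mask = np.zeros((spec.n_bscans, spec.axial_px, spec.n_alines),
                        dtype=np.uint8)
        z_bot = geo["z_bot"]
        for y in range(spec.n_bscans):
            n_vox = geo["n_vox"][y]
            for c in np.nonzero(n_vox > 0)[0]:
                mask[y, z_bot - n_vox[c]: z_bot, c] = 1
    return GroundTruth(
        has_tissue=bool(geo["footprint"].any()),
        mask=mask,
        thickness_map_um=geo["thickness_map_um"],
        area_mm2=area, volume_mm3=volume, central_thickness_um=central,
        analytic=closed is not None,
    )


# ---------------------------------------------------------------------------
# Depth-sweep stacks (Z-motor M-B scan)
# ---------------------------------------------------------------------------

def make_depth_stack(spec: PhantomSpec, n_positions: int, optimal_index: int,
                     seed: int) -> tuple[DepthStack, GroundTruth]:
    """Simulate the Z-motor sweep: one B-scan per candidate stage position.

    A single (possibly noisy) B-scan through the volume center is rendered
    once and rescaled by a triangular brightness profile peaking at
    ``optimal_index``, so mean frame intensity is strictly unimodal with its
    maximum at the optimal position by construction.
    """
    spec.validate()
    if n_positions < 1:
        raise ParameterError("n_positions must be >= 1")
    if not 0 <= optimal_index < n_positions:
        raise ParameterError("optimal_index outside [0, n_positions)")
    geo = _geometry(spec)
    rng = np.random.default_rng(seed)
    drift = _drift_field(spec, rng, (spec.n_bscans, spec.n_alines))
    mid = spec.n_bscans // 2
    base = _render_bscan_float(spec, geo, mid, drift[mid], rng)

    reach = max(optimal_index, n_positions - 1 - optimal_index, 1)
    idx = np.arange(n_positions)
    brightness = 1.0 - 0.7 * np.abs(idx - optimal_index) / reach
    frames = [
        np.round(np.clip(b * base, 0.0, 1.0) * UINT16_MAX).astype(np.uint16)
        for b in brightness
    ]
    positions = 10.0 * np.arange(n_positions, dtype=np.float64)
    stack = DepthStack(positions=positions, frames=frames)
    return stack, GroundTruth(has_tissue=True,
                              optimal_z_index=int(optimal_index))


# ---------------------------------------------------------------------------
# Whole-screen readout tables
# ---------------------------------------------------------------------------

def make_screen_dataset(
    n_negative: int,
    n_positive: int,
    baseline_mean_um: float = 191.8,
    baseline_sd_um: float = 11.5,
    negative_change_frac: float = -0.303,
    positive_change_frac: float = 0.30,
    repeat_sd: float = 0.4,
    n_repeats: int = 5,
    seed: int = 0,
    *,
    area_mean_mm2: float = 17.0,
    area_sd_mm2: float = 0.755,
    negative_area_change_frac: float = -0.20,
    positive_area_change_frac: float = 0.0,
    area_repeat_sd: float = 0.039,
    volume_repeat_sd: float = 0.005,
):
    """Simulate a two-group longitudinal screen as a tidy readout table.

    Emulates the validation design of the screening assay: a negative
    (vehicle) control group whose explants thin over ten days in culture and
    a positive treatment group that thickens. Sample-level true readouts are
    drawn from Normal(group mean, group SD) at each timepoint, with group
    means at day 10 equal to baseline x (1 + change_frac); each of
    ``n_repeats`` repeated measurements adds Normal(0, repeat SD) noise.
    Volume is the product of the thickness and area draws.

    Returns a pandas DataFrame with columns sample_id, group, timepoint,
    repetition, thickness_um, area_mm2, volume_mm3.
    """
    import pandas as pd

    if n_negative <= 0 or n_positive <= 0:
        raise ParameterError("group sizes must be positive")
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    groups = [
        ("negative", n_negative, negative_change_frac,
         negative_area_change_frac),
        ("positive", n_positive, positive_change_frac,
         positive_area_change_frac),
    ]
    for group, n, cf_t, cf_a in groups:
        for i in range(n):
            sample_id = f"{group[:3]}{i + 1:03d}"
            for timepoint, mt, ma in (
                ("baseline", baseline_mean_um, area_mean_mm2),
                ("day10", baseline_mean_um * (1 + cf_t),
                 area_mean_mm2 * (1 + cf_a)),
            ):
                t_true = rng.normal(mt, baseline_sd_um)
                a_true = rng.normal(ma, area_sd_mm2)
                v_true = t_true * 1e-3 * a_true
                for rep in range(1, n_repeats + 1):
                    rows.append({
                        "sample_id": sample_id,
                        "group": group,
                        "timepoint": timepoint,
                        "repetition": rep,
                        "thickness_um": t_true + rng.normal(0, repeat_sd),
                        "area_mm2": a_true + rng.normal(0, area_repeat_sd),
                        "volume_mm3": v_true + rng.normal(0, volume_repeat_sd),
                    })
    return pd.DataFrame(rows)
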