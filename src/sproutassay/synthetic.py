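"""Ground-truthed synthetic chip images and metric tables.

Real acquisitions of the sprouting assay are two-channel confocal stacks of
a microfluidic chip in which an endothelial monolayer abuts a patterned
collagen gel and sprouts extend perpendicular to it, down a growth-factor
gradient.  No public image set exists for this assay, so every downstream
stage (projection, stitching, segmentation, metrics, QC, dose-response) is
exercised against this generator, which emulates the statistical structure
the assay assumes:

* a dense monolayer band at a fixed baseline y-position,
* sprouts as jittered polylines of F-actin signal extending in +y,
* nuclei as 3D Gaussian blobs spaced along each sprout,
* dose-dependent suppression of sprout extent following a four-parameter
  logistic (Hill) inhibition model,
* between-chip variability as truncated-normal noise on the expected
  migration distance, plus Poisson shot noise and Gaussian read noise on
  the rendered intensities.

The generator is phenomenological: it makes no attempt to model sprouting
dynamics, only the geometry and noise of the measured endpoints.  Every
render returns its ground truth so segmentation and metric accuracy can be
scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from sproutassay.imaging import ChipStack

__all__ = [
    "SproutingModelParams",
    "ChipGeometry",
    "ChipGroundTruth",
    "PlateLayout",
    "expected_response",
    "simulate_metric_table",
    "render_chip_stack",
    "generate_dose_response_dataset",
]

ROLES = ("max_control", "min_control", "test")

# rendering constants (µm unless noted)
_SPROUT_WIDTH_UM = 14.0      # F-actin tube full width
_NUCLEUS_SIGMA_UM = 4.0      # Gaussian blob sigma, lateral
_NUCLEUS_SIGMA_Z_UM = 5.0    # Gaussian blob sigma, axial
_MONOLAYER_NUCLEI_PER_100UM = 4.0
_BACKGROUND_LEVEL = 100.0    # camera offset, grey levels
_READ_NOISE_SD = 8.0         # grey levels


class SproutingModelParams(BaseModel):
    """Parameters of the dose-dependent sprouting model.

    The expected migration distance at inhibitor concentration ``c`` is

        E(c) = D0 * (1 - Imax * c^hill / (c^hill + ic50^hill))

    and per-chip distances scatter around E(c) with coefficient of
    variation ``cv_chip`` (normal, truncated at zero).

    Defaults describe an uninhibited control condition of the assay:
    250 µm mean sprout extent, full inhibition achievable, IC50 20 nM,
    unit Hill slope, 13% between-chip CV.
    """

    D0: float = Field(default=250.0, gt=0, description="control migration distance, µm")
    Imax: float = Field(default=1.0, ge=0, le=1, description="maximal fractional inhibition")
    ic50: float = Field(default=20.0, gt=0, description="half-maximal concentration, nM")
    hill: float = Field(default=1.0, gt=0, description="Hill slope")
    cv_chip: float = Field(default=0.13, ge=0, description="between-chip CV of distance")
    sprouts_per_chip: int = Field(default=6, ge=0)
    nuclei_spacing: float = Field(default=25.0, gt=0, description="µm between nuclei along a sprout")
    baseline_y: float = Field(default=400.0, ge=0, description="monolayer/gel boundary, µm")
    seed: int | None = None


@dataclass(frozen=True)
class ChipGeometry:
    """Image geometry of one chip site.

    The default is a desk-scale frame (512x512 px at 2.7 µm/px, 8 z-planes)
    that preserves the field of view of the full-resolution acquisition
    (2048x2048 px at 0.677 µm/px, 80 z-planes at 1 µm) while keeping
    renders fast; the full geometry is available by constructing this
    object explicitly.
    """

    shape_px: tuple[int, int] = (512, 512)  # (ny, nx)
    pixel_size: float = 2.7                 # µm/px
    n_z: int = 8
    z_step: float = 5.0                     # µm
    bit_depth: int = 16

    @property
    def height_um(self) -> float:
        return self.shape_px[0] * self.pixel_size

    @property
    def width_um(self) -> float:
        return self.shape_px[1] * self.pixel_size

    @property
    def depth_um(self) -> float:
        return self.n_z * self.z_step

    @classmethod
    def full_resolution(cls) -> "ChipGeometry":
        return cls(shape_px=(2048, 2048), pixel_size=0.677, n_z=80, z_step=1.0)


@dataclass
class ChipGroundTruth:
    """Exact generative state of one rendered chip.

    ``nuclei_positions`` holds every rendered nucleus (monolayer and
    sprout) as (x, y, z) in µm; ``true_distance`` is computed from the
    sprout nuclei with the same top-k rule the metrics module uses, so the
    render -> segment -> quantify round trip has a well-defined target.
    """

    nuclei_positions: np.ndarray            # (N, 3) µm
    sprout_paths: list[np.ndarray]          # each (M, 2) of (x, y) µm
    true_distance: float                    # µm
    true_area: float                        # µm², tube pixels beyond baseline
    true_nuclei_in_sprouts: int
    baseline_y: float
    sprout_nuclei: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of chips to compound, concentration and control role.

    ``chips`` rows are (chip_id, compound, concentration, role) with role
    one of max_control / min_control / test.
    """

    chips: tuple[tuple[str, str, float, str], ...]

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.chips]
        if len(set(ids)) != len(ids):
            raise ValueError("chip_ids must be unique")
        for cid, _, conc, role in self.chips:
            if conc < 0:
                raise ValueError(f"chip {cid}: negative concentration")
            if role not in ROLES:
                raise ValueError(f"chip {cid}: unknown role {role!r}")

    def __len__(self) -> int:
        return len(self.chips)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.chips, columns=["chip_id", "compound", "concentration_nM", "role"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        required = {"chip_id", "compound", "concentration_nM", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"layout is missing columns: {sorted(missing)}")
        rows = tuple(
            (str(r.chip_id), str(r.compound), float(r.concentration_nM), str(r.role))
            for r in df.itertuples()
        )
        return cls(rows)

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def control_plate(
        cls,
        n_max: int = 15,
        n_min: int = 14,
        compound: str = "sunitinib",
        min_conc: float = 50.0,
    ) -> "PlateLayout":
        """Max/min control design of the assay-characterisation plate:
        vehicle (0 nM) max-controls and saturating-inhibitor min-controls."""
        rows = [(f"max{i:02d}", compound, 0.0, "max_control") for i in range(n_max)]
        rows += [(f"min{i:02d}", compound, min_conc, "min_control") for i in range(n_min)]
        return cls(tuple(rows))

    @classmethod
    def dose_series(
        cls,
        concentrations: Sequence[float],
        n_per_conc: int,
        compound: str = "sunitinib",
    ) -> "PlateLayout":
        rows = []
        for c in concentrations:
            role = "max_control" if c == 0 else "test"
            for i in range(n_per_conc):
                rows.append((f"{compound}_{c:g}_{i:02d}", compound, float(c), role))
        return cls(tuple(rows))


def expected_response(c: float, p: SproutingModelParams) -> float:
    """Expected migration distance (µm) at inhibitor concentration ``c``.

    4PL inhibition: E(c) = D0 * (1 - Imax * c^h / (c^h + IC50^h)).
    Monotone non-increasing in c; E(0) = D0; E(inf) = D0 * (1 - Imax).
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if c == 0:
        return p.D0
    ch = c**p.hill
    return p.D0 * (1.0 - p.Imax * ch / (ch + p.ic50**p.hill))


def _sample_distance(
    expected: float, cv: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Truncated-normal per-chip distance: Normal(E, cv*E) clipped below 0."""
    if expected == 0 or cv == 0:
        return np.full(size, expected) if size else float(expected)
    sd = cv * expected
    a = (0.0 - expected) / sd  # lower truncation at 0 in standard units
    return truncnorm.rvs(a, np.inf, loc=expected, scale=sd, size=size, random_state=rng)


def _derived_metrics(
    distance: np.ndarray, p: SproutingModelParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Companion area / nuclei / length readouts consistent with a distance.

    Area and skeleton length scale with total sprout extent (distance times
    sprout count); nuclei count with extent over spacing.  Each carries its
    own multiplicative noise so the three readouts have distinct CVs, as
    observed on real plates where area and nuclei count are noisier than
    distance.
    """
    n = distance.size
    extent = distance * max(p.sprouts_per_chip, 1)
    area = extent * _SPROUT_WIDTH_UM * rng.lognormal(0.0, 0.15, n)
    nuclei = np.round(extent / p.nuclei_spacing * rng.lognormal(0.0, 0.15, n))
    length = extent * rng.lognormal(0.0, 0.05, n)
    return pd.DataFrame(
        {
            "total_area_um2": area,
            "nuclei_count": nuclei.astype(int),
            "length_um": length,
        }
    )


def simulate_metric_table(
    layout: PlateLayout,
    p: SproutingModelParams,
    replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a per-chip metric table for a plate layout.

    One row per chip per replicate, with the distance readout drawn from
    the truncated-normal noise model around the 4PL expectation and the
    companion readouts derived from it.  Group means converge to E(c) as
    replicates grow.
    """
    if len(layout) == 0:
        raise ValueError("empty plate layout")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    rows = []
    for rep in range(replicates):
        for cid, compound, conc, role in layout.chips:
            e = expected_response(conc, p)
            d = _sample_distance(e, p.cv_chip, rng)
            rows.append(
                {
                    "chip_id": cid if replicates == 1 else f"{cid}_r{rep}",
                    "compound": compound,
                    "concentration_nM": conc,
                    "role": role,
                    "distance_um": float(d),
                }
            )
    df = pd.DataFrame(rows)
    derived = _derived_metrics(df["distance_um"].to_numpy(), p, rng)
    df = pd.concat([df, derived], axis=1)
    df["n_sites"] = 2
    return df[
        [
            "chip_id", "compound", "concentration_nM", "role",
            "total_area_um2", "distance_um", "nuclei_count", "length_um",
            "n_sites",
        ]
    ]


def _sprout_polyline(
    x0: float,
    baseline_y: float,
    length: float,
    rng: np.random.Generator,
    step: float = 10.0,
    jitter_sd: float = 3.0,
) -> np.ndarray:
    """Jittered polyline marching in +y from the baseline, arc length ≈ length."""
    pts = [(x0, baseline_y)]
    travelled = 0.0
    x = x0
    while travelled < length:
        dy = min(step, length - travelled)
        x = x + rng.normal(0.0, jitter_sd * dy / step)
        pts.append((x, pts[-1][1] + dy))
        travelled += dy
    return np.asarray(pts)


def _resample_polyline(path: np.ndarray, spacing: float) -> np.ndarray:
    """Points at fixed arc-length spacing along a polyline."""
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total == 0:
        return path[:1]
    s = np.arange(spacing, total + 1e-9, spacing)
    x = np.interp(s, arclen, path[:, 0])
    y = np.interp(s, arclen, path[:, 1])
    return np.column_stack([x, y])


def _splat_2d(shape: tuple[int, int], xy_px: np.ndarray, amplitude: float) -> np.ndarray:
    """Bilinear splat of point masses onto a 2D grid (preserves sub-pixel centroids)."""
    img = np.zeros(shape)
    if xy_px.size == 0:
        return img
    cx, cy = xy_px[:, 0], xy_px[:, 1]
    x0 = np.floor(cx).astype(int)
    y0 = np.floor(cy).astype(int)
    fx, fy = cx - x0, cy - y0
    for dx, dy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xs, ys = x0 + dx, y0 + dy
        ok = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
        np.add.at(img, (ys[ok], xs[ok]), amplitude * w[ok])
    return img


def _z_profile(geom: ChipGeometry, center_um: float, sigma_um: float) -> np.ndarray:
    z = (np.arange(geom.n_z) + 0.5) * geom.z_step
    prof = np.exp(-0.5 * ((z - center_um) / sigma_um) ** 2)
    return prof / prof.max()


def render_chip_stack(
    p: SproutingModelParams,
    geometry: ChipGeometry | None = None,
    concentration: float = 0.0,
    seed: int | None = None,
    noise: bool = True,
    n_sprouts: int | None = None,
) -> tuple[ChipStack, ChipGroundTruth]:
    """Render one synthetic chip site and return it with its ground truth.

    The chip's migration distance is drawn from the noise model at the
    given concentration; individual sprout lengths scatter around it.
    ``noise=False`` disables shot and read noise (geometry noise — sprout
    jitter, nucleus placement — remains, controlled by the seed).

    Nuclei requested outside the frame are clipped with a warning.
    Deterministic given (params, geometry, concentration, seed).
    """
    geom = geometry or ChipGeometry()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    ny, nx = geom.shape_px
    px = geom.pixel_size

    n_spr = p.sprouts_per_chip if n_sprouts is None else n_sprouts
    chip_distance = float(
        _sample_distance(expected_response(concentration, p), p.cv_chip, rng)
    )

    # sprout geometry: start points spread over the central 80% of the width
    paths: list[np.ndarray] = []
    sprout_nuclei: list[np.ndarray] = []
    if n_spr > 0 and chip_distance > p.nuclei_spacing / 2:
        margin = 0.1 * geom.width_um
        x_starts = np.linspace(margin, geom.width_um - margin, n_spr)
        x_starts = x_starts + rng.normal(0.0, 0.02 * geom.width_um, n_spr)
        lengths = chip_distance * rng.normal(1.0, 0.10, n_spr).clip(0.3)
        for x0, li in zip(x_starts, lengths):
            path = _sprout_polyline(float(x0), p.baseline_y, float(li), rng)
            paths.append(path)
            beads = _resample_polyline(path, p.nuclei_spacing)
            if beads.size:
                lat = rng.normal(0.0, 1.0, beads.shape)
                z = rng.uniform(0.3, 0.7, len(beads)) * geom.depth_um
                sprout_nuclei.append(np.column_stack([beads + lat, z]))
    spr_nuc = (
        np.concatenate(sprout_nuclei) if sprout_nuclei else np.empty((0, 3))
    )

    # monolayer nuclei: dense band just below the baseline
    n_mono = int(_MONOLAYER_NUCLEI_PER_100UM * geom.width_um / 100.0 * 4)
    mono_x = rng.uniform(0, geom.width_um, n_mono)
    mono_y = rng.uniform(max(0.0, p.baseline_y - 60.0), p.baseline_y, n_mono)
    mono_z = rng.uniform(0.3, 0.7, n_mono) * geom.depth_um
    mono_nuc = np.column_stack([mono_x, mono_y, mono_z])

    nuclei = np.concatenate([mono_nuc, spr_nuc]) if spr_nuc.size else mono_nuc
    inside = (
        (nuclei[:, 0] >= 0) & (nuclei[:, 0] < geom.width_um)
        & (nuclei[:, 1] >= 0) & (nuclei[:, 1] < geom.height_um)
    )
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} nuclei outside the frame were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        nuclei = nuclei[inside]

    # --- F-actin channel -------------------------------------------------
    tube_sigma_px = _SPROUT_WIDTH_UM / 4.0 / px
    factin2d = np.zeros((ny, nx))
    for path in paths:
        dense = _resample_polyline(path, px / 2.0)
        factin2d += _splat_2d((ny, nx), dense / px, 1.0)
    factin2d = gaussian_filter(factin2d, tube_sigma_px)
    if factin2d.max() > 0:
        factin2d *= 3000.0 / factin2d.max()
    true_tube_mask = factin2d > 0.1 * factin2d.max() if factin2d.max() > 0 else factin2d > 0
    baseline_px = int(round(p.baseline_y / px))
    true_area = float(true_tube_mask[baseline_px:, :].sum()) * px**2

    # monolayer F-actin: textured band below the baseline
    mono_band = np.zeros((ny, nx))
    mono_band[:baseline_px, :] = 1500.0
    mono_band[:baseline_px, :] *= 1.0 + 0.15 * rng.standard_normal((baseline_px, nx))
    factin2d = factin2d + gaussian_filter(mono_band.clip(0), 1.0)

    z_prof = _z_profile(geom, 0.5 * geom.depth_um, 0.3 * geom.depth_um)
    factin = z_prof[:, None, None] * factin2d[None, :, :]

    # --- nuclei channel ---------------------------------------------------
    nuc = np.zeros((geom.n_z, ny, nx))
    if nuclei.size:
        zc = nuclei[:, 2] / geom.z_step - 0.5
        zi = np.clip(np.round(zc).astype(int), 0, geom.n_z - 1)
        for plane in range(geom.n_z):
            sel = zi == plane
            if sel.any():
                nuc[plane] += _splat_2d((ny, nx), nuclei[sel, :2] / px, 1.0)
        nuc = gaussian_filter(
            nuc, (_NUCLEUS_SIGMA_Z_UM / geom.z_step, _NUCLEUS_SIGMA_UM / px,
                  _NUCLEUS_SIGMA_UM / px)
        )
        nuc *= 4000.0 / nuc.max()

    def _finish(channel: np.ndarray) -> np.ndarray:
        img = channel + _BACKGROUND_LEVEL
        if noise:
            img = rng.poisson(img).astype(float)
            img += rng.normal(0.0, _READ_NOISE_SD, img.shape)
        return np.clip(img, 0, 2**geom.bit_depth - 1).astype(np.uint16)

    stack = ChipStack(
        channels={"nuclei": _finish(nuc), "factin": _finish(factin)},
        pixel_size=px,
        z_step=geom.z_step,
        bit_depth=geom.bit_depth,
    )

    beyond = spr_nuc[spr_nuc[:, 1] > p.baseline_y] if spr_nuc.size else spr_nuc
    if beyond.size:
        top = np.sort(beyond[:, 1])[-10:]
        true_distance = float(top.mean() - p.baseline_y)
    else:
        true_distance = 0.0

    truth = ChipGroundTruth(
        nuclei_positions=nuclei,
        sprout_paths=paths,
        true_distance=max(true_distance, 0.0),
        true_area=true_area,
        true_nuclei_in_sprouts=int(beyond.shape[0]) if beyond.size else 0,
        baseline_y=p.baseline_y,
        sprout_nuclei=spr_nuc,
    )
    return stack, truth


def generate_dose_response_dataset(
    concentrations: Sequence[float],
    p: SproutingModelParams,
    n_per_conc: int = 8,
    seed: int | None = None,
    compound: str = "sunitinib",
) -> pd.DataFrame:
    """Per-chip metric table across a concentration series, ready for 4PL fitting.

    Requires at least 4 distinct concentrations (4PL identifiability).
    """
    distinct = set(float(c) for c in concentrations)
    if len(distinct) < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations, got {len(distinct)}"
        )
    if n_per_conc < 1:
        raise ValueError("n_per_conc must be >= 1")
    layout = PlateLayout.dose_series(sorted(distinct), n_per_conc, compound)
    return simulate_metric_table(layout, p, seed=seed)
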