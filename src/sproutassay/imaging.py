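"""Image-stack I/O, maximum-intensity projection and two-site stitching.

Each chip is acquired as two overlapping confocal sites (nominal 10%
overlap along the sprouting axis).  Quantification runs on the stitched
maximum projection.  Coordinate convention throughout the package: pixel
(0, 0) is the top-left corner, y (axis 0) increases toward the gel — the
direction of sprouting — and physical coordinates are obtained by
multiplying pixel indices by ``pixel_size`` (µm/px).

OME-TIFF is the canonical on-disk format; pixel size and z-step are
written to and recovered from the OME metadata.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation

__all__ = [
    "ChipStack",
    "ProjectedImage",
    "read_stack",
    "write_stack",
    "max_project",
    "stitch_pair",
]

CHANNEL_ORDER = ("nuclei", "factin")


@dataclass
class ChipStack:
    """Two-channel 3D intensity grid for one chip site.

    ``channels`` maps channel name -> (z, y, x) array; both channels must
    share a shape.  Geometry is carried in µm.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    z_step: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 3:
                raise ValueError(f"channel {name!r} must be 3D (z, y, x)")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ProjectedImage:
    """Named 2D channels after max projection, with physical geometry."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) µm offset after stitching

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("projected channels must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def write_stack(stack: ChipStack, path: str | Path) -> None:
    """Write a ChipStack as OME-TIFF with axes CZYX and physical pixel sizes."""
    arr = np.stack([stack.channels[name] for name in CHANNEL_ORDER])
    tifffile.imwrite(
        str(path),
        arr,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(CHANNEL_ORDER)},
        },
    )


def _ome_pixel_sizes(ome_xml: str) -> tuple[float | None, float | None]:
    """(pixel_size, z_step) from OME-XML, or None where absent."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            px = el.attrib.get("PhysicalSizeX")
            pz = el.attrib.get("PhysicalSizeZ")
            return (
                float(px) if px is not None else None,
                float(pz) if pz is not None else None,
            )
    return None, None


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> ChipStack:
    """Read an OME-TIFF (or plain TIFF) stack into a ChipStack.

    Metadata (pixel size, z-step) is taken from the OME header when
    present; the keyword arguments act as fallbacks for plain TIFFs.
    Accepted array layouts: (C, Z, Y, X), (Z, Y, X) single channel,
    or (Y, X) single plane.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If the file is not an image or a required channel is missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            meta_px = meta_pz = None
            if tif.ome_metadata:
                meta_px, meta_pz = _ome_pixel_sizes(tif.ome_metadata)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc

    px = meta_px or pixel_size
    pz = meta_pz or z_step
    if px is None:
        raise ValueError(f"{path}: pixel size absent from metadata and not provided")
    if pz is None:
        pz = 1.0

    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim == 3:
        channels = {"nuclei": arr}
    elif arr.ndim == 4:
        if arr.shape[0] < len(CHANNEL_ORDER):
            missing = CHANNEL_ORDER[arr.shape[0]:]
            raise ValueError(f"{path}: missing channel(s) {missing}")
        channels = {name: arr[i] for i, name in enumerate(CHANNEL_ORDER)}
    else:
        raise ValueError(f"{path}: unsupported array shape {arr.shape}")

    bit_depth = 16 if arr.dtype == np.uint16 else 8 * arr.dtype.itemsize
    return ChipStack(channels=channels, pixel_size=float(px), z_step=float(pz),
                     bit_depth=bit_depth)


def max_project(stack: ChipStack) -> ProjectedImage:
    """Per-pixel maximum over z for every channel.

    Collapses the 3D fluorescence to 2D; dtype and value range are
    preserved (the max of a stack of uint16 planes is uint16).
    """
    return ProjectedImage(
        channels={name: ch.max(axis=0) for name, ch in stack.channels.items()},
        pixel_size=stack.pixel_size,
    )


def stitch_pair(
    img_a: ProjectedImage,
    img_b: ProjectedImage,
    nominal_overlap: float = 0.10,
    registration_channel: str = "factin",
    max_shift_fraction: float = 0.10,
) -> ProjectedImage:
    """Stitch two vertically adjacent site projections with linear blending.

    ``img_b`` sits below ``img_a`` along y with the given nominal
    fractional overlap.  The translation is refined by phase
    cross-correlation between the nominally overlapping strips; if the
    refined offset deviates from nominal by more than
    ``max_shift_fraction`` of the frame height, the refinement is
    considered spurious, a warning is raised and the nominal offset is
    used.  The overlap zone is fused with a linear (distance-weighted)
    ramp whose weights are 0/1 at the seam edges and sum to 1 throughout.
    """
    if img_a.pixel_size != img_b.pixel_size:
        raise ValueError("pixel sizes differ between sites")
    if not 0.0 < nominal_overlap <= 0.5:
        raise ValueError("nominal_overlap must be in (0, 0.5]")
    ha, wa = img_a.shape
    hb, wb = img_b.shape
    if wa != wb:
        raise ValueError("site widths differ")

    ov = int(round(nominal_overlap * ha))
    ov = max(ov, 1)

    # refine translation on strips wide enough to contain the overlap plus
    # the maximum admissible misalignment
    margin = int(np.ceil(max_shift_fraction * ha)) + 2
    strip = min(ha, hb, ov + margin)
    ref = np.asarray(img_a.channels[registration_channel][ha - strip:], dtype=float)
    mov = np.asarray(img_b.channels[registration_channel][:strip], dtype=float)
    eff_ov = ov
    if ref.std() > 0 and mov.std() > 0:
        shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10)
        dy = int(round(shift[0]))
        dx = int(round(shift[1]))
        refined_ov = strip - dy  # overlap implied by the refined offset
        if (abs(refined_ov - ov) > max_shift_fraction * ha
                or abs(dx) > max_shift_fraction * wa):
            warnings.warn(
                f"registration offset ({dy}, {dx}) px deviates more than "
                f"{max_shift_fraction:.0%} of frame from nominal; "
                "using nominal overlap",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            eff_ov = refined_ov
    eff_ov = int(np.clip(eff_ov, 1, min(ha, hb)))

    out_h = ha + hb - eff_ov
    ramp = np.linspace(0.0, 1.0, eff_ov + 2)[1:-1]  # strictly inside (0, 1)
    fused: dict[str, np.ndarray] = {}
    for name in img_a.channels:
        a = np.asarray(img_a.channels[name], dtype=float)
        b = np.asarray(img_b.channels[name], dtype=float)
        out = np.empty((out_h, wa))
        out[: ha - eff_ov] = a[: ha - eff_ov]
        out[ha:] = b[eff_ov:]
        seam_a = a[ha - eff_ov:]
        seam_b = b[:eff_ov]
        out[ha - eff_ov: ha] = (1.0 - ramp[:, None]) * seam_a + ramp[:, None] * seam_b
        dtype = img_a.channels[name].dtype
        if np.issubdtype(dtype, np.integer):
            out = np.clip(np.round(out), np.iinfo(dtype).min, np.iinfo(dtype).max)
        fused[name] = out.astype(dtype)

    return ProjectedImage(channels=fused, pixel_size=img_a.pixel_size,
                          origin=img_a.origin)
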