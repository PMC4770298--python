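"""Scanner raster IO, RGB channel handling, and per-pixel absorbance.

A flatbed scanner in transmission ("film scan") mode records the light
transmitted through a dye-filled transparent device as a 16-bit RGB TIFF.
Absorbance at each pixel is ``A = log10(I0 / It)`` where ``I0`` comes from a
blank-solvent reference scan (or a blank region of the sample scan) and
``It`` from the dye-filled scan, both in 16-bit counts.  Under the
Beer-Lambert law ``A = eps * c * d``, so the absorbance image is a scaled
depth image — that inversion lives in :mod:`uscape.reconstruction`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "MICRONS_PER_INCH",
    "ScanImage",
    "AbsorbanceMap",
    "pixel_pitch_um",
    "read_scan",
    "write_scan",
    "split_channel",
    "compute_absorbance",
    "average_scans",
    "write_absorbance",
    "read_absorbance",
]

MICRONS_PER_INCH = 25400.0

#: channel name -> index in the last axis of an RGB raster
CHANNELS = {"R": 0, "G": 1, "B": 2}

MAX_COUNT = 65535


class FormatError(ValueError):
    """Raised when a raster does not match the expected 16-bit RGB layout."""


class PairingError(ValueError):
    """Raised when two rasters/maps that must match (shape, channel) do not."""


def pixel_pitch_um(dpi: float) -> float:
    """Physical pixel pitch in microns for a scan resolution in dots/inch.

    12800 dpi gives 1.984 um (the "2 um per pixel" regime); 1200 dpi gives
    21.17 um.
    """
    if dpi <= 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return MICRONS_PER_INCH / dpi


@dataclass
class ScanImage:
    """A 16-bit, 3-channel scanner raster with physical pixel pitch.

    Attributes
    ----------
    pixels : (H, W, 3) uint16 array
        Transmitted-light counts per channel, 0..65535.
    dpi : float
        Scan resolution; pixel pitch is ``25400 / dpi`` microns.
    meta : dict
        Acquisition metadata (scan index, mode tag, simulation seed, ...).
    """

    pixels: np.ndarray
    dpi: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected (H, W, 3) raster, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint16:
            if np.issubdtype(self.pixels.dtype, np.integer):
                if self.pixels.min() < 0 or self.pixels.max() > MAX_COUNT:
                    raise FormatError("integer counts outside [0, 65535]")
                self.pixels = self.pixels.astype(np.uint16)
            else:
                raise FormatError(f"expected uint16 counts, got {self.pixels.dtype}")
        if self.dpi <= 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")

    @property
    def pitch_um(self) -> float:
        return pixel_pitch_um(self.dpi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class AbsorbanceMap:
    """Per-pixel absorbance in one color channel.

    ``values`` is dimensionless (log10 units).  ``mask`` is True where the
    absorbance is computable; noise may drive valid values slightly negative
    and they are kept as-is.  ``pitch_um`` carries the physical grid.
    """

    values: np.ndarray
    channel: str
    pitch_um: float
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError("absorbance map must be 2-D")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {sorted(CHANNELS)}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise PairingError("mask shape does not match values")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("absorbance must be finite wherever mask is true")


def read_scan(path: str | Path, dpi: float | None = None) -> ScanImage:
    """Read a 16-bit RGB TIFF scan.

    The pixel pitch is derived from the TIFF resolution tags when present;
    an explicit ``dpi`` argument overrides them.  8-bit images are accepted
    with a warning and upscaled by 257 so that white maps to 65535.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tag_dpi = None
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is not None:
            num, den = xres.value
            if den and num:
                res = num / den
                # ResolutionUnit 2 = inch (TIFF default), 3 = cm
                if unit is None or unit.value == 2:
                    tag_dpi = res
                elif unit.value == 3:
                    tag_dpi = res * 2.54
    if data.ndim != 3 or data.shape[2] != 3:
        raise FormatError(
            f"{path}: expected a 3-channel raster, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        warnings.warn(f"{path}: 8-bit image; upscaling counts by 257", stacklevel=2)
        data = data.astype(np.uint16) * 257
    elif data.dtype != np.uint16:
        raise FormatError(f"{path}: expected uint16 data, got {data.dtype}")
    use_dpi = dpi if dpi is not None else tag_dpi
    if use_dpi is None:
        raise FormatError(
            f"{path}: no resolution tag and no dpi override; cannot set pixel pitch"
        )
    return ScanImage(pixels=data, dpi=float(use_dpi), meta={"path": str(path)})


def write_scan(img: ScanImage, path: str | Path) -> None:
    """Write a scan as a single-page contiguous 16-bit RGB TIFF with dpi tags."""
    tifffile.imwrite(
        Path(path),
        img.pixels,
        photometric="rgb",
        resolution=(img.dpi, img.dpi),
        resolutionunit="INCH",
        contiguous=True,
    )


def split_channel(img: ScanImage, channel: str) -> np.ndarray:
    """Return one color channel of a scan as a (H, W) uint16 array."""
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {sorted(CHANNELS)}, got {channel!r}")
    return img.pixels[:, :, CHANNELS[channel]]


def _reference_counts(
    sample: np.ndarray,
    reference: "ScanImage | tuple[int, int, int, int] | None",
    channel: str,
    sample_img: ScanImage,
) -> np.ndarray | float:
    """Resolve the incident-intensity I0 as a full raster or scalar mean."""
    if isinstance(reference, ScanImage):
        if reference.shape != sample_img.shape:
            raise PairingError(
                f"reference shape {reference.shape} != sample shape {sample_img.shape}"
            )
        return split_channel(reference, channel).astype(np.float64)
    # region mode: (row0, row1, col0, col1) half-open slice into the sample
    r0, r1, c0, c1 = reference
    region = sample[r0:r1, c0:c1]
    if region.size == 0:
        raise ValueError(f"background region {reference} is empty or outside sample")
    return float(region.mean())


def compute_absorbance(
    sample: ScanImage,
    reference: "ScanImage | tuple[int, int, int, int]",
    channel: str = "B",
) -> AbsorbanceMap:
    """Per-pixel absorbance ``A = log10(I0 / It)`` in one channel.

    Parameters
    ----------
    sample : ScanImage
        Scan of the dye-filled structure (transmitted counts ``It``).
    reference : ScanImage or (row0, row1, col0, col1)
        Either a paired blank-solvent scan of the same geometry (per-pixel
        ``I0``, the default practice) or a rectangular background region of
        the sample whose scalar mean serves as ``I0``.
    channel : {"R", "G", "B"}
        Color channel to use; blue has the largest extinction coefficient
        for an Allura-Red-like dye.

    Zero transmitted counts are clamped to 1 before division and flagged
    invalid in the mask, so noisy deep pixels do not produce infinities.
    """
    it = split_channel(sample, channel).astype(np.float64)
    i0 = _reference_counts(it, reference, channel, sample)
    mask = it >= 1
    if not np.isscalar(i0):
        mask &= i0 >= 1
        i0 = np.maximum(i0, 1.0)
    values = np.log10(np.maximum(np.asarray(i0, dtype=np.float64), 1.0)
                      / np.maximum(it, 1.0))
    meta = {
        "channel": channel,
        "reference": "image" if isinstance(reference, ScanImage) else "region",
        "n_scans": 1,
    }
    return AbsorbanceMap(values=values, channel=channel,
                         pitch_um=sample.pitch_um, mask=mask, meta=meta)


def _integer_shift(moving: np.ndarray, fixed: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) aligning ``moving`` onto ``fixed`` by peak cross-correlation."""
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=1)
    return int(round(shift[0])), int(round(shift[1]))


def average_scans(
    maps: Sequence[AbsorbanceMap], align: str = "none"
) -> AbsorbanceMap:
    """Pixelwise mean of repeated-scan absorbance maps.

    Averaging N scans with independent sensor noise reduces the absorbance
    (and therefore depth) noise by ~1/sqrt(N).  With ``align="integer-shift"``
    each map is registered to the first by maximum cross-correlation before
    averaging; the default assumes flatbed repeat scans are pixel-aligned.
    The output mask is the union of input validity, and each pixel averages
    only the maps valid there.
    """
    if len(maps) == 0:
        raise ValueError("need at least one absorbance map")
    if align not in ("none", "integer-shift"):
        raise ValueError(f"unknown align mode {align!r}")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape:
            raise PairingError("absorbance maps differ in shape")
        if m.channel != first.channel:
            raise PairingError(
                f"mixed channels: {m.channel!r} vs {first.channel!r}"
            )
    total = np.zeros_like(first.values)
    count = np.zeros(first.values.shape, dtype=np.int64)
    for m in maps:
        vals, msk = m.values, m.mask
        if align == "integer-shift" and m is not first:
            dy, dx = _integer_shift(vals, first.values)
            vals = np.roll(vals, (dy, dx), axis=(0, 1))
            msk = np.roll(msk, (dy, dx), axis=(0, 1))
        total += np.where(msk, vals, 0.0)
        count += msk
    mask = count > 0
    mean = np.divide(total, count, out=np.zeros_like(total), where=mask)
    meta = dict(first.meta)
    meta["n_scans"] = len(maps)
    return AbsorbanceMap(values=mean, channel=first.channel,
                         pitch_um=first.pitch_um, mask=mask, meta=meta)


def write_absorbance(amap: AbsorbanceMap, path: str | Path) -> None:
    """Persist an absorbance map as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, amap.values.astype(np.float32), contiguous=True)
    sidecar = {
        "channel": amap.channel,
        "pitch_um": amap.pitch_um,
        "meta": amap.meta,
        "n_invalid": int((~amap.mask).sum()),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    if not amap.mask.all():
        tifffile.imwrite(
            path.with_name(path.stem + ".mask" + path.suffix),
            amap.mask.astype(np.uint8),
        )


def read_absorbance(path: str | Path) -> AbsorbanceMap:
    """Read an absorbance map written by :func:`write_absorbance`."""
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mask_path = path.with_name(path.stem + ".mask" + path.suffix)
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return AbsorbanceMap(
        values=values,
        channel=sidecar["channel"],
        pitch_um=sidecar["pitch_um"],
        mask=mask,
        meta=sidecar.get("meta", {}),
    )
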