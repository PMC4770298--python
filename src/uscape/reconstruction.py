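"""Depth reconstruction: invert calibrated absorbance into optical path.

With a known extinction coefficient and dye concentration the Beer-Lambert
law inverts pixelwise to ``d = A / (eps * c)``.  The result is the optical
path length through dye at each pixel — equal to the structure depth when
one bounding surface is flat, and the *sum* of both surface deformations
for doubly-deformed laminated chambers (volumes stay correct either way).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from sklearn.base import BaseEstimator, TransformerMixin

from .scan_io import AbsorbanceMap

__all__ = [
    "DepthMap",
    "DepthReconstructor",
    "reconstruct_depth",
    "depth_noise_estimate",
    "write_depth_map",
    "read_depth_map",
]


@dataclass
class DepthMap:
    """Per-pixel reconstructed depth (um) on a physical grid.

    Negative depths from noise are retained (not clipped) so statistics on
    blank regions stay unbiased; clipping is a report-time choice.
    ``provenance`` records eps, concentration, channel and the number of
    averaged scans.
    """

    depth_um: np.ndarray
    pitch_um: float
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=np.float64)
        if self.depth_um.ndim != 2:
            raise ValueError("depth map must be 2-D")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if self.mask is None:
            self.mask = np.ones(self.depth_um.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.depth_um.shape:
                raise ValueError("mask shape does not match depth")
        if not np.all(np.isfinite(self.depth_um[self.mask])):
            raise ValueError("valid depths must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth_um.shape


class DepthReconstructor(BaseEstimator, TransformerMixin):
    """Transformer turning absorbance maps into depth maps.

    Parameters
    ----------
    epsilon : float
        Extinction coefficient in / mM / um (from calibration).
    concentration_mm : float
        Dye concentration filling the structure.

    ``transform`` accepts an :class:`~uscape.scan_io.AbsorbanceMap` (or a
    bare 2-D array plus ``pitch_um``) and divides by ``eps * c``.  The
    transform is stateless, so ``fit`` only validates parameters; depth is
    linear in 1/c — doubling the concentration halves reconstructed depth
    for the same absorbance.
    """

    def __init__(self, epsilon: float = 0.00052, concentration_mm: float = 6.0):
        self.epsilon = epsilon
        self.concentration_mm = concentration_mm

    def fit(self, X=None, y=None):
        if self.epsilon * self.concentration_mm <= 0:
            raise ValueError("epsilon * concentration must be positive")
        self.scale_ = 1.0 / (self.epsilon * self.concentration_mm)
        return self

    def transform(self, X: AbsorbanceMap | np.ndarray,
                  pitch_um: float | None = None) -> DepthMap:
        if not hasattr(self, "scale_"):
            self.fit()
        if isinstance(X, AbsorbanceMap):
            values, mask, pitch = X.values, X.mask, X.pitch_um
            prov = dict(X.meta)
        else:
            values = np.asarray(X, dtype=np.float64)
            mask = None
            if pitch_um is None:
                raise ValueError("pitch_um required for a bare array")
            pitch = pitch_um
            prov = {}
        prov.update(
            epsilon=self.epsilon,
            concentration_mm=self.concentration_mm,
        )
        return DepthMap(depth_um=values * self.scale_, pitch_um=pitch,
                        mask=mask, provenance=prov)


def reconstruct_depth(amap: AbsorbanceMap, epsilon: float,
                      concentration_mm: float) -> DepthMap:
    """Pixelwise ``d = A / (eps * c)``; mask propagated from the absorbance map."""
    return DepthReconstructor(epsilon, concentration_mm).fit().transform(amap)


def depth_noise_estimate(
    maps: Sequence[DepthMap],
    region: tuple[int, int, int, int],
) -> float:
    """Depth-noise sd (um) over a known-flat region.

    With several repeat maps: the pixelwise sd across maps, averaged over
    the region (sensor-noise estimate independent of surface texture).
    With one map: the spatial sd within the region.
    """
    if len(maps) == 0:
        raise ValueError("need at least one depth map")
    r0, r1, c0, c1 = region
    h, w = maps[0].shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise IndexError(f"region {region} outside map of shape {(h, w)}")
    stack = np.stack([m.depth_um[r0:r1, c0:c1] for m in maps])
    if len(maps) == 1:
        return float(stack[0].std(ddof=1))
    return float(stack.std(axis=0, ddof=1).mean())


def write_depth_map(dmap: DepthMap, path: str | Path) -> None:
    """Persist as 32-bit float TIFF (um) plus a JSON provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, dmap.depth_um.astype(np.float32), contiguous=True)
    sidecar = {
        "units": "um",
        "pitch_um": dmap.pitch_um,
        "provenance": dmap.provenance,
        "n_invalid": int((~dmap.mask).sum()),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_depth_map(path: str | Path) -> DepthMap:
    path = Path(path)
    depth = tifffile.imread(path).astype(np.float64)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DepthMap(depth_um=depth, pitch_um=sidecar["pitch_um"],
                    provenance=sidecar.get("provenance", {}))
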