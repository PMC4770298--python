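"""Forward model: ground-truth depth fields and synthetic scanner images.

Renders analytic depth fields of common microfluidic features (cylindrical
chambers, isotropic-etch basin wells, laser-ablated cone wells and Gaussian
channels, sagging laminated chambers) and pushes them through a Beer-Lambert
transmission model with 16-bit quantization and sensor noise, emulating a
flatbed scanner in film-scan mode.  Everything is seedable, so repeated
"scans" of one device and whole well arrays with known per-well ground truth
can be produced for testing the inverse pipeline.

Geometry conventions: physical coordinates in microns, x right / y down,
the center of pixel ``(row, col)`` at ``((col + 0.5) * pitch,
(row + 0.5) * pitch)``.  A pixel takes the depth at its center (no
anti-aliasing at feature edges).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scan_io import MAX_COUNT, ScanImage, pixel_pitch_um

__all__ = [
    "FeatureSpec",
    "DepthField",
    "ScanSimConfig",
    "LayoutError",
    "render_depth_field",
    "simulate_scan",
    "generate_well_array",
    "WellArrayTruth",
    "sample_well_volumes",
    "cylinder_volume_um3",
    "basin_well_volume_um3",
    "cone_well_volume_um3",
    "sag_cap_height",
]

logger = logging.getLogger(__name__)

KINDS = (
    "cylinder_chamber",
    "basin_well",
    "cone_well",
    "ablated_channel",
    "sagging_chamber",
)


class LayoutError(ValueError):
    """Raised when features overlap or fall outside the rendered extent."""


@dataclass
class FeatureSpec:
    """One microfluidic feature to render.

    Parameters
    ----------
    kind : str
        One of ``cylinder_chamber`` (flat-bottom disk), ``basin_well``
        (isotropic-etch profile: flat bottom of the mask radius, quarter-circle
        sidewall of radius equal to the etch depth), ``cone_well`` (conical
        pit from single-pulse laser ablation), ``ablated_channel`` (straight
        channel with Gaussian cross-section), ``sagging_chamber`` (cylinder
        whose cap sags inward as a spherical cap of volume ``k_sag * r**3``).
    center : (x, y) microns
        Feature center (channel midpoint for ``ablated_channel``).
    radius : microns
        Characteristic radius: disk/mask/mouth radius, or the channel
        half-length for ``ablated_channel``.
    depth : microns
        Maximum depth of the feature.
    params : dict
        Kind-specific extras: ``ablated_channel`` takes ``width_um``
        (Gaussian sigma of the cross-section, default ``depth``) and
        ``angle_deg`` (axis orientation, default 0 = along x);
        ``sagging_chamber`` takes ``k_sag`` (dimensionless sag-volume
        coefficient, ``V_sag = k_sag * r**3``, default 0.05).
    """

    kind: str
    center: tuple[float, float]
    radius: float
    depth: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    # --- footprint used for overlap / bounds checks -------------------------
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in microns enclosing the feature."""
        cx, cy = self.center
        if self.kind == "basin_well":
            r = self.radius + self.depth  # sidewall extends one etch depth
            return cx - r, cy - r, cx + r, cy + r
        if self.kind == "ablated_channel":
            half_len = self.radius
            width = 3.0 * self.params.get("width_um", self.depth)
            ang = math.radians(self.params.get("angle_deg", 0.0))
            ux, uy = math.cos(ang), math.sin(ang)
            hx = abs(ux) * half_len + abs(uy) * width
            hy = abs(uy) * half_len + abs(ux) * width
            return cx - hx, cy - hy, cx + hx, cy + hy
        r = self.radius
        return cx - r, cy - r, cx + r, cy + r

    # --- analytic depth profile --------------------------------------------
    def depth_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Depth (um) of this feature at physical coordinates (vectorized)."""
        cx, cy = self.center
        if self.kind == "ablated_channel":
            ang = math.radians(self.params.get("angle_deg", 0.0))
            ux, uy = math.cos(ang), math.sin(ang)
            dx, dy = x - cx, y - cy
            along = dx * ux + dy * uy
            perp = -dx * uy + dy * ux
            width = self.params.get("width_um", self.depth)
            prof = self.depth * np.exp(-0.5 * (perp / width) ** 2)
            return np.where(np.abs(along) <= self.radius, prof, 0.0)

        rho = np.hypot(x - cx, y - cy)
        if self.kind == "cylinder_chamber":
            return np.where(rho <= self.radius, self.depth, 0.0)
        if self.kind == "cone_well":
            return np.clip(self.depth * (1.0 - rho / self.radius), 0.0, None)
        if self.kind == "basin_well":
            r0, d = self.radius, self.depth
            wall = np.clip(d**2 - np.clip(rho - r0, 0.0, None) ** 2, 0.0, None)
            prof = np.where(rho <= r0, d, np.sqrt(wall))
            return np.where(rho <= r0 + d, prof, 0.0)
        if self.kind == "sagging_chamber":
            r, d = self.radius, self.depth
            k_sag = self.params.get("k_sag", 0.05)
            h = sag_cap_height(r, k_sag * r**3)
            sphere_r = (r**2 + h**2) / (2.0 * h) if h > 0 else np.inf
            inside = rho <= r
            if h > 0:
                sag = np.sqrt(np.clip(sphere_r**2 - rho**2, 0.0, None)) - (
                    sphere_r - h
                )
                sag = np.clip(sag, 0.0, None)
            else:
                sag = np.zeros_like(rho)
            return np.where(inside, np.clip(d - sag, 0.0, None), 0.0)
        raise AssertionError(self.kind)

    def volume_um3(self) -> float:
        """Analytic volume of the feature in cubic microns."""
        r, d = self.radius, self.depth
        if self.kind == "cylinder_chamber":
            return cylinder_volume_um3(r, d)
        if self.kind == "basin_well":
            return basin_well_volume_um3(r, d)
        if self.kind == "cone_well":
            return cone_well_volume_um3(r, d)
        if self.kind == "ablated_channel":
            width = self.params.get("width_um", d)
            # full Gaussian cross-section integrates to d*width*sqrt(2*pi)
            return d * width * math.sqrt(2.0 * math.pi) * (2.0 * r)
        if self.kind == "sagging_chamber":
            k_sag = self.params.get("k_sag", 0.05)
            return cylinder_volume_um3(r, d) - k_sag * r**3
        raise AssertionError(self.kind)


def cylinder_volume_um3(r: float, d: float) -> float:
    return math.pi * r**2 * d


def basin_well_volume_um3(r0: float, d: float) -> float:
    """Isotropic-etch well: flat bottom radius r0 plus quarter-circle shoulder.

    Solid of revolution: ``pi * (r0^2 d + (pi/2) r0 d^2 + (2/3) d^3)``.
    """
    return math.pi * (r0**2 * d + (math.pi / 2.0) * r0 * d**2 + (2.0 / 3.0) * d**3)


def cone_well_volume_um3(r: float, d: float) -> float:
    return math.pi * r**2 * d / 3.0


def sag_cap_height(r: float, v_sag: float) -> float:
    """Height of a spherical cap of base radius ``r`` and volume ``v_sag``.

    Solves ``pi*h*(3*r^2 + h^2)/6 = v_sag`` for h (the unique positive root).
    """
    if v_sag <= 0:
        return 0.0
    roots = np.roots([math.pi / 6.0, 0.0, math.pi * r**2 / 2.0, -v_sag])
    real = roots[np.abs(roots.imag) < 1e-9].real
    pos = real[real > 0]
    if pos.size == 0:
        raise ValueError("no positive cap height; sag volume too large?")
    return float(pos.min())


@dataclass
class DepthField:
    """Ground-truth (or reconstructed-equivalent) depth grid in microns."""

    depth: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2:
            raise ValueError("depth field must be 2-D")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth field must be finite")
        if np.any(self.depth < 0):
            raise ValueError("ground-truth depths must be non-negative")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")

    def volume_nl(self) -> float:
        """Total volume, sum of pixel depths times pixel area, in nL."""
        return float(self.depth.sum() * self.pitch_um**2 * 1e-6)


def render_depth_field(
    features: Sequence[FeatureSpec],
    extent_um: tuple[float, float],
    pitch_um: float,
) -> DepthField:
    """Rasterize analytic features onto a pixel grid.

    ``extent_um`` is (width, height).  Each pixel holds the maximum feature
    depth at its center.  Features must lie inside the extent and must not
    overlap (checked on bounding boxes, then on rendered footprints).
    """
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    w_um, h_um = extent_um
    if w_um <= 0 or h_um <= 0:
        raise ValueError("extent must be positive")
    n_cols = max(1, int(round(w_um / pitch_um)))
    n_rows = max(1, int(round(h_um / pitch_um)))
    depth = np.zeros((n_rows, n_cols), dtype=np.float64)
    claimed = np.zeros((n_rows, n_cols), dtype=bool)

    for feat in features:
        xmin, ymin, xmax, ymax = feat.bounding_box()
        if xmin < 0 or ymin < 0 or xmax > w_um or ymax > h_um:
            raise LayoutError(
                f"{feat.kind} at {feat.center} extends outside extent {extent_um}"
            )
        c0 = max(0, int(xmin / pitch_um) - 1)
        c1 = min(n_cols, int(math.ceil(xmax / pitch_um)) + 1)
        r0 = max(0, int(ymin / pitch_um) - 1)
        r1 = min(n_rows, int(math.ceil(ymax / pitch_um)) + 1)
        cols = (np.arange(c0, c1) + 0.5) * pitch_um
        rows = (np.arange(r0, r1) + 0.5) * pitch_um
        xx, yy = np.meshgrid(cols, rows)
        d = feat.depth_at(xx, yy)
        footprint = d > 0
        if np.any(claimed[r0:r1, c0:c1] & footprint):
            raise LayoutError(
                f"{feat.kind} at {feat.center} overlaps a previous feature"
            )
        claimed[r0:r1, c0:c1] |= footprint
        np.maximum(depth[r0:r1, c0:c1], d, out=depth[r0:r1, c0:c1])

    return DepthField(depth=depth, pitch_um=pitch_um)


@dataclass
class ScanSimConfig:
    """Scanner + dye parameters for the Beer-Lambert forward model.

    Transmitted counts per channel x are
    ``It_x = I0 * 10**(-eps_x * c * d) + N(0, noise_sd)``, rounded and
    clipped to the 16-bit range.  Extinction coefficients default to an
    Allura-Red-like dye: strong absorption in blue (0.00052 / mM / um),
    intermediate in green, essentially none in red.
    """

    dpi: float = 12800.0
    i0: float = 60000.0
    noise_sd: float = 100.0
    eps_rgb: tuple[float, float, float] = (0.0, 0.00026, 0.00052)
    concentration_mm: float = 6.0
    seed: int | None = None
    poisson: bool = False
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.i0 <= MAX_COUNT):
            raise ValueError(f"incident intensity must be in (0, {MAX_COUNT}]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        er, eg, eb = self.eps_rgb
        if not (eb >= eg >= er >= 0):
            raise ValueError(
                "extinction coefficients must satisfy eps_B >= eps_G >= eps_R >= 0"
            )
        if self.concentration_mm < 0:
            raise ValueError("concentration must be non-negative")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def pitch_um(self) -> float:
        return pixel_pitch_um(self.dpi)


def simulate_scan(fld: DepthField, config: ScanSimConfig) -> ScanImage:
    """Synthesize one 16-bit RGB scan of a depth field.

    Repeated calls with distinct seeds model repeated scans of the same
    device; identical seed and config give bit-identical images.
    """
    rng = np.random.default_rng(config.seed)
    d = fld.depth
    channels = []
    for eps in config.eps_rgb:
        it = config.i0 * np.power(10.0, -eps * config.concentration_mm * d)
        if config.poisson:
            it = rng.poisson(it).astype(np.float64)
        if config.noise_sd > 0:
            it = it + rng.normal(0.0, config.noise_sd, size=it.shape)
        if config.gamma is not None:
            it = MAX_COUNT * np.power(np.clip(it, 0, MAX_COUNT) / MAX_COUNT,
                                      1.0 / config.gamma)
        channels.append(np.clip(np.rint(it), 0, MAX_COUNT).astype(np.uint16))
    pixels = np.stack(channels, axis=-1)
    meta = {"sim": True, "seed": config.seed, "noise_sd": config.noise_sd}
    return ScanImage(pixels=pixels, dpi=config.dpi, meta=meta)


@dataclass
class WellArrayTruth:
    """Ground truth for a simulated well array: one record per well."""

    labels: np.ndarray  # (n,) int type index per well
    volumes_nl: np.ndarray  # (n,) analytic volume
    centers_um: np.ndarray  # (n, 2) x, y
    specs: list[FeatureSpec]


def generate_well_array(
    n_per_type: Sequence[int],
    type_specs: Sequence[FeatureSpec],
    jitter_sd: dict | None = None,
    seed: int | None = None,
    spacing_um: float | None = None,
    pitch_um: float = 2.0,
) -> tuple[DepthField, WellArrayTruth]:
    """Place jittered wells of several designed types on a regular grid.

    Types are shuffled over grid sites so neighbors are mixed, as in a
    deliberately heterogeneous array.  ``jitter_sd`` gives per-parameter
    Gaussian sd, keys ``radius`` and ``depth`` (um); draws that would make a
    parameter non-positive are redrawn.  Returns the rendered field plus
    per-well ground-truth labels, analytic volumes and centers.
    """
    if len(n_per_type) != len(type_specs):
        raise ValueError("n_per_type and type_specs must have equal length")
    if any(n < 1 for n in n_per_type):
        raise ValueError("counts must be >= 1")
    jitter_sd = jitter_sd or {}
    rng = np.random.default_rng(seed)

    n_total = int(sum(n_per_type))
    max_diam = max(2.0 * (s.radius + (s.depth if s.kind == "basin_well" else 0.0))
                   for s in type_specs)
    if spacing_um is None:
        spacing_um = 1.5 * max_diam
    if spacing_um < max_diam:
        raise LayoutError(
            f"grid spacing {spacing_um} um is smaller than the largest well "
            f"diameter {max_diam} um"
        )
    n_cols = int(math.ceil(math.sqrt(n_total)))
    n_rows = int(math.ceil(n_total / n_cols))

    labels = np.repeat(np.arange(len(n_per_type)), n_per_type)
    rng.shuffle(labels)

    def _jitter(value: float, key: str) -> float:
        sd = jitter_sd.get(key, 0.0)
        if sd <= 0:
            return value
        for _ in range(100):
            draw = rng.normal(value, sd)
            if draw > 0:
                return draw
        raise ValueError(f"could not draw positive {key} around {value}")

    specs: list[FeatureSpec] = []
    centers = np.empty((n_total, 2))
    volumes = np.empty(n_total)
    for i, lab in enumerate(labels):
        proto = type_specs[lab]
        row, col = divmod(i, n_cols)
        cx = (col + 0.5) * spacing_um
        cy = (row + 0.5) * spacing_um
        spec = FeatureSpec(
            kind=proto.kind,
            center=(cx, cy),
            radius=_jitter(proto.radius, "radius"),
            depth=_jitter(proto.depth, "depth"),
            params=dict(proto.params),
        )
        specs.append(spec)
        centers[i] = (cx, cy)
        volumes[i] = spec.volume_um3() * 1e-6  # nL

    extent = (n_cols * spacing_um, n_rows * spacing_um)
    fld = render_depth_field(specs, extent, pitch_um)
    truth = WellArrayTruth(labels=labels, volumes_nl=volumes,
                           centers_um=centers, specs=specs)
    return fld, truth


def sample_well_volumes(
    means_nl: Sequence[float],
    sds_nl: Sequence[float],
    counts: Sequence[int],
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast statistical surrogate for a multi-type well array.

    Draws per-group Gaussian well volumes (nL).  Negative draws are
    physically meaningless and are rejected and redrawn; the number of
    redraws is logged.  Returns (volumes, group labels).
    """
    if not (len(means_nl) == len(sds_nl) == len(counts)):
        raise ValueError("means, sds and counts must have equal length")
    if any(sd < 0 for sd in sds_nl):
        raise ValueError("sds must be non-negative")
    if any(n < 1 for n in counts):
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    volumes, labels = [], []
    n_redraws = 0
    for g, (mu, sd, n) in enumerate(zip(means_nl, sds_nl, counts)):
        draws = rng.normal(mu, sd, size=n)
        bad = draws <= 0
        while bad.any():
            n_redraws += int(bad.sum())
            draws[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            bad = draws <= 0
        volumes.append(draws)
        labels.append(np.full(n, g, dtype=np.int64))
    if n_redraws:
        logger.info("sample_well_volumes: redrew %d negative volumes", n_redraws)
    return np.concatenate(volumes), np.concatenate(labels)
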