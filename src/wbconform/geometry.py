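"""Conformational morphometry of broiler-carcass breast silhouettes.

A carcass silhouette is a calibrated binary raster with the keel tip (the
caudal apex of the sternum) pointing toward increasing row index.  From two
landmarks — the keel tip and the cranial extreme of the breast — this module
measures the eight conformational quantities used for woody-breast grading:

=====  ====================================================================
M0     breast length, keel tip to cranial end (cm)
M1     maximal breast width in the cranial half, perpendicular to the
       breast axis (cm)
M2     keel-tip offset, exactly M0/5 (cm)
M3     breast width at distance M2 from the keel tip (cm)
M4     apex angle at the keel tip subtended by the endpoints of the M3
       chord (degrees)
M5     area of the triangle (keel tip, M3 chord endpoints) (cm^2)
M6     silhouette area on the keel-tip side of the M3 chord line (cm^2)
M7     M6 - M5, the caudal bulge area outside the apex triangle (cm^2)
=====  ====================================================================

plus the dimensionless ratios M8 = M3/M1, M9 = M3/M2, M10 = M7/M5 and
M11 = M1/M0.

Widths are chord lengths along scanlines perpendicular to the keel-tip ->
cranial-end axis, with sub-pixel boundary crossings obtained by linear
interpolation of the bilinearly sampled mask, and measured between the two
outermost crossings (an outer-caliper convention that bridges small
concavities).  Areas count unit-square pixels by centre position; a pixel
whose centre falls exactly on the chord line is assigned to the cranial
side.  Coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskInvariantError",
    "DegenerateSilhouetteError",
    "SilhouetteMask",
    "Landmarks",
    "Conformation",
    "locate_landmarks",
    "measure_conformation",
    "conformation_from_table",
]

#: minimum foreground size for a mask to count as a silhouette
MIN_FOREGROUND_PX = 100

_EIGHT_CONN = np.ones((3, 3), dtype=int)


class MaskInvariantError(ValueError):
    """The raster is not a valid single-component silhouette."""


class DegenerateSilhouetteError(ValueError):
    """The silhouette is valid but a measurement is undefined on it."""


@dataclass(frozen=True)
class SilhouetteMask:
    """Calibrated binary silhouette, keel tip toward increasing row index.

    Parameters
    ----------
    pixels
        2-D array; nonzero entries are foreground.
    scale_cm_per_px
        Physical size of one pixel edge in centimetres (> 0).
    keel_down
        Orientation flag asserting the keel tip points toward increasing
        row index (the convention after vertical-rotation preprocessing).
    """

    pixels: np.ndarray
    scale_cm_per_px: float
    keel_down: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise MaskInvariantError(f"mask must be 2-D, got shape {px.shape}")
        px = px != 0
        object.__setattr__(self, "pixels", px)
        if not self.scale_cm_per_px > 0:
            raise MaskInvariantError("scale_cm_per_px must be positive")
        n_fg = int(px.sum())
        if n_fg == 0:
            raise MaskInvariantError("empty mask")
        if n_fg < MIN_FOREGROUND_PX:
            raise MaskInvariantError(
                f"foreground has {n_fg} px, need >= {MIN_FOREGROUND_PX}"
            )
        _, n_comp = ndimage.label(px, structure=_EIGHT_CONN)
        if n_comp != 1:
            raise MaskInvariantError(
                f"mask has {n_comp} connected components, need exactly 1"
            )

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class Landmarks:
    """Keel tip and cranial end, as (row, col) points on the silhouette."""

    keel_tip: tuple[float, float]
    cranial_end: tuple[float, float]
    axis: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        kt = np.asarray(self.keel_tip, dtype=float)
        ce = np.asarray(self.cranial_end, dtype=float)
        vec = ce - kt
        norm = float(np.hypot(*vec))
        if norm == 0.0:
            raise DegenerateSilhouetteError("keel tip and cranial end coincide")
        object.__setattr__(self, "keel_tip", (float(kt[0]), float(kt[1])))
        object.__setattr__(self, "cranial_end", (float(ce[0]), float(ce[1])))
        object.__setattr__(self, "axis", vec / norm)

    @property
    def length_px(self) -> float:
        return float(
            np.hypot(
                self.cranial_end[0] - self.keel_tip[0],
                self.cranial_end[1] - self.keel_tip[1],
            )
        )


@dataclass(frozen=True)
class Conformation:
    """The eight conformational measurements and four ratios."""

    m0: float
    m1: float
    m2: float
    m3: float
    m4: float
    m5: float
    m6: float
    m7: float
    m8: float
    m9: float
    m10: float
    m11: float

    _NAMES = tuple(f"M{i}" for i in range(12))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name.lower()) for name in self._NAMES}

    def __getitem__(self, key: str) -> float:
        return getattr(self, key.lower())

    def validate(self) -> None:
        for name in ("m0", "m1", "m2", "m3"):
            if not getattr(self, name) > 0:
                raise DegenerateSilhouetteError(f"{name.upper()} must be positive")
        if not 0.0 < self.m4 < 180.0:
            raise DegenerateSilhouetteError("M4 must lie strictly in (0, 180) degrees")
        # tabulated records carry rounded M2 values; allow table rounding here,
        # mask measurements satisfy the identity to machine precision anyway
        if not math.isclose(self.m2, self.m0 / 5.0, rel_tol=2.5e-2):
            raise DegenerateSilhouetteError("identity M2 = M0/5 violated")
        if math.isfinite(self.m7) and not math.isclose(
            self.m7, self.m6 - self.m5, rel_tol=1e-9, abs_tol=1e-9
        ):
            raise DegenerateSilhouetteError("identity M7 = M6 - M5 violated")


def _finish_conformation(
    m0: float, m1: float, m3: float, m4: float, m5: float, m6: float
) -> Conformation:
    """Fill M2, M7 and the ratios from the primary measurements."""
    m2 = m0 / 5.0
    m7 = m6 - m5
    conf = Conformation(
        m0=m0,
        m1=m1,
        m2=m2,
        m3=m3,
        m4=m4,
        m5=m5,
        m6=m6,
        m7=m7,
        m8=m3 / m1,
        m9=m3 / m2,
        m10=m7 / m5 if m5 > 0 else math.nan,
        m11=m1 / m0,
    )
    return conf


def locate_landmarks(mask: SilhouetteMask) -> Landmarks:
    """Find keel tip and cranial end as extreme foreground points.

    The keel tip is the foreground point with maximal projection on the
    caudal direction (increasing row index under the keel-down convention);
    the cranial end maximises the opposite projection.  Ties are broken by
    the smallest column index, so the output is deterministic.
    """
    rows, cols = np.nonzero(mask.pixels)
    r_keel = rows.max()
    c_keel = cols[rows == r_keel].min()
    r_cran = rows.min()
    c_cran = cols[rows == r_cran].min()
    return Landmarks(
        keel_tip=(float(r_keel), float(c_keel)),
        cranial_end=(float(r_cran), float(c_cran)),
    )


def _scanline_widths(
    pixels: np.ndarray,
    origin: np.ndarray,
    axis: np.ndarray,
    us: np.ndarray,
    t_step: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outer chord widths along scanlines perpendicular to ``axis``.

    For each axial position ``u`` (px from ``origin``) the mask is sampled
    bilinearly along the perpendicular direction; the chord spans the two
    outermost 0.5-level crossings, located by linear interpolation between
    adjacent samples.  Returns ``(widths, v_lo, v_hi)`` in pixels; rows with
    no foreground on the scanline have width NaN.
    """
    perp = np.array([-axis[1], axis[0]])
    half = 0.5 * math.hypot(*pixels.shape) + 2.0
    ts = np.arange(-half, half + t_step, t_step)
    # sample every scanline in a single map_coordinates call
    centers = origin[None, :] + us[:, None] * axis[None, :]
    pts = centers[:, None, :] + ts[None, :, None] * perp[None, None, :]
    vals = ndimage.map_coordinates(
        pixels.astype(float), pts.reshape(-1, 2).T, order=1, mode="constant", cval=0.0
    ).reshape(len(us), len(ts))

    inside = vals >= 0.5
    widths = np.full(len(us), np.nan)
    v_lo = np.full(len(us), np.nan)
    v_hi = np.full(len(us), np.nan)
    any_in = inside.any(axis=1)
    for i in np.nonzero(any_in)[0]:
        row = vals[i]
        idx = np.nonzero(inside[i])[0]
        i0, i1 = idx[0], idx[-1]
        lo = ts[i0]
        if i0 > 0 and row[i0] > row[i0 - 1]:
            frac = (0.5 - row[i0 - 1]) / (row[i0] - row[i0 - 1])
            lo = ts[i0 - 1] + frac * t_step
        hi = ts[i1]
        if i1 < len(ts) - 1 and row[i1] > row[i1 + 1]:
            frac = (0.5 - row[i1 + 1]) / (row[i1] - row[i1 + 1])
            hi = ts[i1 + 1] - frac * t_step
        v_lo[i], v_hi[i] = lo, hi
        widths[i] = hi - lo
    return widths, v_lo, v_hi


def measure_conformation(
    mask: SilhouetteMask,
    landmarks: Landmarks | None = None,
    *,
    n_axis_samples: int = 256,
    t_step: float = 0.25,
) -> Conformation:
    """Measure M0–M11 on a silhouette.

    Parameters
    ----------
    mask
        Validated silhouette raster.
    landmarks
        Keel tip / cranial end; located automatically when omitted.
    n_axis_samples
        Number of scanline positions used in the cranial-half search for M1.
    t_step
        Perpendicular sampling step in pixels for chord crossings.
    """
    lm = landmarks if landmarks is not None else locate_landmarks(mask)
    scale = mask.scale_cm_per_px
    origin = np.asarray(lm.keel_tip, dtype=float)
    axis = lm.axis

    m0_px = lm.length_px
    m0 = m0_px * scale
    m2_px = m0_px / 5.0

    # M3 chord at the keel-tip offset
    w, v_lo, v_hi = _scanline_widths(
        mask.pixels, origin, axis, np.array([m2_px]), t_step=t_step
    )
    if not np.isfinite(w[0]):
        raise DegenerateSilhouetteError(
            "scanline at the M2 offset intersects background only"
        )
    m3_px = float(w[0])
    vlo, vhi = float(v_lo[0]), float(v_hi[0])

    # apex angle at the keel tip from the actual chord endpoints
    if m2_px <= t_step:
        raise DegenerateSilhouetteError("keel tip lies on the M3 chord; M4 undefined")
    # chord endpoints in the (axis, perp) frame relative to the keel tip
    len_lo = math.hypot(m2_px, vlo)
    len_hi = math.hypot(m2_px, vhi)
    cosang = (m2_px * m2_px + vlo * vhi) / (len_lo * len_hi)
    m4 = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    # M1: widest chord over the cranial half of the axis
    us = np.linspace(0.5 * m0_px, m0_px, n_axis_samples)
    widths, _, _ = _scanline_widths(mask.pixels, origin, axis, us, t_step=t_step)
    if not np.isfinite(widths).any():
        raise DegenerateSilhouetteError("no foreground found in the cranial half")
    m1_px = float(np.nanmax(widths))

    # areas: apex triangle and the caudal cap of the silhouette
    m5 = 0.5 * m3_px * m2_px * scale * scale
    rows, cols = np.nonzero(mask.pixels)
    u_centers = (rows - origin[0]) * axis[0] + (cols - origin[1]) * axis[1]
    m6 = float(np.count_nonzero(u_centers < m2_px)) * scale * scale

    conf = _finish_conformation(
        m0=m0, m1=m1_px * scale, m3=m3_px * scale, m4=m4, m5=m5, m6=m6
    )
    conf.validate()
    return conf


#: tolerance (cm^2) before a tabulated M7 is considered inconsistent
M7_ROUNDING_TOL = 0.05


def conformation_from_table(row: Mapping[str, float]) -> Conformation:
    """Build a :class:`Conformation` from a tabulated measurement record.

    Accepts the measured columns M0–M7 (M4, M5, M6, M7 optional) and fills
    whatever is derivable: M2 = M0/5, the symmetric-apex closures
    M4 = 2·atan(M3/(2·M2)) and M5 = M3·M2/2 when those were not recorded,
    M7 = M6 − M5 and the four ratios.  A recorded M7 that disagrees with
    M6 − M5 beyond ±0.05 cm² triggers a warning and is recomputed.
    """

    def get(name: str) -> float:
        for key in (name, name.lower()):
            if key in row:
                val = row[key]
                if val is not None and not (
                    isinstance(val, float) and math.isnan(val)
                ):
                    return float(val)
        return math.nan

    m0, m1, m3 = get("M0"), get("M1"), get("M3")
    m2 = get("M2")
    if math.isnan(m0) and not math.isnan(m2):
        m0 = 5.0 * m2
    for name, val in (("M0", m0), ("M1", m1), ("M3", m3)):
        if math.isnan(val):
            raise ValueError(f"measurement record lacks required column {name}")
    if math.isnan(m2):
        m2 = m0 / 5.0
    elif not math.isclose(m2, m0 / 5.0, rel_tol=2.5e-2):
        warnings.warn(
            f"tabulated M2={m2:g} is not M0/5={m0 / 5.0:g}; recomputing", stacklevel=2
        )
        m2 = m0 / 5.0
    m4 = get("M4")
    if math.isnan(m4):
        m4 = 2.0 * math.degrees(math.atan(m3 / (2.0 * m2)))
    m5 = get("M5")
    if math.isnan(m5):
        m5 = 0.5 * m3 * m2
    m6, m7 = get("M6"), get("M7")
    if math.isnan(m6) and not math.isnan(m7):
        m6 = m5 + m7
    if not math.isnan(m6) and not math.isnan(m7):
        if abs(m7 - (m6 - m5)) > M7_ROUNDING_TOL:
            warnings.warn(
                f"tabulated M7={m7:g} violates M6-M5={m6 - m5:g}; recomputing",
                stacklevel=2,
            )
    conf = _finish_conformation(m0=m0, m1=m1, m3=m3, m4=m4, m5=m5, m6=m6)
    conf.validate()
    return conf
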