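"""Centre-of-pressure computation from force-plate wrenches.

Axis convention (fixed throughout the package): right-handed laboratory
frame with x anterior (AP), y to the stander's left (ML), z vertically up.
A plate wrench is the 3-D force and the 3-D moment of the ground-reaction
load expressed about the origin of the plate's top surface.

The centre of pressure on a horizontal plane is *defined* as the point
about which the horizontal components of the wrench's moment vanish.  For a
wrench (F, M) expressed at the surface origin, the zero-moment point on the
surface itself is

    x = -M_y / F_z,      y = M_x / F_z

and on a parallel plane ``delta_h`` above the surface

    x' = (delta_h * F_x - M_y) / F_z = x + delta_h * F_x / F_z
    y' = (M_x + delta_h * F_y) / F_z = y + delta_h * F_y / F_z.

Every formula below is derived from that single zero-moment contract, so a
change of sign convention is localized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .common import NoStanceError

#: Default vertical-force threshold below which a sample carries no usable
#: stance information (CoP is a 0/0 limit as the plate unloads).
DEFAULT_FZ_THRESHOLD = 10.0  # N


@dataclass
class PlateWrench:
    """Force and moment time series of one plate, at its surface origin.

    Parameters
    ----------
    force : ndarray, shape (n, 3)
        F_x (AP, anterior +), F_y (ML, left +), F_z (vertical, up +) in N.
    moment : ndarray, shape (n, 3)
        Moments about the plate-surface origin, N·m, same axes.
    surface_height : float
        Height of the plate surface above the laboratory floor, m.
    fs : float
        Sampling rate, Hz.
    """

    force: np.ndarray
    moment: np.ndarray
    surface_height: float = 0.0
    fs: float = 100.0
    name: str = ""

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.force.ndim != 2 or self.force.shape[1] != 3:
            raise ValueError("force must have shape (n, 3)")
        if self.moment.shape != self.force.shape:
            raise ValueError("moment must match force shape")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.force.shape[0]


@dataclass
class CoPSeries:
    """Planar centre-of-pressure trajectory at a stated reference plane.

    ``valid_mask`` flags samples trustworthy for downstream statistics;
    masked samples hold NaN and are excluded from every correlation.
    """

    x: np.ndarray
    y: np.ndarray
    reference_height: float = 0.0
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.x.shape:
                raise ValueError("valid_mask must match series length")
        if not np.all(np.isfinite(self.x[self.valid_mask])):
            raise ValueError("non-finite CoP at samples flagged valid")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    def component(self, direction) -> np.ndarray:
        """Return the AP (x) or ML (y) coordinate array."""
        from .common import Direction

        return self.x if Direction(direction) is Direction.AP else self.y


def cop_from_wrench(
    w: PlateWrench, fz_threshold: float = DEFAULT_FZ_THRESHOLD
) -> CoPSeries:
    """Centre of pressure of a wrench on its own plate surface.

    Samples with ``|F_z| < fz_threshold`` are masked invalid (the quotient
    blows up as the plate unloads).

    Raises
    ------
    NoStanceError
        If every sample is below the threshold.
    """
    return project_cop_to_height(w, 0.0, fz_threshold=fz_threshold)


def project_cop_to_height(
    w: PlateWrench, delta_h: float, fz_threshold: float = DEFAULT_FZ_THRESHOLD
) -> CoPSeries:
    """Zero-horizontal-moment point of ``w`` on the plane ``delta_h`` above
    the plate surface (a "force structure" plane).

    With no shear force the CoP is independent of ``delta_h``; with shear,
    the point shifts by ``delta_h * F_horizontal / F_z``.  Projection is
    additive in the plane offset: projecting by h1 then h2 equals
    projecting by h1 + h2.
    """
    fx, fy, fz = w.force[:, 0], w.force[:, 1], w.force[:, 2]
    mx, my = w.moment[:, 0], w.moment[:, 1]
    valid = np.abs(fz) >= fz_threshold
    if not np.any(valid):
        raise NoStanceError(
            f"no stance detected: all {w.n_samples} samples have "
            f"|F_z| < {fz_threshold} N"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (delta_h * fx - my) / fz
        y = (mx + delta_h * fy) / fz
    x[~valid] = np.nan
    y[~valid] = np.nan
    return CoPSeries(
        x=x, y=y, reference_height=w.surface_height + delta_h, valid_mask=valid
    )


def combine_cop(
    cop_a: CoPSeries,
    fz_a: np.ndarray,
    cop_b: CoPSeries,
    fz_b: np.ndarray,
    fz_threshold: float = DEFAULT_FZ_THRESHOLD,
) -> CoPSeries:
    """Load-weighted combination of two per-limb CoPs (the global CoP).

    Both inputs must already sit at the same reference plane; project
    first if the support heights differ.  A limb whose sample is invalid
    contributes zero weight; samples whose total usable load falls below
    ``fz_threshold`` are masked.  The result always lies on the segment
    between the two per-limb points.
    """
    if abs(cop_a.reference_height - cop_b.reference_height) > 1e-12:
        raise ValueError(
            "reference-height mismatch: "
            f"{cop_a.reference_height} vs {cop_b.reference_height} m; "
            "project both CoPs to a common plane before combining"
        )
    if cop_a.n_samples != cop_b.n_samples:
        raise ValueError("CoP series lengths differ")
    fz_a = np.asarray(fz_a, dtype=float)
    fz_b = np.asarray(fz_b, dtype=float)
    wa = np.where(cop_a.valid_mask, fz_a, 0.0)
    wb = np.where(cop_b.valid_mask, fz_b, 0.0)
    total = wa + wb
    valid = total >= fz_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (np.where(wa > 0, cop_a.x, 0.0) * wa + np.where(wb > 0, cop_b.x, 0.0) * wb) / total
        y = (np.where(wa > 0, cop_a.y, 0.0) * wa + np.where(wb > 0, cop_b.y, 0.0) * wb) / total
    x[~valid] = np.nan
    y[~valid] = np.nan
    return CoPSeries(
        x=x, y=y, reference_height=cop_a.reference_height, valid_mask=valid
    )


def weight_share(
    fz_a: np.ndarray, fz_b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Fraction of total vertical load carried by limb A, per sample.

    Returns the share series (NaN where the total load is zero) and its
    trial mean over valid samples.
    """
    fz_a = np.asarray(fz_a, dtype=float)
    fz_b = np.asarray(fz_b, dtype=float)
    if np.any(fz_a < -1e-9) or np.any(fz_b < -1e-9):
        raise ValueError("vertical forces must be non-negative")
    total = fz_a + fz_b
    with np.errstate(divide="ignore", invalid="ignore"):
        share = fz_a / total
    share[total <= 0] = np.nan
    valid = np.isfinite(share)
    if not np.any(valid):
        raise NoStanceError("no stance detected: zero total load throughout")
    return share, float(np.mean(share[valid]))


def pin_location(
    ankle: np.ndarray, met5: np.ndarray, fraction: float = 0.66
) -> np.ndarray:
    """Point a given fraction of the way from the ankle joint centre to the
    distal head of the 5th metatarsal (the pin axis placement rule)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    ankle = np.asarray(ankle, dtype=float)
    met5 = np.asarray(met5, dtype=float)
    return ankle + fraction * (met5 - ankle)
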