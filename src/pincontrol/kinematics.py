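"""Marker-based kinematics: segmental CoM, filtering, differentiation and
per-marker height/excursion statistics.

All positions are metres in the laboratory frame (x anterior, y left,
z up, z measured above the support surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .common import Direction, GapError

DEFAULT_MARKER_CUTOFF = 10.0  # Hz, markers and forces
DEFAULT_ACC_CUTOFF = 5.0  # Hz, before double differentiation
DEFAULT_MAX_GAP = 10  # samples


@dataclass
class MarkerSet:
    """Labelled 3-D marker trajectories.

    ``positions`` has shape (n_samples, n_markers, 3); ``gap_mask`` is True
    where a marker sample is missing (to be interpolated before use).
    """

    labels: list[str]
    positions: np.ndarray
    fs: float
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n, m, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("label count must match marker count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate marker labels")
        if self.gap_mask is None:
            self.gap_mask = ~np.all(np.isfinite(self.positions), axis=2)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != self.positions.shape[:2]:
                raise ValueError("gap_mask must have shape (n, m)")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not in set") from None

    def trajectory(self, label: str) -> np.ndarray:
        """(n, 3) trajectory of one marker (gaps not interpolated)."""
        return self.positions[:, self.index(label), :]


@dataclass
class SegmentDef:
    """One body segment of the anthropometric model."""

    name: str
    mass_fraction: float
    com_fraction: float  # CoM position along proximal -> distal axis
    proximal: str  # marker label
    distal: str  # marker label


@dataclass
class AnthropometricTable:
    """Per-segment mass fractions and CoM fractions.

    Mass fractions must sum to 1 (within 1e-6): the segmental CoM is a
    convex combination of segment CoMs.
    """

    segments: list[SegmentDef]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, not 1")

    @classmethod
    def from_csv(cls, path) -> "AnthropometricTable":
        import csv

        segs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                segs.append(
                    SegmentDef(
                        name=row["segment"],
                        mass_fraction=float(row["massfrac"]),
                        com_fraction=float(row["comfrac"]),
                        proximal=row["proximal_label"],
                        distal=row["distal_label"],
                    )
                )
        return cls(segs)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(
                ["segment", "massfrac", "comfrac", "proximal_label", "distal_label"]
            )
            for s in self.segments:
                wr.writerow(
                    [s.name, repr(s.mass_fraction), repr(s.com_fraction),
                     s.proximal, s.distal]
                )


@dataclass
class CoMSeries:
    """Whole-body CoM horizontal position and its derivatives.

    ``position`` has shape (n, 2) with columns (AP, ML); velocity and
    acceleration are filled in by :func:`com_acceleration` and carry the
    filter settings used in ``meta``.
    """

    position: np.ndarray
    fs: float
    velocity: np.ndarray | None = None
    acceleration: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] != 2:
            raise ValueError("position must have shape (n, 2)")

    @property
    def n_samples(self) -> int:
        return self.position.shape[0]

    def component(self, direction, which: str = "position") -> np.ndarray:
        col = 0 if Direction(direction) is Direction.AP else 1
        arr = getattr(self, which)
        if arr is None:
            raise ValueError(f"{which} has not been computed")
        return arr[:, col]


def _interpolate_gaps(values: np.ndarray, gaps: np.ndarray, max_gap: int,
                      label: str) -> np.ndarray:
    """Linearly interpolate missing samples of one marker coordinate."""
    if not gaps.any():
        return values
    runs = _gap_runs(gaps)
    longest = max(e - s for s, e in runs)
    if longest > max_gap:
        raise GapError(
            f"marker {label!r} has a gap of {longest} samples "
            f"(max interpolatable run is {max_gap})"
        )
    out = values.copy()
    idx = np.arange(values.shape[0])
    good = ~gaps
    if good.sum() < 2:
        raise GapError(f"marker {label!r} has too few valid samples")
    out[gaps] = np.interp(idx[gaps], idx[good], values[good])
    return out


def _gap_runs(gaps: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of consecutive True runs."""
    padded = np.concatenate([[False], gaps, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def fill_gaps(markers: MarkerSet, max_gap: int = DEFAULT_MAX_GAP) -> MarkerSet:
    """Return a copy with marker gaps linearly interpolated (runs longer
    than ``max_gap`` samples raise :class:`GapError`)."""
    pos = markers.positions.copy()
    for j, label in enumerate(markers.labels):
        gaps = markers.gap_mask[:, j]
        if gaps.any():
            for c in range(3):
                pos[:, j, c] = _interpolate_gaps(
                    pos[:, j, c], gaps, max_gap, label
                )
    return MarkerSet(
        labels=list(markers.labels),
        positions=pos,
        fs=markers.fs,
        gap_mask=np.zeros_like(markers.gap_mask),
    )


def segmental_com(
    markers: MarkerSet,
    table: AnthropometricTable,
    max_gap: int = DEFAULT_MAX_GAP,
) -> CoMSeries:
    """Whole-body CoM position from a segmental anthropometric model.

    CoM = sum over segments of massfrac * (proximal + comfrac * (distal -
    proximal)), using the segment-defining markers.  Marker gaps up to
    ``max_gap`` samples are linearly interpolated; a missing marker raises
    an error naming the segment.
    """
    filled = fill_gaps(markers, max_gap=max_gap)
    com = np.zeros((filled.n_samples, 3))
    for seg in table.segments:
        try:
            prox = filled.trajectory(seg.proximal)
            dist = filled.trajectory(seg.distal)
        except KeyError as exc:
            raise KeyError(
                f"segment {seg.name!r}: {exc.args[0]}"
            ) from None
        com += seg.mass_fraction * (
            prox + seg.com_fraction * (dist - prox)
        )
    return CoMSeries(position=com[:, :2], fs=markers.fs,
                     meta={"model": "segmental", "n_segments": len(table.segments)})


def lowpass(
    series: np.ndarray, cutoff: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0 (DC gain exactly 1)."""
    series = np.asarray(series, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def second_difference(series: np.ndarray, fs: float) -> np.ndarray:
    """Central second difference along axis 0.

    Interior samples use (x[i+1] - 2 x[i] + x[i-1]) * fs**2; each endpoint
    reuses the one-sided stencil anchored at its neighbour (identical
    arithmetic, shifted by one sample).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 5:
        raise ValueError("need at least 5 samples to differentiate")
    acc = np.empty_like(series)
    acc[1:-1] = (series[2:] - 2.0 * series[1:-1] + series[:-2]) * fs**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def com_acceleration(
    com: CoMSeries,
    cutoff: float = DEFAULT_ACC_CUTOFF,
    order: int = 4,
) -> CoMSeries:
    """Low-pass filter the CoM position, then differentiate twice.

    Returns a new :class:`CoMSeries` whose velocity (central first
    difference) and acceleration (central second difference) derive from
    the filtered position; filter settings are recorded in ``meta``.
    """
    if com.n_samples < 5:
        raise ValueError("series too short to differentiate")
    pos_f = lowpass(com.position, cutoff, com.fs, order=order)
    vel = np.gradient(pos_f, 1.0 / com.fs, axis=0)
    acc = second_difference(pos_f, com.fs)
    meta = dict(com.meta)
    meta.update({"acc_cutoff_hz": cutoff, "acc_filter_order": order,
                 "differentiator": "central-2nd-difference"})
    return CoMSeries(position=pos_f, fs=com.fs, velocity=vel,
                     acceleration=acc, meta=meta)


def marker_height_excursion(
    markers: MarkerSet,
    direction,
    max_gap: int = DEFAULT_MAX_GAP,
    use_range: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (mean height above support surface, total linear
    movement) in one horizontal direction.

    Total linear movement is the 1-D path length: the sum of absolute
    sample-to-sample displacements of the AP or ML coordinate.  With
    ``use_range=True`` the peak-to-peak excursion is returned instead.
    """
    if markers.n_markers < 3:
        raise ValueError(
            f"need at least 3 markers, got {markers.n_markers} "
            "(correlation undefined downstream)"
        )
    filled = fill_gaps(markers, max_gap=max_gap)
    axis = 0 if Direction(direction) is Direction.AP else 1
    coords = filled.positions[:, :, axis]
    heights = filled.positions[:, :, 2].mean(axis=0)
    if use_range:
        movement = coords.max(axis=0) - coords.min(axis=0)
    else:
        movement = np.sum(np.abs(np.diff(coords, axis=0)), axis=0)
    return heights, movement
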