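"""Inverted-pendulum correlation statistics and their aggregation.

The kinetic test correlates d(t) = CoP(t) - CoM(t) with the CoM
horizontal acceleration over a whole trial; a limb that conforms to the
single-segment inverted-pendulum relation x'' = (g/h)(x - u) yields
r -> -1, a non-contributing ("pin") limb yields r near 0.  The kinematic
test correlates, across markers, each marker's mean height above the
support surface with its total linear movement; a rigid pendulum yields
r -> +1.

Per-trial correlations are aggregated on the variance-stabilizing scale
z = arctanh(r): trials are averaged within subject first, then subjects
are combined with a t-based 95% interval, and all three quantities are
back-transformed with tanh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .common import (
    Condition,
    DegenerateTrialError,
    Definition,
    Direction,
    Group,
    Limb,
)
from .kinematics import (
    DEFAULT_ACC_CUTOFF,
    DEFAULT_MARKER_CUTOFF,
    AnthropometricTable,
    CoMSeries,
    MarkerSet,
    com_acceleration,
    lowpass,
    marker_height_excursion,
    segmental_com,
)
from .kinetics import (
    DEFAULT_FZ_THRESHOLD,
    CoPSeries,
    combine_cop,
    cop_from_wrench,
    project_cop_to_height,
)
from .trialio import TrialRecording

_R_CLAMP = 1.0 - 1e-9


@dataclass
class CorrelationResult:
    """One Pearson correlation with its grouping metadata."""

    r: float
    n_samples: int
    direction: Direction
    limb: Limb | None
    definition: Definition
    condition: Condition
    group: Group
    subject_id: str
    trial_id: str

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        self.definition = Definition(self.definition)
        self.condition = Condition(self.condition)
        self.group = Group(self.group)
        if self.limb is not None:
            self.limb = Limb(self.limb)
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series.

    Raises :class:`DegenerateTrialError` if either series has zero
    variance (a silent NaN would corrupt group means downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    # scale-aware zero-variance check: mean subtraction of a constant
    # series leaves O(eps * |mean|) residue, not exact zeros
    eps = np.finfo(float).eps * np.sqrt(x.size)
    if sx <= 8 * eps * max(np.abs(x).max(), 1e-300) or sy <= 8 * eps * max(
        np.abs(y).max(), 1e-300
    ):
        raise DegenerateTrialError(
            "degenerate trial: zero variance in a correlation input"
        )
    r = float(np.dot(xc, yc) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def kinetic_ip_corr(
    cop: CoPSeries,
    com: CoMSeries,
    direction: Direction,
    limb: Limb,
    condition: Condition,
    group: Group,
    subject_id: str = "",
    trial_id: str = "",
) -> CorrelationResult:
    """Kinetic inverted-pendulum correlation for one limb and direction:
    Pearson r between CoP - CoM and the CoM acceleration over the jointly
    valid samples of the full trial."""
    direction = Direction(direction)
    if cop.n_samples != com.n_samples:
        raise ValueError("CoP and CoM series lengths differ")
    d = cop.component(direction) - com.component(direction, "position")
    acc = com.component(direction, "acceleration")
    valid = cop.valid_mask & np.isfinite(d) & np.isfinite(acc)
    if valid.sum() < 3:
        raise ValueError("fewer than 3 jointly valid samples")
    r = pearson_r(d[valid], acc[valid])
    return CorrelationResult(
        r=r,
        n_samples=int(valid.sum()),
        direction=direction,
        limb=limb,
        definition=Definition.KINETIC,
        condition=condition,
        group=group,
        subject_id=subject_id,
        trial_id=trial_id,
    )


def kinematic_ip_corr(
    heights: np.ndarray,
    movements: np.ndarray,
    direction: Direction,
    condition: Condition,
    group: Group,
    subject_id: str = "",
    trial_id: str = "",
) -> CorrelationResult:
    """Kinematic inverted-pendulum correlation: Pearson r across markers
    between mean height above the support surface and total linear
    movement in one direction."""
    heights = np.asarray(heights, dtype=float)
    movements = np.asarray(movements, dtype=float)
    if heights.size < 3:
        raise ValueError("need at least 3 markers")
    r = pearson_r(heights, movements)
    return CorrelationResult(
        r=r,
        n_samples=int(heights.size),
        direction=direction,
        limb=None,
        definition=Definition.KINEMATIC,
        condition=condition,
        group=group,
        subject_id=subject_id,
        trial_id=trial_id,
    )


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing transform z = arctanh(r), clamping |r| = 1 to
    1 - 1e-9 with a warning."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn(
            "correlation of magnitude 1 clamped before transformation",
            stacklevel=2,
        )
        arr = np.clip(arr, -_R_CLAMP, _R_CLAMP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def fisher_aggregate(
    rs,
) -> tuple[float, float | None, float | None]:
    """Aggregate correlations on the transformed scale.

    Returns the back-transformed mean and t-based 95% confidence bounds
    (tanh of mean_z +/- t_{0.975, k-1} * SD(z) / sqrt(k)).  With a single
    value the CI is undefined and reported as None.
    """
    rs = np.atleast_1d(np.asarray(rs, dtype=float))
    if rs.size == 0:
        raise ValueError("empty correlation list")
    z = fisher_z(rs)
    mean_z = float(np.mean(z))
    mean_r = float(np.tanh(mean_z))
    if rs.size == 1:
        return mean_r, None, None
    sd = float(np.std(z, ddof=1))
    half = sps.t.ppf(0.975, rs.size - 1) * sd / np.sqrt(rs.size)
    return mean_r, float(np.tanh(mean_z - half)), float(np.tanh(mean_z + half))


@dataclass
class AnalysisConfig:
    """Settings of the trial analysis chain (recorded in outputs)."""

    fz_threshold: float = DEFAULT_FZ_THRESHOLD
    marker_cutoff: float = DEFAULT_MARKER_CUTOFF
    acc_cutoff: float = DEFAULT_ACC_CUTOFF
    filter_order: int = 4
    max_gap: int = 10
    movement_as_range: bool = False
    anthropometric_table: AnthropometricTable | None = None

    def table(self) -> AnthropometricTable:
        if self.anthropometric_table is None:
            from .body import default_anthropometric_table

            return default_anthropometric_table()
        return self.anthropometric_table


def limb_cop_series(
    recording: TrialRecording, config: AnalysisConfig | None = None
) -> tuple[dict[Limb, CoPSeries], dict[Limb, np.ndarray]]:
    """Per-limb and combined CoP series of a recording.

    Each limb's wrench is projected from the plate surface to its support
    plane ("force structure") when the heights differ; the combined CoP
    is formed on the common (highest) support plane.
    """
    cfg = config or AnalysisConfig()
    cops: dict[Limb, CoPSeries] = {}
    fzs: dict[Limb, np.ndarray] = {}
    for role in (Limb.CONSTRAINED, Limb.UNCONSTRAINED):
        side = recording.side_of(role)
        w = recording.wrench(side)
        delta = recording.support_heights[side] - w.surface_height
        if abs(delta) > 1e-12:
            cops[role] = project_cop_to_height(w, delta, cfg.fz_threshold)
        else:
            cops[role] = cop_from_wrench(w, cfg.fz_threshold)
        fzs[role] = w.force[:, 2]

    top = max(c.reference_height for c in cops.values())
    projected = {}
    for role, cop in cops.items():
        if abs(cop.reference_height - top) > 1e-12:
            side = recording.side_of(role)
            w = recording.wrench(side)
            projected[role] = project_cop_to_height(
                w, top - w.surface_height, cfg.fz_threshold
            )
        else:
            projected[role] = cop
    cops[Limb.TOTAL] = combine_cop(
        projected[Limb.CONSTRAINED],
        fzs[Limb.CONSTRAINED],
        projected[Limb.UNCONSTRAINED],
        fzs[Limb.UNCONSTRAINED],
        cfg.fz_threshold,
    )
    fzs[Limb.TOTAL] = fzs[Limb.CONSTRAINED] + fzs[Limb.UNCONSTRAINED]
    return cops, fzs


def com_from_markers(
    recording: TrialRecording, config: AnalysisConfig | None = None
) -> CoMSeries:
    """Segmental CoM of a recording's markers, filtered and twice
    differentiated."""
    cfg = config or AnalysisConfig()
    markers = recording.markers
    filtered = MarkerSet(
        labels=list(markers.labels),
        positions=lowpass(
            markers.positions, cfg.marker_cutoff, markers.fs, cfg.filter_order
        ),
        fs=markers.fs,
        gap_mask=markers.gap_mask,
    )
    com = segmental_com(filtered, cfg.table(), max_gap=cfg.max_gap)
    return com_acceleration(com, cutoff=cfg.acc_cutoff, order=cfg.filter_order)


def analyze_trial(
    recording: TrialRecording, config: AnalysisConfig | None = None
) -> list[CorrelationResult]:
    """Full per-trial analysis: 6 kinetic correlations (3 limb roles x 2
    directions) plus 2 kinematic correlations (2 directions)."""
    cfg = config or AnalysisConfig()
    cops, _ = limb_cop_series(recording, cfg)
    com = com_from_markers(recording, cfg)

    meta = dict(
        condition=recording.condition,
        group=recording.group,
        subject_id=recording.subject_id,
        trial_id=str(recording.meta.get("trial_id", "")),
    )
    results = [
        kinetic_ip_corr(cops[limb], com, direction, limb=limb, **meta)
        for direction in Direction
        for limb in (Limb.CONSTRAINED, Limb.UNCONSTRAINED, Limb.TOTAL)
    ]

    support = min(recording.support_heights.values())
    markers = recording.markers
    lowpassed = MarkerSet(
        labels=list(markers.labels),
        positions=lowpass(
            markers.positions, cfg.marker_cutoff, markers.fs, cfg.filter_order
        ),
        fs=markers.fs,
        gap_mask=markers.gap_mask,
    )
    for direction in Direction:
        heights, movement = marker_height_excursion(
            lowpassed, direction, max_gap=cfg.max_gap,
            use_range=cfg.movement_as_range,
        )
        results.append(
            kinematic_ip_corr(heights - support, movement, direction, **meta)
        )
    return results


def estimate_pendulum_ratio(
    recording: TrialRecording,
    direction: Direction = Direction.AP,
    config: AnalysisConfig | None = None,
) -> float:
    """Least-squares estimate of g/h from one trial.

    Regresses the measured CoM acceleration on (CoM - total CoP).  Both
    series are band-limited with the same low-pass settings (regressing a
    filtered response on an unfiltered regressor would bias the slope
    toward zero).
    """
    cfg = config or AnalysisConfig()
    cops, _ = limb_cop_series(recording, cfg)
    com = com_from_markers(recording, cfg)
    direction = Direction(direction)
    cop = lowpass(
        cops[Limb.TOTAL].component(direction),
        cfg.acc_cutoff,
        recording.fs,
        cfg.filter_order,
    )
    d = com.component(direction, "position") - cop
    acc = com.component(direction, "acceleration")
    d = d - d.mean()
    return float(np.dot(d, acc - acc.mean()) / np.dot(d, d))


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy long-format table (one row per trial x definition x direction
    x limb), suitable for external mixed-ANOVA tools."""
    rows = []
    for res in results:
        rows.append(
            {
                "definition": res.definition.value,
                "direction": res.direction.value,
                "group": res.group.value,
                "condition": res.condition.value,
                "limb": res.limb.value if res.limb else "",
                "subject_id": res.subject_id,
                "trial_id": res.trial_id,
                "n_samples": res.n_samples,
                "r": res.r,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SummaryRow:
    """One cell of the summary: back-transformed mean r with 95% CI."""

    definition: Definition
    direction: Direction
    group: Group
    limb: Limb | None
    condition: Condition
    mean_r: float
    ci_low: float | None
    ci_high: float | None
    n_subjects: int

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (
            self.ci_low - 1e-12 <= self.mean_r <= self.ci_high + 1e-12
        ):
            raise ValueError("confidence bounds must bracket the mean")


def _subject_level(df: pd.DataFrame) -> pd.DataFrame:
    """Average trial correlations within subject on the z scale."""
    df = df.copy()
    df["z"] = fisher_z(df["r"].to_numpy())
    keys = ["definition", "direction", "group", "limb", "condition", "subject_id"]
    out = df.groupby(keys, as_index=False)["z"].mean()
    out["r"] = np.tanh(out["z"])
    return out


def summary_table(
    results: list[CorrelationResult] | pd.DataFrame,
    two_stage: bool = True,
) -> pd.DataFrame:
    """Aggregate correlations into the summary layout: back-transformed
    mean r with 95% CI per (definition x direction x group x limb x
    condition).

    ``two_stage=True`` (default) averages the trials of each subject on
    the transformed scale first, then aggregates across subjects;
    ``two_stage=False`` pools all trials directly.  Rows are ordered
    kinetic before kinematic, AP before ML.  Cells with no data are
    reported (empty counts) rather than silently dropped.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise ValueError("no correlation results to summarize")
    pooled = _subject_level(df) if two_stage else df

    rows = []
    keys = ["definition", "direction", "group", "limb", "condition"]
    order = {
        "definition": [d.value for d in Definition],
        "direction": [d.value for d in Direction],
        "limb": [Limb.UNCONSTRAINED.value, Limb.CONSTRAINED.value,
                 Limb.TOTAL.value, ""],
        "condition": [c.value for c in Condition],
    }
    for key_vals, sub in pooled.groupby(keys, sort=False):
        mean_r, lo, hi = fisher_aggregate(sub["r"].to_numpy())
        row = dict(zip(keys, key_vals))
        row.update(
            mean_r=mean_r,
            ci_low=lo if lo is not None else np.nan,
            ci_high=hi if hi is not None else np.nan,
            n_subjects=int(sub["subject_id"].nunique()),
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        keys,
        key=lambda col: (
            col.map({v: i for i, v in enumerate(order[col.name])})
            if col.name in order
            else col
        ),
    ).reset_index(drop=True)
    return out


def analyze_cohort(
    recordings,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Analyze an iterable of recordings into the tidy long-format table."""
    results: list[CorrelationResult] = []
    for rec in recordings:
        results.extend(analyze_trial(rec, config))
    return results_to_frame(results)
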