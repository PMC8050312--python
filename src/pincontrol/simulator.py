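"""Synthetic quiet-standing trials from a pin-constrained dual-support
inverted pendulum.

The body is a single-segment inverted pendulum, integrated independently
in the AP and ML directions:

    x'' = (g / h) * (x - u_total)

where ``u_total`` is the realized combined centre of pressure.  A delayed
PD controller with low-pass-filtered exploratory noise commands the total
CoP.  In AP the command is realized through the controller limb's
within-foot CoP, with the pin limb's CoP fixed at the pin location when a
pin side is set.  In ML the command is realized by modulating the
vertical-load share between two per-limb CoPs held near the foot centres
(load/unload mechanism) — per-limb ML CoPs barely move, while the
combined CoP tracks the command.

Integration is fixed-step semi-implicit Euler at ``oversample`` times the
output rate (default 1000 Hz internal), decimated to ``fs``.  The stored
ground-truth acceleration equals ``(g/h) * (x - u_total)`` at the stored
samples exactly, so the pendulum relation can be reconstructed from the
outputs to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .common import (
    Condition,
    ConfigError,
    Group,
    Limb,
    Side,
    UnstableSimulationError,
)
from .body import MarkerSpec, default_marker_layout
from .kinematics import CoMSeries, MarkerSet
from .kinetics import CoPSeries, PlateWrench, pin_location
from .trialio import TrialRecording

# Clamp bounds for the instantaneous load share; excursions beyond these
# would imply near-single-support standing.
_SHARE_MIN, _SHARE_MAX = 0.02, 0.98
# Divergence bound: foot length plus generous margin, m.
_DIVERGENCE_BOUND = 0.5
# Re-seed attempts per cohort trial before giving up.
_MAX_TRIAL_ATTEMPTS = 5


@dataclass
class PendulumParams:
    """Single-segment inverted-pendulum constants."""

    body_mass: float = 75.0  # kg
    com_height: float = 0.95  # m, support surface to CoM
    gravity: float = 9.81  # m / s^2

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.com_height <= 0 or self.gravity <= 0:
            raise ConfigError("pendulum parameters must be strictly positive")
        if self.com_height >= 2.0:
            raise ConfigError("com_height must be below 2.0 m")


@dataclass
class ControllerParams:
    """Delayed-PD CoP controller settings.

    ``kp`` multiplies the delayed CoM position error, ``kd`` (seconds) the
    delayed CoM velocity.  ``kp > 1`` is required: with u ~ kp * x the
    closed loop of x'' = (g/h)(x - u) is only stabilizable for kp > 1.
    Exploratory noise is white Gaussian low-passed at ``noise_cutoff`` and
    scaled to ``noise_sd``.  ``fb_share_gain`` (1/s) is the integral gain
    pulling the load share to 0.5 in the FB condition;
    ``ec_noise_multiplier`` scales the noise in the EC condition.
    """

    kp: float = 1.12
    kd: float = 0.35  # s
    delay: float = 0.15  # s
    noise_sd: float = 0.0045  # m
    noise_cutoff: float = 5.0  # Hz
    noise_highpass: float = 0.3  # Hz, lower band edge of exploratory noise
    drift_sd: float = 0.012  # m, SD of the slow set-point wander
    drift_cutoff: float = 0.1  # Hz
    fb_share_gain: float = 0.5  # 1/s
    ec_noise_multiplier: float = 1.4
    within_foot_noise_sd: float = 0.0005  # m, controller-limb CoP jitter
    within_foot_cutoff: float = 2.0  # Hz

    def __post_init__(self) -> None:
        if self.kp <= 1.0:
            raise ConfigError(
                f"kp must exceed 1 for closed-loop stability, got {self.kp}"
            )
        if self.delay < 0:
            raise ConfigError("delay must be non-negative")
        if self.noise_sd < 0 or self.within_foot_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.ec_noise_multiplier < 1.0:
            raise ConfigError("ec_noise_multiplier must be >= 1")


@dataclass
class StanceGeometry:
    """Foot placement and pin-constraint geometry.

    AP origin is at the ankle joint centres; the foot spans
    ``[-ankle_setback, foot_length - ankle_setback]`` in AP.  Foot centres
    sit at ML = +/- stance_width / 2 (left positive).  The pin axis lies
    ``pin_fraction`` of the way from the ankle to the 5th-metatarsal head.
    ``block_height`` raises both support surfaces (constraint device plus
    matching block) above the plates.
    """

    stance_width: float = 0.24  # m between foot centres
    foot_length: float = 0.25  # m
    ankle_to_met5: float = 0.15  # m
    pin_fraction: float = 0.66
    pin_side: Side | None = Side.LEFT
    block_height: float = 0.0  # m
    ankle_setback: float = 0.05  # m, heel behind the ankle

    def __post_init__(self) -> None:
        if isinstance(self.pin_side, str):
            self.pin_side = None if self.pin_side == "none" else Side(self.pin_side)
        if not 0.0 <= self.pin_fraction <= 1.0:
            raise ConfigError("pin_fraction must lie in [0, 1]")
        if self.foot_length <= 0 or self.stance_width <= 0:
            raise ConfigError("foot dimensions must be positive")
        if not 0 <= self.ankle_to_met5 <= self.foot_length:
            raise ConfigError("ankle_to_met5 must lie within the foot")
        ap = self.pin_ap
        lo, hi = self.foot_ap_bounds
        if not lo <= ap <= hi:
            raise ConfigError(
                f"pin CoP at AP {ap:.3f} m lies outside the foot "
                f"bounds [{lo:.3f}, {hi:.3f}] m"
            )

    @property
    def foot_ap_bounds(self) -> tuple[float, float]:
        return (-self.ankle_setback, self.foot_length - self.ankle_setback)

    @property
    def pin_ap(self) -> float:
        """AP coordinate of the pin axis (ankle at 0)."""
        return float(
            pin_location(np.zeros(1), np.array([self.ankle_to_met5]),
                         self.pin_fraction)[0]
        )

    def foot_center_ml(self, side: Side) -> float:
        return self.stance_width / 2 * (1.0 if side is Side.LEFT else -1.0)


@dataclass
class TrialConfig:
    """Complete specification of one synthetic trial."""

    duration: float = 60.0  # s
    fs: float = 100.0  # Hz
    condition: Condition = Condition.EO
    group: Group = Group.TPU
    mean_load_share: float = 0.6  # fraction on the unconstrained/intact limb
    seed: int = 0
    pendulum: PendulumParams = field(default_factory=PendulumParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    geometry: StanceGeometry = field(default_factory=StanceGeometry)
    # CoM equilibrium ahead of the ankles; None centres the set-point in
    # the reachable combined-CoP span (pin location and load share shrink
    # the backward control authority, so a fixed value risks falls).
    ap_setpoint: float | None = None
    init_offset_ap: float = 0.0  # m, initial CoM offset from equilibrium
    init_offset_ml: float = 0.0
    marker_noise_sd: float = 0.0003  # m
    oversample: int = 10
    subject_id: str = "S01"
    trial_id: str = "T01"

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.group = Group(self.group)
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ConfigError("duration * fs must be a positive integer")
        if not 0.0 < self.mean_load_share < 1.0:
            raise ConfigError("mean_load_share must lie in (0, 1)")
        if self.oversample < 1:
            raise ConfigError("oversample must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class SyntheticTrial:
    """A generated trial with its ground truth."""

    recording: TrialRecording
    truth_com: CoMSeries
    truth_total_cop: CoPSeries
    truth_share: np.ndarray
    config: TrialConfig
    degenerate: bool = False
    saturation_count: int = 0


def pd_cop_command(
    com_pos_delayed: float,
    com_vel_delayed: float,
    params: ControllerParams,
    noise_sample: float = 0.0,
) -> float:
    """Commanded total CoP of the delayed-PD law:
    u = kp * x_delayed + kd * v_delayed + noise."""
    vals = (com_pos_delayed, com_vel_delayed, noise_sample)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite controller input: {vals}")
    return (
        params.kp * com_pos_delayed
        + params.kd * com_vel_delayed
        + noise_sample
    )


def _filtered_noise(
    rng: np.random.Generator,
    n: int,
    sd: float,
    cutoff: float,
    fs: float,
    highpass: float | None = None,
) -> np.ndarray:
    """Causally filtered Gaussian noise rescaled to the target SD.

    Low-passed at ``cutoff``; optionally band-passed with a lower edge at
    ``highpass``.  The exploratory CoP noise is band-passed because the
    closed loop amplifies DC noise by 1 / (kp - 1): very-low-frequency
    exploration is modelled separately by the bounded set-point drift.
    """
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if cutoff < fs / 2:
        if highpass and highpass > 0:
            sos = signal.butter(
                2, [highpass, cutoff], btype="bandpass", fs=fs, output="sos"
            )
        else:
            sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
        white = signal.sosfilt(sos, white)
    s = white.std()
    if s > 0:
        white = white * (sd / s)
    return white


def _effective_noise_sd(cfg: TrialConfig) -> float:
    sd = cfg.controller.noise_sd
    if cfg.condition is Condition.EC:
        sd *= cfg.controller.ec_noise_multiplier
    return sd


def simulate_trial(config: TrialConfig) -> SyntheticTrial:
    """Integrate one trial and emit recording plus ground truth.

    Deterministic: identical config and seed reproduce identical output.
    Raises :class:`UnstableSimulationError` if the closed loop diverges.
    """
    cfg = config
    geom, ctl, pend = cfg.geometry, cfg.controller, cfg.pendulum
    rng = np.random.default_rng(cfg.seed)

    ov = cfg.oversample
    fs_int = cfg.fs * ov
    dt = 1.0 / fs_int
    n_out = cfg.n_samples
    n_int = n_out * ov
    dsteps = int(round(ctl.delay * fs_int))
    omega2 = pend.gravity / pend.com_height

    # Limb A is the controller (unconstrained/intact) limb.
    pin = geom.pin_side
    side_a = (
        Side.RIGHT if pin is Side.LEFT
        else Side.LEFT
    )
    side_b = Side.RIGHT if side_a is Side.LEFT else Side.LEFT
    y_a0 = geom.foot_center_ml(side_a)
    y_b0 = geom.foot_center_ml(side_b)
    ap_lo, ap_hi = geom.foot_ap_bounds
    pin_ap = geom.pin_ap
    has_pin = pin is not None

    sd = _effective_noise_sd(cfg)
    hp = ctl.noise_highpass
    n_ap = _filtered_noise(rng, n_int, sd, ctl.noise_cutoff, fs_int, highpass=hp)
    n_ml = _filtered_noise(rng, n_int, sd, ctl.noise_cutoff, fs_int, highpass=hp)
    # Slow exploratory wander of the postural set-point (VLF sway drift).
    drift_ap = _filtered_noise(rng, n_int, ctl.drift_sd, ctl.drift_cutoff, fs_int)
    drift_ml = _filtered_noise(rng, n_int, ctl.drift_sd, ctl.drift_cutoff, fs_int)
    wf_sd = ctl.within_foot_noise_sd
    wf_a_ap = _filtered_noise(rng, n_int, wf_sd, ctl.within_foot_cutoff, fs_int)
    wf_a_ml = _filtered_noise(rng, n_int, wf_sd, ctl.within_foot_cutoff, fs_int)
    # Pin side carries no within-foot noise; a free limb B does.
    if has_pin:
        wf_b_ap = np.zeros(n_int)
        wf_b_ml = np.zeros(n_int)
    else:
        wf_b_ap = _filtered_noise(rng, n_int, wf_sd, ctl.within_foot_cutoff, fs_int)
        wf_b_ml = _filtered_noise(rng, n_int, wf_sd, ctl.within_foot_cutoff, fs_int)

    share0 = cfg.mean_load_share
    if cfg.ap_setpoint is not None:
        sp_ap = cfg.ap_setpoint
    else:
        foot_mid = 0.5 * (ap_lo + ap_hi)
        if has_pin:
            sp_ap = share0 * foot_mid + (1.0 - share0) * pin_ap
        else:
            sp_ap = foot_mid
    sp_ml0 = share0 * y_a0 + (1.0 - share0) * y_b0

    fb_active = cfg.condition is Condition.FB
    fb_gain = ctl.fb_share_gain if fb_active else 0.0

    # State and output buffers (pure-Python floats in the hot loop).
    kp, kd = ctl.kp, ctl.kd
    x_ap = sp_ap + cfg.init_offset_ap
    v_ap = 0.0
    x_ml = sp_ml0 + cfg.init_offset_ml
    v_ml = 0.0
    sp_ml = sp_ml0
    hist_x_ap = [0.0] * n_int
    hist_v_ap = [0.0] * n_int
    hist_x_ml = [0.0] * n_int
    hist_v_ml = [0.0] * n_int
    n_ap_l = n_ap.tolist()
    n_ml_l = n_ml.tolist()
    drift_ap_l = drift_ap.tolist()
    drift_ml_l = drift_ml.tolist()
    wf = [a.tolist() for a in (wf_a_ap, wf_a_ml, wf_b_ap, wf_b_ml)]
    wf_a_ap_l, wf_a_ml_l, wf_b_ap_l, wf_b_ml_l = wf

    keep = n_out
    out_x = np.empty((keep, 2))
    out_v = np.empty((keep, 2))
    out_a = np.empty((keep, 2))
    out_u = np.empty((keep, 2))
    out_share = np.empty(keep)
    out_cop_a = np.empty((keep, 2))
    out_cop_b = np.empty((keep, 2))
    saturations = 0
    y_span = y_a0 - y_b0

    for k in range(n_int):
        j = k - dsteps
        if j < 0:
            # Before the first delayed sample exists, hold the initial state.
            xd_ap = hist_x_ap[0] if k > 0 else x_ap
            vd_ap = hist_v_ap[0] if k > 0 else v_ap
            xd_ml = hist_x_ml[0] if k > 0 else x_ml
            vd_ml = hist_v_ml[0] if k > 0 else v_ml
        else:
            xd_ap, vd_ap = hist_x_ap[j], hist_v_ap[j]
            xd_ml, vd_ml = hist_x_ml[j], hist_v_ml[j]

        hist_x_ap[k] = x_ap
        hist_v_ap[k] = v_ap
        hist_x_ml[k] = x_ml
        hist_v_ml[k] = v_ml

        ref_ap = sp_ap + drift_ap_l[k]
        ref_ml = sp_ml + drift_ml_l[k]
        u_cmd_ap = ref_ap + kp * (xd_ap - ref_ap) + kd * vd_ap + n_ap_l[k]
        u_cmd_ml = ref_ml + kp * (xd_ml - ref_ml) + kd * vd_ml + n_ml_l[k]

        # ML realization: load/unload between near-fixed per-limb CoPs.
        y_a = y_a0 + wf_a_ml_l[k]
        y_b = y_b0 + wf_b_ml_l[k]
        s = (u_cmd_ml - y_b) / (y_a - y_b)
        if s < _SHARE_MIN:
            s = _SHARE_MIN
            saturations += 1
        elif s > _SHARE_MAX:
            s = _SHARE_MAX
            saturations += 1
        u_ml = s * y_a + (1.0 - s) * y_b

        # AP realization: controller limb's within-foot CoP (pin fixed).
        if has_pin:
            cop_b_ap = pin_ap
            needed = (u_cmd_ap - (1.0 - s) * pin_ap) / s
            cop_a_ap = needed + wf_a_ap_l[k]
            if cop_a_ap < ap_lo:
                cop_a_ap = ap_lo
                saturations += 1
            elif cop_a_ap > ap_hi:
                cop_a_ap = ap_hi
                saturations += 1
        else:
            cop_a_ap = u_cmd_ap + wf_a_ap_l[k]
            cop_b_ap = u_cmd_ap + wf_b_ap_l[k]
            if cop_a_ap < ap_lo:
                cop_a_ap = ap_lo
                saturations += 1
            elif cop_a_ap > ap_hi:
                cop_a_ap = ap_hi
                saturations += 1
            if cop_b_ap < ap_lo:
                cop_b_ap = ap_lo
                saturations += 1
            elif cop_b_ap > ap_hi:
                cop_b_ap = ap_hi
                saturations += 1
        u_ap = s * cop_a_ap + (1.0 - s) * cop_b_ap

        a_ap = omega2 * (x_ap - u_ap)
        a_ml = omega2 * (x_ml - u_ml)

        if k % ov == 0:
            i = k // ov
            out_x[i, 0] = x_ap
            out_x[i, 1] = x_ml
            out_v[i, 0] = v_ap
            out_v[i, 1] = v_ml
            out_a[i, 0] = a_ap
            out_a[i, 1] = a_ml
            out_u[i, 0] = u_ap
            out_u[i, 1] = u_ml
            out_share[i] = s
            out_cop_a[i, 0] = cop_a_ap
            out_cop_a[i, 1] = y_a
            out_cop_b[i, 0] = cop_b_ap
            out_cop_b[i, 1] = y_b

        # Semi-implicit Euler.
        v_ap += dt * a_ap
        x_ap += dt * v_ap
        v_ml += dt * a_ml
        x_ml += dt * v_ml

        if fb_active:
            sp_ml -= dt * fb_gain * (s - 0.5) * y_span

        if abs(x_ap - sp_ap) > _DIVERGENCE_BOUND or abs(x_ml - sp_ml0) > _DIVERGENCE_BOUND:
            raise UnstableSimulationError(
                f"simulation diverged at t = {k * dt:.2f} s with "
                f"kp={kp}, kd={kd}, delay={ctl.delay}; "
                "choose gains inside the stable region"
            )

    degenerate = bool(
        np.ptp(out_x[:, 0]) == 0.0 and np.ptp(out_x[:, 1]) == 0.0
    )

    wrench_a, wrench_b = allocate_limb_wrenches(
        cop_a=out_cop_a,
        cop_b=out_cop_b,
        share=out_share,
        acc=out_a,
        pendulum=pend,
        geometry=geom,
        fs=cfg.fs,
    )

    layout = default_marker_layout()
    markers = generate_marker_set(
        com_position=out_x,
        layout=layout,
        com_height=pend.com_height,
        pivot=(sp_ap, sp_ml0),
        fs=cfg.fs,
        noise_sd=cfg.marker_noise_sd,
        rng=rng,
        support_height=geom.block_height,
    )

    roles = {
        side_a: Limb.UNCONSTRAINED,
        side_b: Limb.CONSTRAINED,
    }
    recording = TrialRecording(
        subject_id=cfg.subject_id,
        group=cfg.group,
        condition=cfg.condition,
        fs=cfg.fs,
        duration=cfg.duration,
        left_wrench=wrench_a if side_a is Side.LEFT else wrench_b,
        right_wrench=wrench_a if side_a is Side.RIGHT else wrench_b,
        markers=markers,
        limb_roles=roles,
        support_heights={
            Side.LEFT: geom.block_height,
            Side.RIGHT: geom.block_height,
        },
        meta={
            "seed": int(cfg.seed),
            "trial_id": cfg.trial_id,
            "degenerate": degenerate,
            "saturation_events": int(saturations),
            "pin_side": pin.value if pin else "none",
            "mean_load_share": cfg.mean_load_share,
            "ap_setpoint": sp_ap,
        },
    )
    truth_com = CoMSeries(
        position=out_x, fs=cfg.fs, velocity=out_v, acceleration=out_a,
        meta={"source": "simulation-truth"},
    )
    truth_cop = CoPSeries(
        x=out_u[:, 0], y=out_u[:, 1], reference_height=geom.block_height
    )
    return SyntheticTrial(
        recording=recording,
        truth_com=truth_com,
        truth_total_cop=truth_cop,
        truth_share=out_share,
        config=cfg,
        degenerate=degenerate,
        saturation_count=saturations,
    )


def allocate_limb_wrenches(
    cop_a: np.ndarray,
    cop_b: np.ndarray,
    share: np.ndarray,
    acc: np.ndarray,
    pendulum: PendulumParams,
    geometry: StanceGeometry,
    fs: float,
) -> tuple[PlateWrench, PlateWrench]:
    """Per-limb plate wrenches realizing the per-limb contact CoPs.

    Vertical dynamics are neglected: Fz_A = share * m * g and
    Fz_B = (1 - share) * m * g at every sample.  The horizontal shear
    m * x'' is split by the same share.  Moments about each plate-surface
    origin are set so that the zero-horizontal-moment point on the contact
    plane (``geometry.block_height`` above the plate) is exactly the
    requested per-limb CoP — so each plate's projected CoP, combined with
    vertical-load weighting, reconstructs the commanded total CoP.
    """
    share = np.asarray(share, dtype=float)
    if np.any(share <= 0.0) or np.any(share >= 1.0):
        raise ValueError("share must lie strictly inside (0, 1)")
    m, g = pendulum.body_mass, pendulum.gravity
    zc = geometry.block_height
    shear = m * np.asarray(acc, dtype=float)  # (n, 2): AP, ML

    wrenches = []
    for cop, frac, name in (
        (cop_a, share, "controller"),
        (cop_b, 1.0 - share, "pin-or-second"),
    ):
        fz = frac * m * g
        fx = frac * shear[:, 0]
        fy = frac * shear[:, 1]
        xc, yc = cop[:, 0], cop[:, 1]
        mx = yc * fz - zc * fy
        my = zc * fx - xc * fz
        mz = xc * fy - yc * fx
        wrenches.append(
            PlateWrench(
                force=np.column_stack([fx, fy, fz]),
                moment=np.column_stack([mx, my, mz]),
                surface_height=0.0,
                fs=fs,
                name=name,
            )
        )
    return wrenches[0], wrenches[1]


def generate_marker_set(
    com_position: np.ndarray,
    layout: list[MarkerSpec],
    com_height: float,
    pivot: tuple[float, float],
    fs: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    support_height: float = 0.0,
) -> MarkerSet:
    """Rigid-pendulum marker trajectories.

    Under the small-angle rigid mapping, a marker at height z displaces
    horizontally by (z / h) times the CoM displacement about the pivot.
    Heights are ``height_fraction * com_height`` above the support
    surface; independent Gaussian noise of SD ``noise_sd`` is added to
    every coordinate.
    """
    if not layout:
        raise ValueError("marker layout is empty")
    for spec in layout:
        if not 0.0 <= spec.height_fraction * com_height <= 2.4:
            raise ValueError(
                f"marker {spec.label} height outside the plausible body range"
            )
    com_position = np.asarray(com_position, dtype=float)
    n = com_position.shape[0]
    px, py = pivot
    dev_ap = com_position[:, 0] - px
    dev_ml = com_position[:, 1] - py
    pos = np.empty((n, len(layout), 3))
    for j, spec in enumerate(layout):
        zeta = spec.height_fraction
        pos[:, j, 0] = spec.ap_offset + px + zeta * dev_ap
        pos[:, j, 1] = spec.ml_offset + py + zeta * dev_ml
        pos[:, j, 2] = zeta * com_height + support_height
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pos += rng.normal(0.0, noise_sd, size=pos.shape)
    return MarkerSet(labels=[s.label for s in layout], positions=pos, fs=fs)


def _jitter_subject(
    base: TrialConfig, rng: np.random.Generator
) -> TrialConfig:
    """Per-subject parameter jitter around a base configuration.

    Distributions (documented defaults): body mass N(base, 8 kg) clipped
    to [50, 110]; CoM height N(base, 0.05 m) clipped to [0.80, 1.15];
    mean load share N(base, 0.03) clipped to [0.45, 0.75]; kp and kd
    multiplicative lognormal jitter (sigma 0.05); exploratory noise SD
    lognormal jitter (sigma 0.2).
    """
    pend = replace(
        base.pendulum,
        body_mass=float(np.clip(rng.normal(base.pendulum.body_mass, 8.0), 50, 110)),
        com_height=float(
            np.clip(rng.normal(base.pendulum.com_height, 0.05), 0.80, 1.15)
        ),
    )
    ctl = replace(
        base.controller,
        kp=float(1.0 + (base.controller.kp - 1.0) * np.exp(rng.normal(0.0, 0.15))),
        kd=float(base.controller.kd * np.exp(rng.normal(0.0, 0.05))),
        noise_sd=float(
            base.controller.noise_sd
            * np.exp(np.clip(rng.normal(0.0, 0.15), -0.3, 0.3))
        ),
    )
    share = float(np.clip(rng.normal(base.mean_load_share, 0.03), 0.45, 0.75))
    return replace(base, pendulum=pend, controller=ctl, mean_load_share=share)


def make_cohort(
    base_config: TrialConfig,
    n_subjects: int,
    trials_per_condition: int = 3,
    master_seed: int = 0,
    conditions: tuple[Condition, ...] = (Condition.EO, Condition.EC, Condition.FB),
) -> list[SyntheticTrial]:
    """Simulate a cohort: ``n_subjects`` x conditions x trials.

    Per-subject parameters are jittered around ``base_config``; per-trial
    seeds derive deterministically from ``master_seed`` via the counter
    scheme SeedSequence([master_seed, subject, condition, trial]).  EC
    trials scale the exploratory noise by ``ec_noise_multiplier``; FB
    trials activate the share-feedback integral gain and target a 0.5
    load share.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    trials: list[SyntheticTrial] = []
    for si in range(n_subjects):
        subj_rng = np.random.default_rng(
            np.random.SeedSequence([master_seed, si])
        )
        subj_cfg = _jitter_subject(base_config, subj_rng)
        subject_id = f"{base_config.group.value}-S{si + 1:02d}"
        for ci, cond in enumerate(conditions):
            for ti in range(trials_per_condition):
                trial = None
                for attempt in range(_MAX_TRIAL_ATTEMPTS):
                    seed = int(
                        np.random.SeedSequence(
                            [master_seed, si, ci, ti, attempt]
                        ).generate_state(1)[0]
                    )
                    cfg = replace(
                        subj_cfg,
                        condition=cond,
                        seed=seed,
                        subject_id=subject_id,
                        trial_id=f"{cond.value}-T{ti + 1}",
                        mean_load_share=(
                            0.5 if cond is Condition.FB
                            else subj_cfg.mean_load_share
                        ),
                    )
                    try:
                        trial = simulate_trial(cfg)
                    except UnstableSimulationError:
                        # A lost-balance trial is re-recorded with the next
                        # deterministically derived seed, like a repeated
                        # attempt in a live protocol.
                        continue
                    break
                if trial is None:
                    raise UnstableSimulationError(
                        f"subject {subject_id} {cond.value} trial {ti + 1} "
                        f"diverged on {_MAX_TRIAL_ATTEMPTS} consecutive "
                        "attempts; configuration is too unstable"
                    )
                trial.recording.meta["attempt"] = attempt
                trials.append(trial)
    return trials
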