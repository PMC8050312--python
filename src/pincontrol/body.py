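"""Default synthetic body: a reduced marker layout and the matching
13-pseudo-segment anthropometric table.

The simulator represents the body as a rigid pendulum, so any marker
layout plus segment table whose mass-weighted effective height equals the
pendulum's CoM height reproduces the true CoM exactly.  The factory below
builds a de Leva-style table over a 19-marker layout and rescales marker
heights once so that the weighted effective height is exactly 1.0 in units
of the CoM height — making the segmental estimate an identity on noiseless
rigid-pendulum data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinematics import AnthropometricTable, SegmentDef


@dataclass(frozen=True)
class MarkerSpec:
    """Placement of one synthetic marker on the rigid body.

    ``height_fraction`` is the marker height in units of the pendulum CoM
    height; ``ap_offset``/``ml_offset`` are fixed offsets in metres from
    the body axis.
    """

    label: str
    height_fraction: float
    ap_offset: float = 0.0
    ml_offset: float = 0.0


# Heights in units of CoM height h (h ~ 0.55 * body height, so the head
# sits near 1.8 h).  ML offsets are symmetric pairs so they cancel in the
# segmental CoM; AP offsets are chosen so each segment's CoM sits on the
# body axis.
_RAW_LAYOUT = [
    ("L_HEEL", 0.02, -0.05, +0.06),
    ("R_HEEL", 0.02, -0.05, -0.06),
    ("L_TOE", 0.02, +0.15, +0.06),
    ("R_TOE", 0.02, +0.15, -0.06),
    ("L_ANKLE", 0.08, 0.0, +0.06),
    ("R_ANKLE", 0.08, 0.0, -0.06),
    ("L_KNEE", 0.52, 0.0, +0.09),
    ("R_KNEE", 0.52, 0.0, -0.09),
    ("L_HIP", 0.95, 0.0, +0.12),
    ("R_HIP", 0.95, 0.0, -0.12),
    ("PELVIS", 1.00, 0.0, 0.0),
    ("STERNUM", 1.35, 0.0, 0.0),
    ("C7", 1.55, 0.0, 0.0),
    ("HEAD", 1.75, 0.0, 0.0),
    ("L_SHOULDER", 1.52, 0.0, +0.20),
    ("R_SHOULDER", 1.52, 0.0, -0.20),
    ("L_ELBOW", 1.15, 0.0, +0.25),
    ("R_ELBOW", 1.15, 0.0, -0.25),
    ("L_WRIST", 0.85, 0.0, +0.27),
    ("R_WRIST", 0.85, 0.0, -0.27),
]

# (name, mass fraction, CoM fraction proximal->distal, proximal, distal).
# Mass fractions follow de Leva-style whole-body proportions (hands folded
# into the forearms) and sum exactly to 1.
_RAW_SEGMENTS = [
    ("head", 0.0694, 0.50, "C7", "HEAD"),
    ("thorax", 0.3098, 0.60, "PELVIS", "C7"),
    ("pelvis", 0.1120, 0.50, "L_HIP", "R_HIP"),
    ("upper_arm_l", 0.0270, 0.45, "L_SHOULDER", "L_ELBOW"),
    ("upper_arm_r", 0.0270, 0.45, "R_SHOULDER", "R_ELBOW"),
    ("forearm_l", 0.0290, 0.50, "L_ELBOW", "L_WRIST"),
    ("forearm_r", 0.0290, 0.50, "R_ELBOW", "R_WRIST"),
    ("thigh_l", 0.1416, 0.41, "L_HIP", "L_KNEE"),
    ("thigh_r", 0.1416, 0.41, "R_HIP", "R_KNEE"),
    ("shank_l", 0.0433, 0.44, "L_KNEE", "L_ANKLE"),
    ("shank_r", 0.0433, 0.44, "R_KNEE", "R_ANKLE"),
    ("foot_l", 0.0135, 0.25, "L_HEEL", "L_TOE"),
    ("foot_r", 0.0135, 0.25, "R_HEEL", "R_TOE"),
]


def default_anthropometric_table() -> AnthropometricTable:
    """Bundled 13-pseudo-segment table for the default layout."""
    return AnthropometricTable(
        [SegmentDef(*row) for row in _RAW_SEGMENTS]
    )


def default_marker_layout() -> list[MarkerSpec]:
    """Default 19-marker layout, height-normalized to the segment table.

    Heights are rescaled by a single factor so that the table's
    mass-weighted effective marker height equals exactly 1 CoM height;
    then the segmental CoM of rigid-pendulum markers is the true CoM.
    """
    table = default_anthropometric_table()
    zeta = {label: z for label, z, _, _ in _RAW_LAYOUT}
    weighted = sum(
        s.mass_fraction
        * (zeta[s.proximal] + s.com_fraction * (zeta[s.distal] - zeta[s.proximal]))
        for s in table.segments
    )
    scale = 1.0 / weighted
    return [
        MarkerSpec(label, z * scale, ap, ml)
        for label, z, ap, ml in _RAW_LAYOUT
    ]
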