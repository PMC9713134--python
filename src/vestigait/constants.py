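"""Canonical names shared across the pipeline."""

#: Standard gravity (m/s^2) as measured by a resting accelerometer.
G = 9.81

#: The 13 body-worn IMU placements, left/right resolved.
PLACEMENTS = (
    "head",
    "upper_back",
    "lower_back",
    "l_arm",
    "r_arm",
    "l_wrist",
    "r_wrist",
    "l_thigh",
    "r_thigh",
    "l_shank",
    "r_shank",
    "l_foot",
    "r_foot",
)

#: Placements that carry postural-sway ellipse features.
TRUNK_PLACEMENTS = ("head", "upper_back", "lower_back")

#: Foot-mounted placements that carry spatiotemporal stride features.
FOOT_PLACEMENTS = ("l_foot", "r_foot")

#: The seven gait tasks, by their clinical abbreviations:
#: self-selected speed, change of speed, vertical head turns, horizontal
#: head turns, eyes closed, fast, slow.
TASKS = ("SSGS", "CGS", "GVHT", "GHHT", "GEC", "FGS", "SLGS")
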