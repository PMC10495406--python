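"""Semantic body-part taxonomy shared by the mesh builder, slicer and renderer.

The label set has 23 classes (background + 22 body regions). Torso is split
into four longitudinal bands (pelvis, abdomen, waist, chest) so that each
named torso circumference lives inside a single band; shoulder and
hip-junction classes cover the limb/torso transition zones.
"""

from __future__ import annotations

PART_CLASSES: dict[int, str] = {
    0: "background",
    1: "head",
    2: "neck",
    3: "chest",
    4: "waist",
    5: "abdomen",
    6: "pelvis",
    7: "left_shoulder",
    8: "right_shoulder",
    9: "upper_left_arm",
    10: "upper_right_arm",
    11: "lower_left_arm",
    12: "lower_right_arm",
    13: "left_hand",
    14: "right_hand",
    15: "left_hip_junction",
    16: "right_hip_junction",
    17: "upper_left_leg",
    18: "upper_right_leg",
    19: "lower_left_leg",
    20: "lower_right_leg",
    21: "left_foot",
    22: "right_foot",
}

N_CLASSES = len(PART_CLASSES)  # 23, background included

PART_IDS: dict[str, int] = {v: k for k, v in PART_CLASSES.items()}

# Label groups used to pick the right cross-section loop when a slicing plane
# crosses several components (e.g. a waist plane also cuts both arms).
PART_GROUPS: dict[str, frozenset[int]] = {
    "torso": frozenset({3, 4, 5, 6}),
    "left_leg": frozenset({15, 17, 19, 21}),
    "right_leg": frozenset({16, 18, 20, 22}),
    "left_arm": frozenset({7, 9, 11, 13}),
    "right_arm": frozenset({8, 10, 12, 14}),
    "neck": frozenset({2}),
    "head": frozenset({1}),
}

# Fixed indexed-color palette for segmentation PNGs (RGB per class id).
PALETTE: list[tuple[int, int, int]] = [
    (0, 0, 0),        # background
    (255, 220, 180),  # head
    (240, 200, 160),  # neck
    (200, 60, 60),    # chest
    (230, 120, 40),   # waist
    (240, 180, 60),   # abdomen
    (150, 80, 40),    # pelvis
    (80, 60, 200),    # left_shoulder
    (60, 90, 230),    # right_shoulder
    (60, 160, 220),   # upper_left_arm
    (70, 190, 240),   # upper_right_arm
    (40, 130, 180),   # lower_left_arm
    (50, 150, 200),   # lower_right_arm
    (180, 180, 240),  # left_hand
    (200, 200, 250),  # right_hand
    (120, 40, 120),   # left_hip_junction
    (150, 60, 150),   # right_hip_junction
    (40, 160, 70),    # upper_left_leg
    (60, 190, 90),    # upper_right_leg
    (30, 120, 50),    # lower_left_leg
    (40, 140, 60),    # lower_right_leg
    (160, 240, 160),  # left_foot
    (180, 250, 180),  # right_foot
]
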