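"""15-class land-cover legend and class groupings shared across modules."""

from __future__ import annotations

__all__ = [
    "LEGEND",
    "CLASS_CODES",
    "DEVELOPED_INTENSITY",
    "DEVELOPED_OR_BARREN",
    "AGRICULTURE",
    "TERRESTRIAL_CLASSES",
]

#: Code → class name (NLCD-style numeric codes).
LEGEND = {
    11: "Open Water",
    21: "Developed, Open Space",
    22: "Developed, Low Intensity",
    23: "Developed, Medium Intensity",
    24: "Developed, High Intensity",
    31: "Barren Land",
    41: "Deciduous Forest",
    42: "Evergreen Forest",
    43: "Mixed Forest",
    52: "Shrub/Scrub",
    71: "Herbaceous",
    81: "Hay/Pasture",
    82: "Cultivated Crops",
    90: "Woody Wetlands",
    95: "Emergent Herbaceous Wetlands",
}

CLASS_CODES = {name: code for code, name in LEGEND.items()}

#: Low/Medium/High developed intensity (open space excluded).
DEVELOPED_INTENSITY = frozenset({22, 23, 24})

#: Developed intensities plus barren — the "urban-embedded" screen classes.
DEVELOPED_OR_BARREN = frozenset({22, 23, 24, 31})

#: Pasture/hay and cultivated crops.
AGRICULTURE = frozenset({81, 82})

#: Open-canopy upland classes usable as adult terrestrial habitat.
TERRESTRIAL_CLASSES = frozenset({42, 52, 71})
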