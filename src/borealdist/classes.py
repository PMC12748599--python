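"""Class scheme shared across the pipeline.

Training classes are the labels the temporal classifier is trained on; map
codes are the integer legend of the emitted annual disturbance rasters.
"""
from __future__ import annotations

#: Labels the classifier is trained on, in canonical (index) order.
TRAINING_CLASSES: tuple[str, ...] = (
    "low_defoliation",
    "medium_defoliation",
    "high_defoliation",
    "fire",
    "total_harvest",
    "partial_harvest",
    "windthrow",
    "forest",
    "no_forest",
    "rocks",
    "crops",
    "urban",
    "water",
    "crops_change",
    "urban_change",
    "dams",
    "pest_fire",
    "pest_harv",
)

N_CLASSES = len(TRAINING_CLASSES)

CLASS_INDEX = {label: i for i, label in enumerate(TRAINING_CLASSES)}

#: Map legend codes (0 = undisturbed / no disturbance that year).
CODE_UNDISTURBED = 0
CODE_WILDFIRE = 1
CODE_HARVEST = 2
CODE_WINDTHROW = 3
CODE_WATER_EXTENSION = 4
CODE_PEST_HARV = 5
CODE_LOW_DEFOLIATION = 6
CODE_MEDIUM_DEFOLIATION = 7
CODE_HIGH_DEFOLIATION = 8

#: Training label -> final map code. Land-cover conversions (crops, urban)
#: are treated as undisturbed; pest-followed-by-fire is reported as wildfire.
MAP_CODES: dict[str, int] = {
    "low_defoliation": CODE_LOW_DEFOLIATION,
    "medium_defoliation": CODE_MEDIUM_DEFOLIATION,
    "high_defoliation": CODE_HIGH_DEFOLIATION,
    "fire": CODE_WILDFIRE,
    "total_harvest": CODE_HARVEST,
    "partial_harvest": CODE_HARVEST,
    "windthrow": CODE_WINDTHROW,
    "forest": CODE_UNDISTURBED,
    "no_forest": CODE_UNDISTURBED,
    "rocks": CODE_UNDISTURBED,
    "crops": CODE_UNDISTURBED,
    "urban": CODE_UNDISTURBED,
    "water": CODE_UNDISTURBED,
    "crops_change": CODE_UNDISTURBED,
    "urban_change": CODE_UNDISTURBED,
    "dams": CODE_WATER_EXTENSION,
    "pest_fire": CODE_WILDFIRE,
    "pest_harv": CODE_PEST_HARV,
}

#: Legend: map code -> (label, hex colour) as written to ``legend_type.csv``.
CODE_LABELS: dict[int, tuple[str, str]] = {
    0: ("No disturbance", "#ffffff"),
    1: ("Wildfire", "#d7191c"),
    2: ("Harvesting", "#2b83ba"),
    3: ("Windthrow", "#7b3294"),
    4: ("Water extension", "#74add1"),
    5: ("Defoliation followed by harvesting", "#fdae61"),
    6: ("Low severity defoliation", "#ffffbf"),
    7: ("Medium severity defoliation", "#fee08b"),
    8: ("High severity defoliation", "#f46d43"),
}

#: Codes stamped for a single year per event (rapid, stand-replacing).
RAPID_CODES = frozenset({1, 2, 3, 4})
#: Codes stamped for every year of their segment (multi-year pest).
MULTI_YEAR_CODES = frozenset({5, 6, 7, 8})
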