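"""Naming and nominal scale of the 20 amygdala volumetric measures.

The segmentation protocol emulated here outputs nine bilateral amygdala
nuclei (lateral, basal, accessory basal, central, medial, cortical,
paralaminar, the anterior amygdaloid area and the cortico-amygdaloid
transition area) plus the whole-amygdala total per hemisphere:
9 x 2 + 2 = 20 measures, all in mm^3.
"""

from __future__ import annotations

NUCLEI: tuple[str, ...] = (
    "lateral",
    "basal",
    "accessory_basal",
    "anterior_amygdaloid_area",
    "central",
    "medial",
    "cortical",
    "cortico_amygdaloid_transition",
    "paralaminar",
)

SIDES: tuple[str, ...] = ("left", "right")

#: column order used by every table in the package
MEASURES: tuple[str, ...] = tuple(
    f"{side}_{nucleus}" for side in SIDES for nucleus in NUCLEI
) + ("left_total", "right_total")

NUCLEUS_MEASURES: tuple[str, ...] = MEASURES[:18]
TOTAL_MEASURES: tuple[str, ...] = ("left_total", "right_total")

#: nominal school-age nucleus volumes (mm^3), one hemisphere; right
#: hemisphere is scaled up slightly below.  Values follow the typical
#: relative sizes reported for automated amygdala-subfield volumetry.
BASE_NUCLEUS_VOLUMES_MM3: dict[str, float] = {
    "lateral": 700.0,
    "basal": 450.0,
    "accessory_basal": 280.0,
    "anterior_amygdaloid_area": 60.0,
    "central": 50.0,
    "medial": 25.0,
    "cortical": 30.0,
    "cortico_amygdaloid_transition": 190.0,
    "paralaminar": 55.0,
}

#: right/left asymmetry factor applied to base volumes
RIGHT_ASYMMETRY: float = 1.03

#: measures carrying the additive male > female volume effect
SEX_EFFECT_MEASURES: tuple[str, ...] = (
    "left_basal",
    "left_accessory_basal",
    "left_central",
    "left_paralaminar",
)

BEHAVIOR_RAW_COLUMNS: tuple[str, ...] = (
    "theory_of_mind_raw",
    "affect_recognition_raw",
    "internalizing_raw",
    "emotional_control_T",
)

BEHAVIOR_SCORE_COLUMNS: tuple[str, ...] = (
    "theory_of_mind",
    "affect_recognition",
    "internalizing_problems",
    "emotional_control",
)

GROUPS: tuple[str, ...] = ("VPT", "FT")


def base_volume(measure: str) -> float:
    """Nominal mm^3 volume of a single measure (nucleus or total)."""
    side, _, nucleus = measure.partition("_")
    factor = RIGHT_ASYMMETRY if side == "right" else 1.0
    if nucleus == "total":
        return factor * sum(BASE_NUCLEUS_VOLUMES_MM3.values())
    return factor * BASE_NUCLEUS_VOLUMES_MM3[nucleus]
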