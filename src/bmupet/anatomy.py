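"""Controlled vocabulary for skeletal anatomy and the liver.

Label taxonomies map integer labels to names such as ``vertebra_L3`` or
``hip_bone_left``.  A name resolves to one of the anatomical classes below
(longest-prefix match), which determines its marrow-erosion margin and its
spine / other-bones grouping.
"""

from __future__ import annotations

#: Anatomical classes for bones (class token -> may appear as a bare name or
#: as a prefix followed by ``_<qualifier>``).
BONE_CLASSES: tuple[str, ...] = (
    "vertebra",
    "sacrum",
    "coccyx",
    "hip_bone",
    "humerus",
    "scapula",
    "clavicle",
    "rib",
    "sternum",
    "femur",
)

LIVER: str = "liver"

VOCABULARY: tuple[str, ...] = BONE_CLASSES + (LIVER,)

#: Classes forming the core of the "spine" group (hip-bone voxels close to
#: these are added separately via the sacroiliac-distance rule).
SPINE_CLASSES: tuple[str, ...] = ("vertebra", "sacrum", "coccyx")

#: Classes always assigned to the "other bones" group.
OTHER_CLASSES: tuple[str, ...] = (
    "humerus",
    "scapula",
    "clavicle",
    "rib",
    "sternum",
    "femur",
)

#: Edge-exclusion margins (mm) used to carve bone marrow out of each bone:
#: 7 mm for the long bones of arm and thigh, 5 mm for vertebrae and hip
#: bones, 3 mm for the remaining bones.
DEFAULT_MARGINS_MM: dict[str, float] = {
    "humerus": 7.0,
    "femur": 7.0,
    "vertebra": 5.0,
    "hip_bone": 5.0,
    "sacrum": 3.0,
    "coccyx": 3.0,
    "scapula": 3.0,
    "clavicle": 3.0,
    "rib": 3.0,
    "sternum": 3.0,
}


class UnknownAnatomyError(ValueError):
    """A taxonomy name does not resolve to any known anatomical class."""


def anatomical_class(name: str) -> str:
    """Resolve a taxonomy name to its anatomical class.

    ``vertebra_L3`` -> ``vertebra``; ``hip_bone_left`` -> ``hip_bone``;
    ``liver`` -> ``liver``.  Matching is by the longest class token that is
    either the full name or a ``_``-separated prefix of it.
    """
    name = name.strip().lower()
    best = None
    for token in VOCABULARY:
        if name == token or name.startswith(token + "_"):
            if best is None or len(token) > len(best):
                best = token
    if best is None:
        raise UnknownAnatomyError(
            f"name {name!r} does not match any anatomical class "
            f"(known: {', '.join(VOCABULARY)})"
        )
    return best


def is_bone(name: str) -> bool:
    return anatomical_class(name) != LIVER
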