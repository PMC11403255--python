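"""Geometric four-class dendritic-spine classification and per-neuron summaries.

A dendritic spine is described by three measured quantities (in micrometres):
its total length, its head diameter and its neck diameter.  Spines are sorted
into the four canonical morphological classes — mushroom, thin, stubby and
filopodium — by a fixed decision tree driven by two ratios:

* the **head-to-neck ratio** ``head / neck`` decides between the
  mushroom-like branch (ratio > 1.1) and the stubby-like branch (ratio <= 1.1);
* on the mushroom branch a head diameter above 0.35 µm confirms *mushroom*,
  otherwise the spine falls through to the filopodium determination;
* on the stubby branch a **length-to-head ratio** of at most 3 confirms
  *stubby*, otherwise the spine falls through to the filopodium determination;
* the filopodium determination calls *filopodium* when the total length is
  3 µm or more, and *thin* otherwise.

The tree is a total partition of geometry space: every valid geometry maps to
exactly one class.  Degenerate diameters are handled by convention — a spine
with no measurable neck (``neck == 0``) is maximally head-dominated, so its
head-to-neck ratio is treated as ``+inf``; a headless protrusion
(``head == 0``) on the stubby branch is elongation-dominated, so its
length-to-head ratio is treated as ``+inf``.  Comparisons are exact on the
stored values; no epsilon tolerance is applied at the thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DamagedNeuronError, NoSpinesError, ValidationError

__all__ = [
    "SpineClass",
    "SpineGeometry",
    "NeuronRecord",
    "classify_spine",
    "classify_many",
    "classify_codes",
    "spine_class_proportions",
    "spine_density",
    "HEAD_NECK_RATIO_CUT",
    "MUSHROOM_HEAD_MIN_UM",
    "LENGTH_HEAD_RATIO_CUT",
    "FILOPODIUM_MIN_LENGTH_UM",
]

# Decision-tree thresholds (micrometres where dimensional).
HEAD_NECK_RATIO_CUT = 1.1
MUSHROOM_HEAD_MIN_UM = 0.35
LENGTH_HEAD_RATIO_CUT = 3.0
FILOPODIUM_MIN_LENGTH_UM = 3.0


class SpineClass(str, Enum):
    """The four canonical spine morphology classes."""

    MUSHROOM = "mushroom"
    THIN = "thin"
    STUBBY = "stubby"
    FILOPODIUM = "filopodium"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Stable integer coding used by the vectorised classifier and the generator.
CLASS_ORDER: tuple[SpineClass, ...] = (
    SpineClass.MUSHROOM,
    SpineClass.THIN,
    SpineClass.STUBBY,
    SpineClass.FILOPODIUM,
)
CLASS_CODE: dict[SpineClass, int] = {c: i for i, c in enumerate(CLASS_ORDER)}


class SpineGeometry(NamedTuple):
    """One spine's measured geometry, in micrometres.

    ``total_length`` must be strictly positive; the two diameters are
    non-negative (a zero diameter means "not measurable", see the module
    docstring for the conventions applied).
    """

    total_length: float
    head_diameter: float
    neck_diameter: float


def _validate_geometry(spine: SpineGeometry) -> None:
    for name, value, allow_zero in (
        ("total_length", spine.total_length, False),
        ("head_diameter", spine.head_diameter, True),
        ("neck_diameter", spine.neck_diameter, True),
    ):
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value!r}")
        if value < 0 or (value == 0 and not allow_zero):
            bound = "non-negative" if allow_zero else "strictly positive"
            raise ValidationError(f"{name} must be {bound}, got {value!r}")


def classify_spine(spine: SpineGeometry) -> SpineClass:
    """Classify a single spine into one of the four morphological classes.

    Parameters
    ----------
    spine
        Geometry triple (length, head diameter, neck diameter) in µm.

    Returns
    -------
    SpineClass
        Exactly one of mushroom / thin / stubby / filopodium.

    Raises
    ------
    ValidationError
        If any field is non-finite, a diameter is negative, or the length is
        not strictly positive.  The message names the offending field.
    """
    if not isinstance(spine, SpineGeometry):
        spine = SpineGeometry(*spine)
    _validate_geometry(spine)
    length, head, neck = spine

    head_neck = math.inf if neck == 0 else head / neck
    if head_neck > HEAD_NECK_RATIO_CUT:
        # Mushroom branch: a sufficiently large head confirms mushroom.
        if head > MUSHROOM_HEAD_MIN_UM:
            return SpineClass.MUSHROOM
    else:
        # Stubby branch: compact protrusions stay stubby.
        length_head = math.inf if head == 0 else length / head
        if length_head <= LENGTH_HEAD_RATIO_CUT:
            return SpineClass.STUBBY
    # Filopodium determination: long protrusions are filopodia, short ones thin.
    if length >= FILOPODIUM_MIN_LENGTH_UM:
        return SpineClass.FILOPODIUM
    return SpineClass.THIN


def classify_codes(
    total_length: np.ndarray,
    head_diameter: np.ndarray,
    neck_diameter: np.ndarray,
) -> np.ndarray:
    """Vectorised classifier returning integer codes per :data:`CLASS_ORDER`.

    Inputs are assumed already validated (finite, length > 0, diameters >= 0);
    this is the fast path used by the synthetic generator and table I/O.
    """
    length = np.asarray(total_length, dtype=float)
    head = np.asarray(head_diameter, dtype=float)
    neck = np.asarray(neck_diameter, dtype=float)

    head_neck = np.where(neck > 0, head / np.where(neck > 0, neck, 1.0), np.inf)
    length_head = np.where(head > 0, length / np.where(head > 0, head, 1.0), np.inf)

    mushroom_branch = head_neck > HEAD_NECK_RATIO_CUT
    # Spines that fall through to the filopodium determination:
    falls_through = np.where(
        mushroom_branch,
        head <= MUSHROOM_HEAD_MIN_UM,
        length_head > LENGTH_HEAD_RATIO_CUT,
    )

    codes = np.empty(length.shape, dtype=np.int8)
    codes[mushroom_branch & ~falls_through] = CLASS_CODE[SpineClass.MUSHROOM]
    codes[~mushroom_branch & ~falls_through] = CLASS_CODE[SpineClass.STUBBY]
    long_enough = length >= FILOPODIUM_MIN_LENGTH_UM
    codes[falls_through & long_enough] = CLASS_CODE[SpineClass.FILOPODIUM]
    codes[falls_through & ~long_enough] = CLASS_CODE[SpineClass.THIN]
    return codes


def classify_many(spines: Sequence[SpineGeometry]) -> list[SpineClass]:
    """Classify a sequence of spines (vectorised; validates each geometry)."""
    for s in spines:
        _validate_geometry(s if isinstance(s, SpineGeometry) else SpineGeometry(*s))
    if not spines:
        return []
    arr = np.asarray(spines, dtype=float)
    codes = classify_codes(arr[:, 0], arr[:, 1], arr[:, 2])
    return [CLASS_ORDER[c] for c in codes]


@dataclass
class NeuronRecord:
    """One imaged neuron: its spines, the dendrite length analysed and a
    damage annotation.

    Damaged neurons (toxicity annotation from visual inspection of the image)
    are never used in maturity or class-proportion statistics.
    """

    neuron_id: str
    spines: list[SpineGeometry] = field(default_factory=list)
    dendrite_length_analyzed: float = 1.0
    damaged: bool = False

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.dendrite_length_analyzed)
            and self.dendrite_length_analyzed > 0
        ):
            raise ValidationError(
                "dendrite_length_analyzed must be strictly positive, got "
                f"{self.dendrite_length_analyzed!r}"
            )


def spine_class_proportions(neuron: NeuronRecord) -> dict[SpineClass, float]:
    """Fraction of this neuron's spines in each of the four classes.

    All four classes appear in the result (zero where absent) and the
    fractions sum to 1.

    Raises
    ------
    DamagedNeuronError
        If the neuron carries the damage annotation (excluded by protocol).
    NoSpinesError
        If the neuron has no spines.
    """
    if neuron.damaged:
        raise DamagedNeuronError(
            f"neuron {neuron.neuron_id!r} excluded by damage annotation"
        )
    if not neuron.spines:
        raise NoSpinesError(f"neuron {neuron.neuron_id!r} has no spines")
    classes = classify_many(neuron.spines)
    n = len(classes)
    return {
        cls: sum(1 for c in classes if c is cls) / n for cls in CLASS_ORDER
    }


def spine_density(neuron: NeuronRecord) -> float:
    """Spine density in spines per µm of analysed dendrite.

    Reporting layers may rescale to spines per 10 µm; internally the unit is
    always spines/µm.
    """
    # dendrite length validated at construction; re-check for mutated records
    if not neuron.dendrite_length_analyzed > 0:
        raise ValidationError(
            "dendrite_length_analyzed must be strictly positive, got "
            f"{neuron.dendrite_length_analyzed!r}"
        )
    return len(neuron.spines) / neuron.dendrite_length_analyzed


def mushroom_fraction(neuron: NeuronRecord) -> float:
    """Convenience: fraction of spines classified as mushroom."""
    return spine_class_proportions(neuron)[SpineClass.MUSHROOM]
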