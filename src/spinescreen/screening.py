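"""Two-stage phenotypic screen: maturity calling, DMSO-referenced hit calling,
dilution-series confirmation and per-target tabulation.

The screen follows the high-content workflow of a spine-phenotype assay run in
96-well plates.  Each well holds up to 20 imaged neurons.  A neuron is a
"mature spine neuron" when strictly more than half of its spines classify as
mushroom-type.  The well-level readout is the percentage of mature neurons
among the undamaged (evaluable) neurons of the well.  Every plate carries two
vehicle (DMSO) wells whose average mature percentage is the plate's reference;
a compound is a *candidate hit* when its primary well (1 µM) exceeds the
reference by strictly more than the hit margin (default 10 percentage points),
and a *confirmed hit* when the same criterion is met at one or more
concentrations of its dilution-series rescreen.
"""

from __future__ import annotations

import decimal
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    DamagedNeuronError,
    InvalidWellError,
    NoSpinesError,
    ValidationError,
)
from .morphometry import NeuronRecord, SpineClass, spine_class_proportions

__all__ = [
    "Treatment",
    "WellRecord",
    "PlateRecord",
    "ScreenConfig",
    "ScreenResult",
    "TargetSummary",
    "DILUTION_LADDERS",
    "call_neuron_maturity",
    "well_mature_fraction",
    "dmso_reference",
    "call_hit",
    "confirm_secondary",
    "run_screen",
    "tabulate_by_target",
    "round_half_up",
]

log = logging.getLogger(__name__)

#: Declared dilution ladders for the confirmation rescreen (µM, descending).
DILUTION_LADDERS: dict[str, tuple[float, ...]] = {
    "2fold": (1.0, 0.5, 0.25, 0.13, 0.06, 0.03),
    "3fold": (1.0, 0.3, 0.1, 0.03, 0.01),
}

PRIMARY_CONCENTRATION_UM = 1.0


@dataclass(frozen=True)
class Treatment:
    """A well's treatment: a compound at a concentration, or DMSO vehicle."""

    compound_id: str | None = None
    concentration_um: float | None = None

    def __post_init__(self) -> None:
        if self.compound_id is None:
            if self.concentration_um is not None:
                raise ValidationError("vehicle wells carry no concentration")
        else:
            if self.concentration_um is None or not self.concentration_um > 0:
                raise ValidationError(
                    f"compound {self.compound_id!r} requires a strictly "
                    f"positive concentration, got {self.concentration_um!r}"
                )

    @property
    def is_vehicle(self) -> bool:
        return self.compound_id is None

    @classmethod
    def vehicle(cls) -> "Treatment":
        return cls()


@dataclass
class WellRecord:
    """One well: its treatment, screening stage and imaged neurons."""

    well_id: str
    treatment: Treatment
    neurons: list[NeuronRecord] = field(default_factory=list)
    stage: str = "primary"  # "primary" | "secondary"


@dataclass
class PlateRecord:
    """One plate: its identifier and wells (including the two vehicle wells)."""

    plate_id: str
    wells: list[WellRecord] = field(default_factory=list)

    def vehicle_wells(self) -> list[WellRecord]:
        return [w for w in self.wells if w.treatment.is_vehicle]


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable decision parameters of the screen.

    maturity_cut
        Mushroom-spine fraction above which (strictly) a neuron is mature.
    hit_margin_points
        Percentage-point margin over the DMSO reference required (strictly)
        for a hit call.
    min_evaluable
        Minimum undamaged neurons a well needs to yield a valid percentage.
    confirm_min_passing
        Number of confirmation concentrations that must pass the hit
        criterion for a candidate to be confirmed.
    """

    maturity_cut: float = 0.5
    hit_margin_points: float = 10.0
    min_evaluable: int = 10
    confirm_min_passing: int = 1


@dataclass
class ScreenResult:
    """Per-compound outcome across both screening stages."""

    compound_id: str
    target_class: str
    primary_pct_mature: float | None
    dmso_reference_pct: float | None
    candidate: bool
    confirmation_concentrations: list[float] = field(default_factory=list)
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.confirmed and not self.candidate:
            raise ValidationError(
                f"compound {self.compound_id!r}: confirmed implies candidate"
            )


@dataclass
class TargetSummary:
    """Per-target-class screening counts and hit rate (percent, 1 decimal)."""

    target_class: str
    n_compounds: int
    n_candidates: int
    n_hits: int
    hit_rate: float


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round a non-negative value half-up to ``ndigits`` decimals.

    Uses decimal arithmetic on the shortest repr so 13.15 -> 13.2 (a plain
    float multiply would see 13.1499...).
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def call_neuron_maturity(neuron: NeuronRecord, maturity_cut: float = 0.5) -> bool:
    """True iff strictly more than ``maturity_cut`` of the spines are mushroom.

    Equality at the cut is called immature (a 50% neuron is not "over 50%").

    Raises
    ------
    DamagedNeuronError
        Damaged neurons are excluded from maturity determination.
    NoSpinesError
        A neuron with no spines has no defined mushroom fraction.
    """
    proportions = spine_class_proportions(neuron)  # raises on damaged / empty
    return proportions[SpineClass.MUSHROOM] > maturity_cut


def well_mature_fraction(
    well: WellRecord, config: ScreenConfig | None = None
) -> float:
    """Percentage of mature neurons among the well's evaluable neurons.

    Damaged neurons are excluded from both numerator and denominator.

    Raises
    ------
    InvalidWellError
        If fewer than ``config.min_evaluable`` undamaged neurons remain.
    """
    config = config or ScreenConfig()
    evaluable = [n for n in well.neurons if not n.damaged]
    if len(evaluable) < config.min_evaluable:
        raise InvalidWellError(
            f"well {well.well_id!r}: {len(evaluable)} evaluable neurons "
            f"(minimum {config.min_evaluable})"
        )
    mature = sum(
        1 for n in evaluable if call_neuron_maturity(n, config.maturity_cut)
    )
    return 100.0 * mature / len(evaluable)


def dmso_reference(
    wells: Sequence[WellRecord], config: ScreenConfig | None = None
) -> float:
    """Plate reference: the mean mature percentage of exactly two vehicle wells."""
    if len(wells) != 2:
        raise ConfigurationError(
            f"expected exactly 2 vehicle wells, got {len(wells)}"
        )
    for w in wells:
        if not w.treatment.is_vehicle:
            raise ConfigurationError(f"well {w.well_id!r} is not a vehicle well")
    fractions = [well_mature_fraction(w, config) for w in wells]
    return (fractions[0] + fractions[1]) / 2.0


def _check_pct(name: str, value: float) -> None:
    if not (math.isfinite(value) and 0.0 <= value <= 100.0):
        raise ValidationError(f"{name} must be a percentage in [0, 100], got {value!r}")


def call_hit(
    compound_pct: float, dmso_ref: float, margin_points: float = 10.0
) -> bool:
    """True iff the compound well exceeds the DMSO reference by strictly more
    than ``margin_points`` percentage points."""
    _check_pct("compound_pct", compound_pct)
    _check_pct("dmso_ref", dmso_ref)
    return compound_pct - dmso_ref > margin_points


def confirm_secondary(
    series: Sequence[tuple[float, float]],
    dmso_ref: float,
    margin_points: float = 10.0,
    min_passing: int = 1,
) -> tuple[bool, list[float]]:
    """Evaluate a dilution-series rescreen against the plate reference.

    Parameters
    ----------
    series
        ``(concentration_um, pct_mature)`` pairs; concentrations should come
        from one of the declared 2-fold / 3-fold ladders (others are accepted
        with a warning).
    dmso_ref
        The secondary plate's duplicate-DMSO average, percent.
    min_passing
        Number of concentrations that must individually pass the hit
        criterion for confirmation (default 1: reproducible at at least one
        tested concentration).

    Returns
    -------
    (confirmed, passing_concentrations)
    """
    if not series:
        raise ValidationError("confirmation series is empty")
    known = {c for ladder in DILUTION_LADDERS.values() for c in ladder}
    for conc, _ in series:
        if not conc > 0:
            raise ValidationError(f"concentration must be positive, got {conc!r}")
        if conc not in known:
            warnings.warn(
                f"concentration {conc} µM is not on a declared dilution ladder",
                stacklevel=2,
            )
    passing = [
        conc for conc, pct in series if call_hit(pct, dmso_ref, margin_points)
    ]
    return len(passing) >= min_passing, sorted(passing)


def _plate_reference(
    plate: PlateRecord, config: ScreenConfig
) -> float | None:
    vehicles = plate.vehicle_wells()
    if len(vehicles) != 2:
        log.error(
            "plate %s excluded: %d vehicle wells (expected 2)",
            plate.plate_id,
            len(vehicles),
        )
        return None
    try:
        return dmso_reference(vehicles, config)
    except InvalidWellError as exc:
        log.error("plate %s excluded: %s", plate.plate_id, exc)
        return None


def run_screen(
    plates: Sequence[PlateRecord],
    library: Mapping[str, str] | pd.DataFrame,
    config: ScreenConfig | None = None,
) -> list[ScreenResult]:
    """Run both screening stages over a set of plates.

    Parameters
    ----------
    plates
        Primary and secondary plates.  Primary wells are identified by
        ``stage == "primary"``; secondary wells (``stage == "secondary"``)
        form per-compound dilution series and are referenced against their own
        plate's DMSO average.
    library
        Mapping ``compound_id -> target_class`` (or a DataFrame with
        ``compound_id`` and ``target_class`` columns).  Results are emitted in
        library order; compounds without a valid primary well are reported as
        non-candidates.
    """
    config = config or ScreenConfig()
    if isinstance(library, pd.DataFrame):
        annotation = dict(
            zip(library["compound_id"].astype(str), library["target_class"])
        )
    else:
        annotation = dict(library)

    primary_pct: dict[str, float] = {}
    refs_for_primary: dict[str, float] = {}
    secondary_series: dict[str, list[tuple[float, float]]] = {}
    secondary_ref: dict[str, float] = {}

    for plate in plates:
        ref = _plate_reference(plate, config)
        if ref is None:
            continue
        for well in plate.wells:
            if well.treatment.is_vehicle:
                continue
            cid = well.treatment.compound_id
            assert cid is not None
            try:
                pct = well_mature_fraction(well, config)
            except InvalidWellError as exc:
                log.warning("well excluded: %s", exc)
                continue
            if well.stage == "primary":
                primary_pct[cid] = pct
                refs_for_primary[cid] = ref
            else:
                secondary_series.setdefault(cid, []).append(
                    (well.treatment.concentration_um, pct)
                )
                secondary_ref[cid] = ref

    results: list[ScreenResult] = []
    for cid, target in annotation.items():
        if cid not in primary_pct:
            log.warning("compound %s has no valid primary well", cid)
            results.append(
                ScreenResult(cid, target, None, None, candidate=False)
            )
            continue
        pct = primary_pct[cid]
        ref = refs_for_primary[cid]
        candidate = call_hit(pct, ref, config.hit_margin_points)
        confirmed = False
        passing: list[float] = []
        if candidate and cid in secondary_series:
            confirmed, passing = confirm_secondary(
                secondary_series[cid],
                secondary_ref[cid],
                config.hit_margin_points,
                config.confirm_min_passing,
            )
        results.append(
            ScreenResult(
                compound_id=cid,
                target_class=target,
                primary_pct_mature=pct,
                dmso_reference_pct=ref,
                candidate=candidate,
                confirmation_concentrations=passing,
                confirmed=confirmed,
            )
        )
    return results


def tabulate_by_target(
    results: Iterable[ScreenResult], total_label: str = "Total"
) -> list[TargetSummary]:
    """Per-target-class counts and hit rates, plus a Total row.

    Hit rate is ``100 * hits / compounds`` rounded half-up to one decimal.
    Target classes appear in order of first appearance; unknown classes group
    under their literal string.
    """
    order: list[str] = []
    counts: dict[str, list[int]] = {}
    for r in results:
        key = str(r.target_class)
        if key not in counts:
            counts[key] = [0, 0, 0]
            order.append(key)
        counts[key][0] += 1
        counts[key][1] += int(r.candidate)
        counts[key][2] += int(r.confirmed)

    summaries = []
    for key in order:
        n, cand, hits = counts[key]
        summaries.append(
            TargetSummary(key, n, cand, hits, round_half_up(100.0 * hits / n))
        )
    total_n = sum(c[0] for c in counts.values())
    total_cand = sum(c[1] for c in counts.values())
    total_hits = sum(c[2] for c in counts.values())
    total_rate = (
        round_half_up(100.0 * total_hits / total_n) if total_n else 0.0
    )
    summaries.append(
        TargetSummary(total_label, total_n, total_cand, total_hits, total_rate)
    )
    return summaries


def summaries_to_frame(summaries: Sequence[TargetSummary]) -> pd.DataFrame:
    """Render tabulated summaries as a DataFrame (one row per target class)."""
    return pd.DataFrame(
        {
            "target_class": [s.target_class for s in summaries],
            "n_compounds": [s.n_compounds for s in summaries],
            "n_candidates": [s.n_candidates for s in summaries],
            "n_hits": [s.n_hits for s in summaries],
            "hit_rate_pct": [s.hit_rate for s in summaries],
        }
    )


def results_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Render screen results as a DataFrame (one row per compound)."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "target_class": [r.target_class for r in results],
            "primary_pct_mature": [r.primary_pct_mature for r in results],
            "dmso_reference_pct": [r.dmso_reference_pct for r in results],
            "candidate": [r.candidate for r in results],
            "confirmed": [r.confirmed for r in results],
            "passing_concentrations_um": [
                ";".join(f"{c:g}" for c in r.confirmation_concentrations)
                for r in results
            ],
        }
    )
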