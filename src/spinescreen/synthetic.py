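"""Synthetic spine, plate, screen, behavioral and mEPSC-style data.

The generator inverts the analysis pipeline: it draws per-neuron spine
populations as mixtures of the four morphological classes whose geometries,
by rejection sampling against the classifier, re-classify to their intended
class with certainty.  Neuron-level heterogeneity is modelled by giving each
neuron its own mushroom mixture weight drawn from a Beta distribution; the
Beta mean is *calibrated* (semi-analytically, via the beta-binomial law of the
observed mushroom count) so that the probability that a neuron's observed
mushroom fraction exceeds 50% equals a condition's mature-neuron prevalence.
Default condition profiles target prevalences of 35.5% (B6-like control
strain) and 24.7% (BTBR-like autism-model strain).

Compound effects are three-parameter Hill shifts of the mushroom mixture
weight; the shift mass is taken from the thin weight first, then stubby, then
filopodium, mirroring the observed pharmacology (mushroom up, thin down).
Compound toxicity damages neurons at random with a probability proportional
to concentration (capped at the 1 µM value).

All generators are pure functions of their parameters and a seed; streams are
split with :class:`numpy.random.SeedSequence` so wells are independent and
order-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, ValidationError
from .morphometry import (
    CLASS_CODE,
    CLASS_ORDER,
    NeuronRecord,
    SpineClass,
    SpineGeometry,
    classify_codes,
)
from .screening import (
    DILUTION_LADDERS,
    PRIMARY_CONCENTRATION_UM,
    PlateRecord,
    ScreenConfig,
    Treatment,
    WellRecord,
    run_screen,
)

__all__ = [
    "ClassGeometry",
    "ConditionProfile",
    "CompoundEffect",
    "CompoundSpec",
    "BehaviorRecord",
    "BehaviorProfile",
    "ScreenDataset",
    "b6_profile",
    "btbr_profile",
    "default_library",
    "plant_actives",
    "sample_spine",
    "sample_neuron",
    "sample_neurons",
    "generate_screen_dataset",
    "generate_secondary_plates",
    "run_two_stage_screen",
    "generate_behavior_cohort",
    "generate_mepsc_samples",
    "TARGET_CLASS_SIZES",
]

# ---------------------------------------------------------------------------
# Geometry distributions


@dataclass(frozen=True)
class ClassGeometry:
    """Log-normal geometry parameters for one spine class.

    ``*_median`` are the medians in µm; ``*_sigma`` the log-scale standard
    deviations.  Draws are rejection-sampled against the classifier, so the
    realised distribution is the log-normal law truncated to the class's
    region of geometry space.
    """

    length_median: float
    length_sigma: float
    head_median: float
    head_sigma: float
    neck_median: float
    neck_sigma: float

    def __post_init__(self) -> None:
        for name in (
            "length_median",
            "length_sigma",
            "head_median",
            "head_sigma",
            "neck_median",
            "neck_sigma",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


#: Default per-class geometry: medians chosen inside each class's region so
#: rejection sampling accepts most draws.
DEFAULT_GEOMETRY: dict[SpineClass, ClassGeometry] = {
    SpineClass.MUSHROOM: ClassGeometry(1.2, 0.30, 0.60, 0.25, 0.30, 0.30),
    SpineClass.THIN: ClassGeometry(1.5, 0.35, 0.20, 0.30, 0.20, 0.30),
    SpineClass.STUBBY: ClassGeometry(0.8, 0.30, 0.35, 0.25, 0.40, 0.25),
    SpineClass.FILOPODIUM: ClassGeometry(4.0, 0.20, 0.15, 0.30, 0.15, 0.30),
}

DEFAULT_MAX_REJECTIONS = 1000


def _sample_class_batch(
    cls: SpineClass,
    n: int,
    geometry: ClassGeometry,
    rng: np.random.Generator,
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> np.ndarray:
    """Draw ``n`` geometries guaranteed to classify as ``cls`` (vectorised
    rejection sampling).  Returns an ``(n, 3)`` array of (length, head, neck).
    """
    code = CLASS_CODE[cls]
    out = np.empty((n, 3), dtype=float)
    pending = np.arange(n)
    for _ in range(max_rejections):
        if pending.size == 0:
            return out
        m = pending.size
        length = rng.lognormal(math.log(geometry.length_median), geometry.length_sigma, m)
        head = rng.lognormal(math.log(geometry.head_median), geometry.head_sigma, m)
        neck = rng.lognormal(math.log(geometry.neck_median), geometry.neck_sigma, m)
        ok = classify_codes(length, head, neck) == code
        idx = pending[ok]
        out[idx, 0] = length[ok]
        out[idx, 1] = head[ok]
        out[idx, 2] = neck[ok]
        pending = pending[~ok]
    raise ValidationError(
        f"could not sample a {cls.value} spine within {max_rejections} "
        "rejection rounds; geometry parameters place too little mass in the "
        "class region"
    )


def sample_spine(
    cls: SpineClass,
    geometry: ClassGeometry | None = None,
    rng: np.random.Generator | int | None = None,
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> SpineGeometry:
    """Draw one spine geometry that classifies exactly as ``cls``."""
    geometry = geometry or DEFAULT_GEOMETRY[cls]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    row = _sample_class_batch(cls, 1, geometry, rng, max_rejections)[0]
    return SpineGeometry(*row)


# ---------------------------------------------------------------------------
# Condition profiles and calibration


@dataclass
class ConditionProfile:
    """One experimental condition (strain-like state of the culture).

    The spine-class mixture is parameterised by a *mushroom weight* that
    varies across neurons as ``Beta(kappa*m, kappa*(1-m))`` where ``kappa``
    is ``mixture_concentration`` and ``m`` is solved so that the prevalence
    of neurons with an observed mushroom fraction > 50% equals
    ``mature_neuron_target``.  The non-mushroom mass is split among thin /
    stubby / filopodium in the fixed proportions ``non_mushroom_split``.
    """

    label: str
    mature_neuron_target: float
    density_mean: float = 1.0  # spines per µm
    dendrite_length_um: float = 30.0
    mixture_concentration: float = 10.0
    non_mushroom_split: tuple[float, float, float] = (0.60, 0.25, 0.15)
    geometry: Mapping[SpineClass, ClassGeometry] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY)
    )
    _mushroom_mean: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.mature_neuron_target < 1:
            raise ValidationError("mature_neuron_target must be in (0, 1)")
        if not self.density_mean > 0 or not self.dendrite_length_um > 0:
            raise ValidationError("density and dendrite length must be positive")
        split = np.asarray(self.non_mushroom_split, dtype=float)
        if split.min() < 0 or not math.isclose(split.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("non_mushroom_split must be a probability vector")

    @property
    def spine_count_mean(self) -> float:
        return self.density_mean * self.dendrite_length_um

    @property
    def mushroom_weight_mean(self) -> float:
        """Calibrated Beta mean of the per-neuron mushroom weight (cached)."""
        if self._mushroom_mean is None:
            self._mushroom_mean = calibrate_mushroom_mean(
                self.mature_neuron_target,
                self.mixture_concentration,
                self.spine_count_mean,
            )
        return self._mushroom_mean


def _mature_probability(m: float, kappa: float, lam: float) -> float:
    """P(observed mushroom fraction > 1/2) for a neuron whose spine count is
    zero-truncated Poisson(lam) and whose mushroom count, given n spines, is
    beta-binomial(n, kappa*m, kappa*(1-m)).

    This is exact for the sampling scheme used by :func:`sample_neurons`
    (rejection sampling preserves class labels, so observed class == intended
    class).
    """
    n_max = int(lam + 12 * math.sqrt(lam)) + 2
    ns = np.arange(1, n_max + 1)
    pois = stats.poisson.pmf(ns, lam)
    pois /= pois.sum()  # zero-truncated and tail-renormalised
    # mature: mushroom count k > n/2, i.e. k >= floor(n/2) + 1
    sf = stats.betabinom.sf(ns // 2, ns, kappa * m, kappa * (1.0 - m))
    return float(np.sum(pois * sf))


def calibrate_mushroom_mean(
    target: float, kappa: float, lam: float
) -> float:
    """Solve for the Beta mean giving a mature-neuron prevalence of ``target``."""
    f = lambda m: _mature_probability(m, kappa, lam) - target
    lo, hi = 1e-3, 1.0 - 1e-3
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError(
            f"mature-neuron target {target} unreachable with kappa={kappa}, "
            f"mean spine count {lam}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def b6_profile(**overrides) -> ConditionProfile:
    """Default control-strain-like condition (mature prevalence 35.5%)."""
    return ConditionProfile(label="B6-like", mature_neuron_target=0.355, **overrides)


def btbr_profile(**overrides) -> ConditionProfile:
    """Default autism-model-like condition (mature prevalence 24.7%)."""
    return ConditionProfile(label="BTBR-like", mature_neuron_target=0.247, **overrides)


# ---------------------------------------------------------------------------
# Compound effects


@dataclass(frozen=True)
class CompoundEffect:
    """Concentration-dependent shift of the mushroom mixture weight.

    The shift at concentration ``c`` (µM) is
    ``efficacy * c**hill / (ec50**hill + c**hill)`` mixture-weight points
    (0–1 scale); ``toxicity_prob`` is the per-neuron damage probability at
    1 µM, scaled linearly with concentration and capped at 1.
    """

    efficacy: float = 0.0
    ec50_um: float = 0.1
    hill: float = 1.0
    toxicity_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.efficacy <= 1:
            raise ValidationError("efficacy (mixture points) must be in [0, 1]")
        if not self.ec50_um > 0:
            raise ValidationError("ec50_um must be positive")
        if not self.hill > 0:
            raise ValidationError("hill must be positive")
        if not 0 <= self.toxicity_prob <= 1:
            raise ValidationError("toxicity_prob must be in [0, 1]")

    def shift_at(self, concentration_um: float) -> float:
        if not concentration_um > 0:
            raise ValidationError("concentration must be positive")
        c = concentration_um ** self.hill
        return self.efficacy * c / (self.ec50_um ** self.hill + c)

    def damage_prob_at(self, concentration_um: float) -> float:
        return min(1.0, self.toxicity_prob * concentration_um / PRIMARY_CONCENTRATION_UM)


@dataclass(frozen=True)
class CompoundSpec:
    """One library entry: annotation plus (for true actives) a ground-truth
    effect.  ``effect is None`` means the compound is inert."""

    compound_id: str
    name: str
    target_class: str
    ladder: str = "3fold"
    effect: CompoundEffect | None = None

    def __post_init__(self) -> None:
        if self.ladder not in DILUTION_LADDERS:
            raise ValidationError(
                f"unknown dilution ladder {self.ladder!r}; "
                f"choose from {sorted(DILUTION_LADDERS)}"
            )


#: Per-target-class compound counts of the default 181-compound library.
TARGET_CLASS_SIZES: tuple[tuple[str, int], ...] = (
    ("5-HT receptor", 38),
    ("Adrenergic receptor", 23),
    ("Dopamine receptor", 17),
    ("mACh receptor", 17),
    ("GABA receptor", 11),
    ("γ-secretase", 8),
    ("AMPA receptor", 8),
    ("nACh receptor", 8),
    ("LRRK2", 8),
    ("NMDA receptor", 7),
    ("Opioid receptor", 7),
    ("Monoamine oxidase", 6),
    ("Neurokinin receptor", 6),
    ("FAAH", 4),
    ("SSRI", 4),
    ("Amyloid-β", 3),
    ("AChE", 2),
    ("CGRP receptor", 2),
    ("β-secretase", 1),
    ("MAGL", 1),
)


def default_library() -> list[CompoundSpec]:
    """A 181-compound inert library with the default target-class makeup.

    Dilution ladders alternate between the 3-fold and 2-fold series.
    """
    specs: list[CompoundSpec] = []
    i = 0
    for target, count in TARGET_CLASS_SIZES:
        for _ in range(count):
            i += 1
            specs.append(
                CompoundSpec(
                    compound_id=f"C{i:03d}",
                    name=f"compound-{i:03d}",
                    target_class=target,
                    ladder="3fold" if i % 2 else "2fold",
                )
            )
    return specs


def plant_actives(
    library: Sequence[CompoundSpec],
    active_ids: Iterable[str],
    effect: CompoundEffect,
) -> list[CompoundSpec]:
    """Return a copy of the library with ``effect`` attached to ``active_ids``."""
    ids = set(active_ids)
    out = [
        replace(spec, effect=effect) if spec.compound_id in ids else spec
        for spec in library
    ]
    missing = ids - {s.compound_id for s in library}
    if missing:
        raise ConfigurationError(f"unknown compound ids: {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# Neuron sampling


def _shift_mixtures(weights: np.ndarray, delta: float) -> np.ndarray:
    """Add ``delta`` to the mushroom weight of each row, taking the mass from
    thin first, then stubby, then filopodium.  ``weights`` is (n, 4) in
    CLASS_ORDER (mushroom, thin, stubby, filopodium)."""
    if delta <= 0:
        return weights
    w = weights.copy()
    remaining = np.minimum(delta, 1.0 - w[:, 0])
    for donor in (1, 2, 3):
        take = np.minimum(remaining, w[:, donor])
        w[:, donor] -= take
        remaining -= take
    w[:, 0] = 1.0 - w[:, 1:].sum(axis=1)
    return w


def sample_neurons(
    profile: ConditionProfile,
    n_neurons: int,
    rng: np.random.Generator | int | None = None,
    effect: CompoundEffect | None = None,
    concentration_um: float | None = None,
    id_prefix: str = "n",
    max_rejections: int = DEFAULT_MAX_REJECTIONS,
) -> list[NeuronRecord]:
    """Draw ``n_neurons`` neurons from a condition profile, optionally under a
    compound effect at the given concentration.

    Per neuron: spine count ~ zero-truncated Poisson(density x dendrite
    length); mushroom weight ~ calibrated Beta, shifted by the compound's
    Hill response; spine classes ~ the per-neuron mixture; geometries by
    per-class rejection sampling; a damaged flag ~ Bernoulli(toxicity).
    """
    if effect is not None and (concentration_um is None or not concentration_um > 0):
        raise ValidationError("a compound effect requires a positive concentration")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    lam = profile.spine_count_mean
    counts = rng.poisson(lam, n_neurons)
    while np.any(counts == 0):  # zero-truncated: every neuron has >= 1 spine
        zeros = counts == 0
        counts[zeros] = rng.poisson(lam, int(zeros.sum()))

    kappa = profile.mixture_concentration
    m = profile.mushroom_weight_mean
    p_mush = rng.beta(kappa * m, kappa * (1.0 - m), n_neurons)
    split = np.asarray(profile.non_mushroom_split, dtype=float)
    weights = np.empty((n_neurons, 4), dtype=float)
    weights[:, 0] = p_mush
    weights[:, 1:] = (1.0 - p_mush)[:, None] * split[None, :]

    damage_p = 0.0
    if effect is not None:
        weights = _shift_mixtures(weights, effect.shift_at(concentration_um))
        damage_p = effect.damage_prob_at(concentration_um)
    damaged = rng.random(n_neurons) < damage_p

    # Class draw for every spine at once via per-neuron cumulative weights.
    total = int(counts.sum())
    neuron_idx = np.repeat(np.arange(n_neurons), counts)
    cum = np.cumsum(weights, axis=1)
    u = rng.random(total)
    codes = (u[:, None] > cum[neuron_idx, :-1]).sum(axis=1).astype(np.int8)

    # Geometry per class, batched, then scattered back into spine order.
    geom = np.empty((total, 3), dtype=float)
    for cls in CLASS_ORDER:
        mask = codes == CLASS_CODE[cls]
        k = int(mask.sum())
        if k:
            geom[mask] = _sample_class_batch(
                cls, k, profile.geometry[cls], rng, max_rejections
            )

    neurons: list[NeuronRecord] = []
    offsets = np.concatenate(([0], np.cumsum(counts)))
    for i in range(n_neurons):
        rows = geom[offsets[i] : offsets[i + 1]]
        spines = [SpineGeometry(*row) for row in rows]
        neurons.append(
            NeuronRecord(
                neuron_id=f"{id_prefix}{i:04d}",
                spines=spines,
                dendrite_length_analyzed=profile.dendrite_length_um,
                damaged=bool(damaged[i]),
            )
        )
    return neurons


def sample_neuron(
    profile: ConditionProfile,
    rng: np.random.Generator | int | None = None,
    effect: CompoundEffect | None = None,
    concentration_um: float | None = None,
    neuron_id: str = "n0000",
) -> NeuronRecord:
    """Draw a single neuron (see :func:`sample_neurons`)."""
    neuron = sample_neurons(profile, 1, rng, effect, concentration_um)[0]
    neuron.neuron_id = neuron_id
    return neuron


# ---------------------------------------------------------------------------
# Screen dataset generation


@dataclass
class ScreenDataset:
    """Plates plus their library annotation."""

    plates: list[PlateRecord]
    library: list[CompoundSpec]


def _well_rngs(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in seed_seq.spawn(n)]


def _build_plates(
    treatments: Sequence[tuple[str | None, float | None, str]],
    profile: ConditionProfile,
    effects: Mapping[str, CompoundEffect | None],
    seed_seq: np.random.SeedSequence,
    plate_prefix: str,
    neurons_per_well: int,
    wells_per_plate: int,
    dmso_per_plate: int,
) -> list[PlateRecord]:
    """Lay out treatment wells onto plates, adding ``dmso_per_plate`` vehicle
    wells per plate.  ``treatments`` holds (compound_id|None, conc, stage)."""
    capacity = wells_per_plate - dmso_per_plate
    if capacity < 1:
        raise ConfigurationError(
            "plate layout leaves no room for treatment wells"
        )
    n_plates = max(1, math.ceil(len(treatments) / capacity))
    plates: list[PlateRecord] = []
    t = 0
    for p in range(n_plates):
        plate_id = f"{plate_prefix}{p + 1:02d}"
        chunk = treatments[t : t + capacity]
        t += capacity
        n_wells = len(chunk) + dmso_per_plate
        rngs = _well_rngs(seed_seq.spawn(1)[0], n_wells)
        wells: list[WellRecord] = []
        for d in range(dmso_per_plate):
            wells.append(
                WellRecord(
                    well_id=f"{plate_id}-DMSO{d + 1}",
                    treatment=Treatment.vehicle(),
                    neurons=sample_neurons(
                        profile, neurons_per_well, rngs[d], id_prefix=f"{plate_id}d{d}-"
                    ),
                    stage="vehicle",
                )
            )
        for w, (cid, conc, stage) in enumerate(chunk):
            rng = rngs[dmso_per_plate + w]
            wells.append(
                WellRecord(
                    well_id=f"{plate_id}-W{w + 1:02d}",
                    treatment=Treatment(cid, conc),
                    neurons=sample_neurons(
                        profile,
                        neurons_per_well,
                        rng,
                        effect=effects.get(cid),
                        concentration_um=conc,
                        id_prefix=f"{plate_id}w{w}-",
                    ),
                    stage=stage,
                )
            )
        plates.append(PlateRecord(plate_id, wells))
    return plates


def generate_screen_dataset(
    library: Sequence[CompoundSpec] | None = None,
    profile: ConditionProfile | None = None,
    seed: int | np.random.SeedSequence | None = None,
    neurons_per_well: int = 20,
    wells_per_plate: int = 96,
    dmso_per_plate: int = 2,
    secondary_for: Sequence[str] | None = None,
) -> ScreenDataset:
    """Generate primary-screen plates (1 µM for every compound), and
    optionally secondary dilution-series plates for ``secondary_for``.

    Deterministic given the seed.  The condition profile defaults to the
    BTBR-like (disease-model) culture, the state the screen runs in.
    """
    library = list(library) if library is not None else default_library()
    if not library:
        raise ConfigurationError("library must contain at least one compound")
    profile = profile or btbr_profile()
    seed_seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    effects = {s.compound_id: s.effect for s in library}

    primary = [
        (s.compound_id, PRIMARY_CONCENTRATION_UM, "primary") for s in library
    ]
    primary_seq, secondary_seq = seed_seq.spawn(2)
    plates = _build_plates(
        primary,
        profile,
        effects,
        primary_seq,
        "P",
        neurons_per_well,
        wells_per_plate,
        dmso_per_plate,
    )
    if secondary_for:
        plates += generate_secondary_plates(
            library,
            secondary_for,
            profile,
            secondary_seq,
            neurons_per_well,
            wells_per_plate,
            dmso_per_plate,
        )
    return ScreenDataset(plates=plates, library=library)


def generate_secondary_plates(
    library: Sequence[CompoundSpec],
    compound_ids: Sequence[str],
    profile: ConditionProfile,
    seed: int | np.random.SeedSequence | None = None,
    neurons_per_well: int = 20,
    wells_per_plate: int = 96,
    dmso_per_plate: int = 2,
) -> list[PlateRecord]:
    """Dilution-series plates for the given candidate compounds, each using
    its declared 2-fold or 3-fold ladder."""
    seed_seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    by_id = {s.compound_id: s for s in library}
    treatments: list[tuple[str | None, float | None, str]] = []
    for cid in compound_ids:
        if cid not in by_id:
            raise ConfigurationError(f"unknown compound id {cid!r}")
        for conc in DILUTION_LADDERS[by_id[cid].ladder]:
            treatments.append((cid, conc, "secondary"))
    effects = {s.compound_id: s.effect for s in library}
    return _build_plates(
        treatments,
        profile,
        effects,
        seed_seq,
        "S",
        neurons_per_well,
        wells_per_plate,
        dmso_per_plate,
    )


def run_two_stage_screen(
    library: Sequence[CompoundSpec] | None = None,
    profile: ConditionProfile | None = None,
    seed: int | None = None,
    config: ScreenConfig | None = None,
    neurons_per_well: int = 20,
    wells_per_plate: int = 96,
    dmso_per_plate: int = 2,
):
    """Full workflow: generate the primary screen, call candidates, generate
    dilution-series rescreens for the candidates only, and produce the final
    per-compound results.

    Returns ``(results, dataset)`` where ``dataset`` holds every plate of
    both stages.  Deterministic given the seed.
    """
    library = list(library) if library is not None else default_library()
    profile = profile or btbr_profile()
    config = config or ScreenConfig()
    seed_seq = np.random.SeedSequence(seed)
    primary_seq, secondary_seq = seed_seq.spawn(2)

    dataset = generate_screen_dataset(
        library,
        profile,
        primary_seq,
        neurons_per_well,
        wells_per_plate,
        dmso_per_plate,
    )
    annotation = {s.compound_id: s.target_class for s in library}
    primary_results = run_screen(dataset.plates, annotation, config)
    candidates = [r.compound_id for r in primary_results if r.candidate]
    if candidates:
        dataset.plates += generate_secondary_plates(
            library,
            candidates,
            profile,
            secondary_seq,
            neurons_per_well,
            wells_per_plate,
            dmso_per_plate,
        )
    results = run_screen(dataset.plates, annotation, config)
    return results, dataset


# ---------------------------------------------------------------------------
# Behavioral cohorts


@dataclass
class BehaviorRecord:
    """One animal's three-chamber times and grooming duration (seconds)."""

    animal_id: str
    group: str
    time_novel_mouse_s: float
    time_center_s: float
    time_novel_object_s: float
    grooming_s_per_10min: float

    def __post_init__(self) -> None:
        times = (
            self.time_novel_mouse_s,
            self.time_center_s,
            self.time_novel_object_s,
        )
        if any(t < 0 for t in times):
            raise ValidationError("chamber times must be non-negative")
        if not math.isclose(sum(times), SESSION_LENGTH_S, rel_tol=1e-9):
            raise ValidationError(
                f"chamber times must sum to the session length {SESSION_LENGTH_S} s"
            )
        if not 0 <= self.grooming_s_per_10min <= SESSION_LENGTH_S:
            raise ValidationError("grooming time must lie within the session")


SESSION_LENGTH_S = 600.0  # both behavioral sessions last 10 min


@dataclass(frozen=True)
class BehaviorProfile:
    """Group-level behavioral tendencies.

    ``social_index_mean`` is the expected sociability index (time with the
    novel mouse over time with mouse + object); ``center_fraction`` the
    expected fraction of the session spent in the centre chamber;
    ``allocation_concentration`` the Dirichlet concentration controlling
    animal-to-animal spread; grooming follows a Gamma law with the given mean
    and shape, clipped to the session.
    """

    social_index_mean: float = 0.5
    center_fraction: float = 1.0 / 3.0
    allocation_concentration: float = 50.0
    grooming_mean_s: float = 100.0
    grooming_shape: float = 9.0

    def __post_init__(self) -> None:
        if not 0 < self.social_index_mean < 1:
            raise ValidationError("social_index_mean must be in (0, 1)")
        if not 0 < self.center_fraction < 1:
            raise ValidationError("center_fraction must be in (0, 1)")
        if not self.allocation_concentration > 0:
            raise ValidationError("allocation_concentration must be positive")
        if not self.grooming_mean_s > 0 or not self.grooming_shape > 0:
            raise ValidationError("grooming parameters must be positive")


#: Default cohort behavioral profiles.  The disease-model vehicle group shows
#: a social-avoidance tendency (index below 0.5) and elevated grooming; the
#: treated group shows restored social preference with grooming unchanged;
#: the control strain shows normal preference and low grooming.
DEFAULT_BEHAVIOR_PROFILES: dict[str, BehaviorProfile] = {
    "B6": BehaviorProfile(0.62, grooming_mean_s=60.0),
    "BTBR": BehaviorProfile(0.44, grooming_mean_s=150.0),
    "vehicle": BehaviorProfile(0.44, grooming_mean_s=150.0),
    "treated": BehaviorProfile(0.62, grooming_mean_s=150.0),
}

#: Default cohort sizes for the treatment experiment (vehicle vs treated).
DEFAULT_COHORT_SIZES: dict[str, int] = {"vehicle": 10, "treated": 12}


def generate_behavior_cohort(
    group_sizes: Mapping[str, int] | None = None,
    profiles: Mapping[str, BehaviorProfile] | None = None,
    seed: int | None = None,
) -> list[BehaviorRecord]:
    """Simulate per-animal three-chamber times and grooming durations.

    Chamber times are a Dirichlet allocation of the 600 s session over
    (novel mouse, centre, novel object); by the aggregation property of the
    Dirichlet, the sociability index of each animal is Beta-distributed with
    mean ``social_index_mean``.
    """
    group_sizes = dict(group_sizes or DEFAULT_COHORT_SIZES)
    profiles = dict(profiles or DEFAULT_BEHAVIOR_PROFILES)
    rng = np.random.default_rng(seed)
    records: list[BehaviorRecord] = []
    for group, n in group_sizes.items():
        if n < 1:
            raise ValidationError(f"group {group!r} size must be >= 1")
        prof = profiles.get(group, BehaviorProfile())
        side = 1.0 - prof.center_fraction
        alpha = prof.allocation_concentration * np.array(
            [
                side * prof.social_index_mean,
                prof.center_fraction,
                side * (1.0 - prof.social_index_mean),
            ]
        )
        times = SESSION_LENGTH_S * rng.dirichlet(alpha, n)
        grooming = np.minimum(
            SESSION_LENGTH_S,
            rng.gamma(prof.grooming_shape, prof.grooming_mean_s / prof.grooming_shape, n),
        )
        for i in range(n):
            records.append(
                BehaviorRecord(
                    animal_id=f"{group}-{i + 1:02d}",
                    group=group,
                    time_novel_mouse_s=float(times[i, 0]),
                    time_center_s=float(times[i, 1]),
                    time_novel_object_s=float(times[i, 2]),
                    grooming_s_per_10min=float(grooming[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# mEPSC-style samples


def generate_mepsc_samples(
    n_events: int,
    amplitude_median_pa: float = 15.0,
    amplitude_sigma: float = 0.45,
    amplitude_scale: float = 1.0,
    mean_interval_s: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic miniature-EPSC amplitudes and inter-event intervals.

    Amplitudes are log-normal (positive, right-skewed); ``amplitude_scale``
    multiplies the median, so a disease-model group with weakened synapses
    uses a scale below 1.  Intervals are exponential with the given mean.
    Returns ``(amplitudes_pA, intervals_s)``.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    if amplitude_median_pa <= 0 or amplitude_sigma <= 0 or amplitude_scale <= 0:
        raise ValidationError("amplitude parameters must be positive")
    if mean_interval_s <= 0:
        raise ValidationError("mean_interval_s must be positive")
    rng = np.random.default_rng(seed)
    amplitudes = rng.lognormal(
        math.log(amplitude_median_pa * amplitude_scale), amplitude_sigma, n_events
    )
    intervals = rng.exponential(mean_interval_s, n_events)
    return amplitudes, intervals
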