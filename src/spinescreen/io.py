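"""CSV schemas: spine/neuron tables, well layouts, libraries, behavior records.

All tables are UTF-8 CSV with a header row and '.' decimal separator.

* spine table — one row per spine:
  ``plate_id, well_id, neuron_id, spine_id, total_length_um,
  head_diameter_um, neck_diameter_um``
* neuron table — one row per neuron:
  ``plate_id, well_id, neuron_id, dendrite_length_um, damaged`` (0/1)
* well table — one row per well:
  ``plate_id, well_id, compound_id (empty for DMSO), concentration_um, stage``
* library table:
  ``compound_id, compound_name, target_class, primary_concentration_um,
  dilution_ladder``
* behavior table:
  ``animal_id, group, time_novel_mouse_s, time_center_s, time_novel_object_s,
  grooming_s``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .morphometry import NeuronRecord, SpineGeometry
from .screening import PlateRecord, Treatment, WellRecord
from .synthetic import BehaviorRecord, CompoundSpec, ScreenDataset

SPINE_COLUMNS = [
    "plate_id",
    "well_id",
    "neuron_id",
    "spine_id",
    "total_length_um",
    "head_diameter_um",
    "neck_diameter_um",
]
NEURON_COLUMNS = ["plate_id", "well_id", "neuron_id", "dendrite_length_um", "damaged"]
WELL_COLUMNS = ["plate_id", "well_id", "compound_id", "concentration_um", "stage"]
LIBRARY_COLUMNS = [
    "compound_id",
    "compound_name",
    "target_class",
    "primary_concentration_um",
    "dilution_ladder",
]
BEHAVIOR_COLUMNS = [
    "animal_id",
    "group",
    "time_novel_mouse_s",
    "time_center_s",
    "time_novel_object_s",
    "grooming_s",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns: {missing}")


def dataset_to_frames(
    dataset: ScreenDataset,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten a dataset into (spines, neurons, wells, library) DataFrames."""
    spine_rows, neuron_rows, well_rows = [], [], []
    for plate in dataset.plates:
        for well in plate.wells:
            t = well.treatment
            well_rows.append(
                (
                    plate.plate_id,
                    well.well_id,
                    "" if t.is_vehicle else t.compound_id,
                    "" if t.is_vehicle else t.concentration_um,
                    well.stage,
                )
            )
            for neuron in well.neurons:
                neuron_rows.append(
                    (
                        plate.plate_id,
                        well.well_id,
                        neuron.neuron_id,
                        neuron.dendrite_length_analyzed,
                        int(neuron.damaged),
                    )
                )
                for k, s in enumerate(neuron.spines):
                    spine_rows.append(
                        (
                            plate.plate_id,
                            well.well_id,
                            neuron.neuron_id,
                            f"{neuron.neuron_id}-s{k:03d}",
                            s.total_length,
                            s.head_diameter,
                            s.neck_diameter,
                        )
                    )
    spines = pd.DataFrame(spine_rows, columns=SPINE_COLUMNS)
    neurons = pd.DataFrame(neuron_rows, columns=NEURON_COLUMNS)
    wells = pd.DataFrame(well_rows, columns=WELL_COLUMNS)
    library = pd.DataFrame(
        [
            (s.compound_id, s.name, s.target_class, 1.0, s.ladder)
            for s in dataset.library
        ],
        columns=LIBRARY_COLUMNS,
    )
    return spines, neurons, wells, library


def write_dataset(dataset: ScreenDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four dataset tables to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spines, neurons, wells, library = dataset_to_frames(dataset)
    paths = {}
    for name, df in (
        ("spines", spines),
        ("neurons", neurons),
        ("wells", wells),
        ("library", library),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_plates(
    spines_path: str | Path,
    neurons_path: str | Path,
    wells_path: str | Path,
) -> list[PlateRecord]:
    """Reassemble plate records from the spine, neuron and well tables."""
    spines = pd.read_csv(spines_path)
    neurons = pd.read_csv(neurons_path)
    wells = pd.read_csv(wells_path)
    _require_columns(spines, SPINE_COLUMNS, "spine")
    _require_columns(neurons, NEURON_COLUMNS, "neuron")
    _require_columns(wells, WELL_COLUMNS, "well")

    spine_groups = {
        key: grp for key, grp in spines.groupby(["plate_id", "well_id", "neuron_id"])
    }
    neuron_groups = {
        key: grp for key, grp in neurons.groupby(["plate_id", "well_id"])
    }

    plates: dict[str, PlateRecord] = {}
    for row in wells.itertuples(index=False):
        plate = plates.setdefault(row.plate_id, PlateRecord(row.plate_id, []))
        cid = row.compound_id if isinstance(row.compound_id, str) and row.compound_id else None
        treatment = (
            Treatment.vehicle()
            if cid is None
            else Treatment(cid, float(row.concentration_um))
        )
        neuron_records = []
        for n_row in neuron_groups.get(
            (row.plate_id, row.well_id), pd.DataFrame(columns=NEURON_COLUMNS)
        ).itertuples(index=False):
            grp = spine_groups.get((row.plate_id, row.well_id, n_row.neuron_id))
            spine_list = (
                [
                    SpineGeometry(r.total_length_um, r.head_diameter_um, r.neck_diameter_um)
                    for r in grp.itertuples(index=False)
                ]
                if grp is not None
                else []
            )
            neuron_records.append(
                NeuronRecord(
                    neuron_id=str(n_row.neuron_id),
                    spines=spine_list,
                    dendrite_length_analyzed=float(n_row.dendrite_length_um),
                    damaged=bool(int(n_row.damaged)),
                )
            )
        plate.wells.append(
            WellRecord(
                well_id=str(row.well_id),
                treatment=treatment,
                neurons=neuron_records,
                stage=str(row.stage),
            )
        )
    return list(plates.values())


def read_library(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["compound_id", "target_class"], "library")
    return df


def behavior_to_frame(records: Sequence[BehaviorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.animal_id,
                r.group,
                r.time_novel_mouse_s,
                r.time_center_s,
                r.time_novel_object_s,
                r.grooming_s_per_10min,
            )
            for r in records
        ],
        columns=BEHAVIOR_COLUMNS,
    )


def read_behavior(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BEHAVIOR_COLUMNS, "behavior")
    return df
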