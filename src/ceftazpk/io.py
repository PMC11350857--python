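"""Dataset and configuration I/O.

The on-disk dataset format is a NONMEM-style CSV with one row per event:

    ID,TIME,EVID,AMT,DUR,DV,MDV,GFR,WT,AGE,SEX,CREAT

EVID 1 rows are doses (AMT mg infused over DUR h; DUR 0 = bolus), EVID 0
rows are observations (DV mg/L).  Missing numeric fields are written as
".".  Concentrations and times are written with two decimals so that a
write/read cycle is lossless for canonical files.

Configuration files are flat YAML blocks whose keys mirror the
:class:`~ceftazpk.population.PopulationParameters` and
:class:`~ceftazpk.cohort.CohortConfig` fields; regimens are lists of
``[start_h, amount_mg, duration_h]`` triples.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cohort import COLUMNS, CohortConfig, TdmDataset
from .pk import DoseEvent, Regimen
from .population import LLOQ, LLOQ_SUBSTITUTE, PopulationParameters

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_config",
    "save_config",
    "regimen_from_triples",
]

_FORMATS = {
    "TIME": "{:.2f}",
    "AMT": "{:.2f}",
    "DUR": "{:.2f}",
    "DV": "{:.2f}",
    "GFR": "{:.2f}",
    "WT": "{:.2f}",
    "AGE": "{:.1f}",
    "CREAT": "{:.2f}",
}
_INT_COLUMNS = ("EVID", "MDV")


class DatasetFormatError(ValueError):
    """A file violates the dataset dialect."""


def read_dataset(path: str | Path) -> TdmDataset:
    """Read and validate a NONMEM-style CSV dataset.

    Unknown columns and out-of-order times are hard errors; observed values
    below the LLOQ that are not the standard substitute raise a warning
    (the laboratory convention records sub-LLOQ samples as exactly
    4 mg/L).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in COLUMNS]
    if unknown:
        raise DatasetFormatError(f"{path}: unknown columns {unknown}")
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")

    def parse_num(col: pd.Series, line_offset: int = 2) -> pd.Series:
        vals = []
        for i, v in enumerate(col):
            if v in (".", ""):
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(v))
                except ValueError as exc:
                    raise DatasetFormatError(
                        f"{path}:{i + line_offset}: cannot parse {col.name}={v!r}"
                    ) from exc
        return pd.Series(vals, dtype=float)

    frame = pd.DataFrame({"ID": raw["ID"]})
    for c in COLUMNS[1:]:
        if c == "SEX":
            frame[c] = raw[c].replace({".": None, "": None})
        else:
            frame[c] = parse_num(raw[c])
    for c in _INT_COLUMNS:
        frame[c] = frame[c].astype(int)
    # keep numeric-looking IDs numeric so generated and re-read datasets match
    try:
        frame["ID"] = frame["ID"].astype(int)
    except ValueError:
        pass

    obs = frame[frame["EVID"] == 0]
    odd = obs["DV"].between(0, LLOQ, inclusive="neither") & (obs["DV"] != LLOQ_SUBSTITUTE)
    if odd.any():
        lines = (obs.index[odd] + 2).tolist()
        warnings.warn(
            f"{path}: observed values below the LLOQ ({LLOQ} mg/L) that are not the "
            f"substitute {LLOQ_SUBSTITUTE} mg/L at lines {lines}",
            stacklevel=2,
        )
    try:
        return TdmDataset(frame)
    except ValueError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc


def write_dataset(dataset: TdmDataset, path: str | Path) -> None:
    """Write a dataset in the canonical dialect (fixed column order/format)."""
    path = Path(path)
    d = dataset.data
    with open(path, "w", newline="") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for row in d.itertuples(index=False):
            cells = []
            for col, val in zip(COLUMNS, row):
                if col == "ID":
                    cells.append(str(val))
                elif col == "SEX":
                    cells.append("." if val is None or (isinstance(val, float) and math.isnan(val)) else str(val))
                elif col in _INT_COLUMNS:
                    cells.append(str(int(val)))
                else:
                    if val is None or (isinstance(val, float) and math.isnan(val)):
                        cells.append(".")
                    else:
                        cells.append(_FORMATS[col].format(float(val)))
            fh.write(",".join(cells) + "\n")


def regimen_from_triples(triples: list) -> Regimen:
    """Build a regimen from ``[start_h, amount_mg, duration_h]`` triples.

    A duration given as the string ``"inf"`` (or a non-finite number) makes
    the event an open-ended infusion whose amount field is read as mg/h.
    """
    events = []
    for start, amount, duration in triples:
        if isinstance(duration, str):
            token = duration.strip().lstrip(".").lower()
            dur = math.inf if token in ("inf", "infinity") else float(duration)
        else:
            dur = float(duration)
        if math.isinf(dur):
            events.append(DoseEvent(float(start), math.inf, math.inf, rate=float(amount)))
        else:
            events.append(DoseEvent(float(start), float(amount), dur))
    return Regimen(events)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config; returns typed blocks where present.

    Recognized top-level blocks: ``population`` (PopulationParameters
    fields), ``cohort`` (CohortConfig fields), ``regimen`` (list of
    triples).  Unrecognized keys are passed through untouched.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = dict(raw)
    if "population" in raw:
        out["population"] = PopulationParameters.from_dict(raw["population"])
    if "cohort" in raw:
        fields = CohortConfig.__dataclass_fields__
        kw = {k: v for k, v in raw["cohort"].items() if k in fields}
        for tup in ("GFR_bounds", "samples_per_subject_range", "daily_rate_choices",
                    "daily_rate_weights"):
            if tup in kw:
                kw[tup] = tuple(kw[tup])
        out["cohort"] = CohortConfig(**kw)
    if "regimen" in raw:
        out["regimen"] = regimen_from_triples(raw["regimen"])
    return out


def save_config(path: str | Path, population: PopulationParameters | None = None,
                **extra: Any) -> None:
    """Write a flat YAML config mirroring the parameter field names."""
    doc: dict[str, Any] = {}
    if population is not None:
        doc["population"] = population.to_dict()
    doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
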