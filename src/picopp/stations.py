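"""Station records and the canonical CSV schema.

One :class:`StationRecord` holds a single station/depth observation:
position and date, surface environment (temperature, chlorophyll, PAR,
light attenuation and/or euphotic depth), per-group picophytoplankton
abundances from flow cytometry, and optionally a concomitant
14C-incubation primary-production measurement.

The CSV schema is fixed and carries units in the column names, because
field datasets in this domain routinely mix unit conventions (hourly vs
daily PAR being the classic trap). Empty cells mean "missing"; no
sentinel numbers are used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GROUPS",
    "STATION_COLUMNS",
    "SchemaError",
    "StationRecord",
    "read_stations",
    "write_stations",
    "stations_to_frame",
]

#: canonical group keys, in reporting order
GROUPS = ("prochlorococcus", "synechococcus", "picoeukaryotes")

#: canonical station CSV columns, with units embedded in the names
STATION_COLUMNS = [
    "lat",
    "lon",
    "date",
    "sst_c",
    "chl_mgm3",
    "par_mol_m2_d",
    "k490_m1",
    "zeu_m",
    "pro_cells_ml",
    "syn_cells_ml",
    "euk_cells_ml",
    "pp14c",
]

_ABUNDANCE_COLUMNS = {
    "prochlorococcus": "pro_cells_ml",
    "synechococcus": "syn_cells_ml",
    "picoeukaryotes": "euk_cells_ml",
}


class SchemaError(ValueError):
    """Raised when a station CSV does not conform to the canonical schema."""


@dataclass
class StationRecord:
    """A single station/depth observation.

    All numeric fields are optional; ``None`` means the quantity was not
    measured. Abundances are cells mL^-1, temperature degC, chlorophyll
    mg m^-3, PAR mol photons m^-2 d^-1, k490 m^-1, euphotic depth m, and
    ``pp14c`` is measured volumetric primary production (mg C m^-3 d^-1).
    """

    lat: Optional[float] = None
    lon: Optional[float] = None
    date: Optional[str] = None
    sst_c: Optional[float] = None
    chl_mgm3: Optional[float] = None
    par_mol_m2_d: Optional[float] = None
    k490_m1: Optional[float] = None
    zeu_m: Optional[float] = None
    pro_cells_ml: Optional[float] = None
    syn_cells_ml: Optional[float] = None
    euk_cells_ml: Optional[float] = None
    pp14c: Optional[float] = None

    def abundance(self, group: str) -> Optional[float]:
        """Cell abundance (cells mL^-1) for a canonical group key."""
        return getattr(self, _ABUNDANCE_COLUMNS[group])


def _cell(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return value


def read_stations(path) -> list[StationRecord]:
    """Read station records from a canonical-schema CSV.

    Raises
    ------
    SchemaError
        If any mandatory column header is missing (the error message
        lists the missing names).
    """
    frame = pd.read_csv(path, dtype={"date": "string"}, float_precision="round_trip")
    missing = [c for c in STATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory station columns: {', '.join(missing)}"
        )
    records = []
    for row in frame.itertuples(index=False):
        date = getattr(row, "date")
        records.append(
            StationRecord(
                date=None if pd.isna(date) else str(date),
                **{
                    c: _cell(getattr(row, c))
                    for c in STATION_COLUMNS
                    if c != "date"
                },
            )
        )
    return records


def stations_to_frame(records: Iterable[StationRecord]) -> pd.DataFrame:
    """Station records as a DataFrame in canonical column order."""
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=STATION_COLUMNS)


def write_stations(records: Sequence[StationRecord], path) -> None:
    """Write records as a canonical-schema CSV (empty cells for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    stations_to_frame(records).to_csv(path, index=False)
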