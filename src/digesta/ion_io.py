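"""Data model and CSV I/O for LC-MS peptide ion-peak tables and biological read-outs.

An *ion table* is the per-(source, replicate) export of a feature-detection
run: one row per detected ion peak with mass-to-charge ratio (Thomson),
charge state, retention time (minutes) and raw abundance (arbitrary units).
A *biological read-out table* holds the intestinal-tubule assay panel in
long format: one row per (source, replicate, variable) measurement.

Column names in ion-table CSVs are configurable because feature-detection
exports vary between vendors; defaults are ``mz, charge, rt_min, abundance``.
Retention times are minutes everywhere downstream (the matching tolerance is
stated in minutes); seconds inputs are converted at read time.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: Default CSV header → field mapping for ion tables.
DEFAULT_ION_COLUMNS = {
    "mz": "mz",
    "charge": "charge",
    "rt": "rt_min",
    "abundance": "abundance",
    "ion_id": "ion_id",  # optional in inputs; always written on output
}

#: The seven intestinal-tubule read-out variables, in canonical order.
BIO_VARIABLES = (
    "inulin_fitc_leakage",
    "zo1_intersections",
    "cell_viability",
    "alkaline_phosphatase",
    "il6",
    "tgf_beta",
    "no_production",
)


class IonTableError(ValueError):
    """Malformed or invalid ion-table input."""

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        self.diagnostics = diagnostics or []
        if self.diagnostics:
            message = message + "\n  " + "\n  ".join(self.diagnostics)
        super().__init__(message)


class BioTableError(ValueError):
    """Malformed or invalid biological read-out input."""


@dataclass(frozen=True)
class PeptideIon:
    """One detected LC-MS feature.

    Attributes
    ----------
    ion_id : identifier, unique within its table.
    mz : mass-to-charge ratio in Thomson, > 0.
    charge : positive integer charge state.
    rt : retention time in minutes, >= 0.
    abundance : raw abundance in arbitrary units, >= 0.
    """

    ion_id: object
    mz: float
    charge: int
    rt: float
    abundance: float

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if not (math.isfinite(self.mz) and self.mz > 0):
            problems.append(f"mz must be finite and > 0, got {self.mz!r}")
        if not (isinstance(self.charge, int) and self.charge >= 1):
            problems.append(f"charge must be an integer >= 1, got {self.charge!r}")
        if not (math.isfinite(self.rt) and self.rt >= 0):
            problems.append(f"rt must be finite and >= 0, got {self.rt!r}")
        if not (math.isfinite(self.abundance) and self.abundance >= 0):
            problems.append(f"abundance must be finite and >= 0, got {self.abundance!r}")
        return problems


@dataclass(frozen=True)
class IonTable:
    """An ordered collection of :class:`PeptideIon` for one sample replicate."""

    source_id: str
    replicate_id: str
    ions: tuple[PeptideIon, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "ions", tuple(self.ions))
        ids = [ion.ion_id for ion in self.ions]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise IonTableError(
                f"duplicate ion_id(s) in table {self.source_id}/{self.replicate_id}: "
                f"{sorted(map(repr, dups))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.ions)

    def __iter__(self):
        return iter(self.ions)

    def with_ions(self, ions) -> "IonTable":
        """Return a copy of this table holding ``ions`` (order as given)."""
        return replace(self, ions=tuple(ions))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ion_id": [i.ion_id for i in self.ions],
                "mz": [i.mz for i in self.ions],
                "charge": [i.charge for i in self.ions],
                "rt_min": [i.rt for i in self.ions],
                "abundance": [i.abundance for i in self.ions],
            }
        )


def _validate_rows(rows: list[PeptideIon], label: str) -> None:
    diagnostics = []
    for idx, ion in enumerate(rows):
        for problem in ion.validate():
            diagnostics.append(f"row {idx}: {problem}")
    if diagnostics:
        raise IonTableError(f"invalid rows in ion table {label}", diagnostics)


def read_ion_table(
    path,
    source_id: str,
    replicate_id: str,
    columns: dict | None = None,
    rt_in_seconds: bool = False,
) -> IonTable:
    """Read one per-replicate ion-peak CSV into a validated :class:`IonTable`.

    Parameters
    ----------
    columns
        Header mapping, field name → CSV column name; missing keys fall back
        to :data:`DEFAULT_ION_COLUMNS`. The ``ion_id`` column is optional in
        the file; when absent, sequential integer ids are assigned in row
        order so that matching audit trails have stable identifiers.
    rt_in_seconds
        If true, retention times are divided by 60 on ingest.
    """
    cols = dict(DEFAULT_ION_COLUMNS)
    if columns:
        cols.update(columns)
    frame = pd.read_csv(path, float_precision="round_trip")
    label = f"{source_id}/{replicate_id} ({path})"

    for fieldname in ("mz", "charge", "rt", "abundance"):
        if cols[fieldname] not in frame.columns:
            raise IonTableError(
                f"ion table {label} is missing required column {cols[fieldname]!r} "
                f"(mapped from field {fieldname!r}); found {list(frame.columns)}"
            )

    numeric = {}
    for fieldname in ("mz", "charge", "rt", "abundance"):
        raw = frame[cols[fieldname]]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            idx = int(bad.idxmax())
            raise IonTableError(
                f"non-numeric value {raw[idx]!r} in column {cols[fieldname]!r} "
                f"of {label} at row {idx}"
            )
        if parsed.isna().any():
            idx = int(parsed.isna().idxmax())
            raise IonTableError(f"missing value in column {cols[fieldname]!r} of {label} at row {idx}")
        numeric[fieldname] = parsed

    charge = numeric["charge"]
    if not (charge == charge.round()).all():
        idx = int((charge != charge.round()).idxmax())
        raise IonTableError(f"non-integer charge {charge[idx]!r} in {label} at row {idx}")

    if cols["ion_id"] in frame.columns:
        ids = list(frame[cols["ion_id"]])
    else:
        ids = list(range(len(frame)))

    rt_scale = 1.0 / 60.0 if rt_in_seconds else 1.0
    rows = [
        PeptideIon(
            ion_id=ids[i],
            mz=float(numeric["mz"].iloc[i]),
            charge=int(charge.iloc[i]),
            rt=float(numeric["rt"].iloc[i]) * rt_scale,
            abundance=float(numeric["abundance"].iloc[i]),
        )
        for i in range(len(frame))
    ]
    _validate_rows(rows, label)
    return IonTable(source_id=source_id, replicate_id=replicate_id, ions=tuple(rows))


def write_ion_table(table: IonTable, path) -> None:
    """Write ``table`` as CSV, re-readable with bit-identical numeric values.

    Floats are serialized with ``repr`` (shortest round-trip) precision.
    """
    _validate_rows(list(table.ions), f"{table.source_id}/{table.replicate_id}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ion_id", "mz", "charge", "rt_min", "abundance"])
        for ion in table.ions:
            writer.writerow([ion.ion_id, repr(ion.mz), ion.charge, repr(ion.rt),
                             repr(ion.abundance)])


@dataclass(frozen=True)
class BioReadoutTable:
    """Long-format biological read-outs: (source_id, replicate_id, variable, value).

    Values are non-negative reals in each assay's units (relative-to-control
    or concentration). Every (source, variable) group is expected to hold at
    least three replicates before outlier screening; fewer is logged as a
    warning, not an error.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("source_id", "replicate_id", "variable", "value")

    def __post_init__(self):
        frame = self.data
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise BioTableError(f"bio table missing column(s) {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        values = pd.to_numeric(frame["value"], errors="coerce")
        if values.isna().any():
            idx = int(values.isna().idxmax())
            raise BioTableError(f"non-numeric value {frame['value'][idx]!r} at row {idx}")
        if (values < 0).any():
            idx = int((values < 0).idxmax())
            raise BioTableError(f"negative read-out value {values[idx]!r} at row {idx}")
        frame = frame.assign(value=values.astype(float))
        dup = frame.duplicated(subset=["source_id", "replicate_id", "variable"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise BioTableError(
                "duplicate (source, replicate, variable) row: "
                f"({row.source_id!r}, {row.replicate_id!r}, {row.variable!r})"
            )
        counts = frame.groupby(["source_id", "variable"], sort=False).size()
        under = counts[counts < 3]
        if len(under):
            examples = ", ".join(f"({s}, {v}): {n}" for (s, v), n in under.head(3).items())
            logger.warning(
                "bio table has %d (source, variable) group(s) with fewer than 3 "
                "replicates, e.g. %s", len(under), examples,
            )
        object.__setattr__(self, "data", frame)

    @property
    def sources(self) -> list[str]:
        return list(dict.fromkeys(self.data["source_id"]))

    @property
    def variables(self) -> list[str]:
        return list(dict.fromkeys(self.data["variable"]))

    def values_for(self, source_id: str, variable: str):
        mask = (self.data["source_id"] == source_id) & (self.data["variable"] == variable)
        return self.data.loc[mask, "value"].to_numpy()

    def replicate_means(self) -> pd.DataFrame:
        """Per-source mean over replicates, one column per variable."""
        wide = self.data.pivot_table(
            index="source_id", columns="variable", values="value", aggfunc="mean", sort=False
        )
        return wide.reindex(index=self.sources, columns=self.variables)


def read_bio_table(path) -> BioReadoutTable:
    """Read a long-format biological read-out CSV."""
    return BioReadoutTable(pd.read_csv(path))


def write_bio_table(table: BioReadoutTable, path) -> None:
    table.data.to_csv(path, index=False)
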