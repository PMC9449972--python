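"""Reading, referencing and assembly of variable-temperature HSQC peak lists.

A thermal series experiment records one assigned ``15N–1H`` HSQC spectrum per
temperature.  Each cross-peak contributes a :class:`PeakRecord` (residue,
amide 1H and 15N chemical shifts in ppm, peak intensity).  The records from
every temperature are assembled into a :class:`TemperatureSeries`, the central
container the downstream trajectory / intensity / correlation analyses
operate on.

Two plain-text peak-list dialects are supported:

``tsv``
    One table for the whole series with header
    ``residue_index  residue_type  temperature_K  delta_H_ppm  delta_N_ppm
    intensity`` (tab-separated, ``#`` comments allowed).

``sparky``
    Sparky-style ``.list`` files, one per temperature, with lines like
    ``Q134N-H   119.400   8.120   1.0e6``.  The temperature is not part of
    the format; it is supplied out of band, conventionally encoded in the
    filename suffix ``_<kelvin>K.list`` (see :func:`temperature_from_filename`).
"""

from __future__ import annotations

import io
import logging
import math
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger("hsqcmelt")

__all__ = [
    "PeakRecord",
    "TemperatureSeries",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "parse_sparky_assignment",
    "temperature_from_filename",
    "reference_to_tsp",
    "assemble_series",
    "filter_missing",
    "NITROGEN_FREQUENCY_RATIO",
]

#: IUPAC frequency ratio Xi(15N)/Xi(1H) used for indirect 15N referencing.
NITROGEN_FREQUENCY_RATIO = 0.101329118

TSV_COLUMNS = (
    "residue_index",
    "residue_type",
    "temperature_K",
    "delta_H_ppm",
    "delta_N_ppm",
    "intensity",
)

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")


class PeakTableError(ValueError):
    """Malformed peak-list input (bad header, unparsable row, conflict)."""


@dataclass(frozen=True)
class PeakRecord:
    """One assigned cross-peak at one temperature.

    Parameters
    ----------
    residue_index : int
        Residue number in the pipeline's canonical (mature-sequence)
        numbering.
    residue_type : str
        One-letter amino-acid code (``X`` when unknown).
    temperature : float
        Sample temperature in kelvin.
    delta_h, delta_n : float
        Amide 1H and 15N chemical shifts in ppm.
    intensity : float
        Peak intensity (height or volume), arbitrary units, non-negative.
    """

    residue_index: int
    residue_type: str
    temperature: float
    delta_h: float
    delta_n: float
    intensity: float

    def validate(self) -> None:
        """Range-check the record; raise :class:`ValueError` on violation.

        The windows are generous amide-region bounds meant to catch unit
        mistakes (Celsius vs kelvin, Hz vs ppm), not to enforce chemistry.
        """
        if not (200.0 <= self.temperature <= 400.0):
            raise ValueError(
                f"residue {self.residue_index}: temperature {self.temperature} K "
                "outside [200, 400] K"
            )
        if self.intensity < 0:
            raise ValueError(
                f"residue {self.residue_index}: negative intensity {self.intensity}"
            )
        if not (-2.0 <= self.delta_h <= 15.0):
            raise ValueError(
                f"residue {self.residue_index}: delta_H {self.delta_h} ppm "
                "outside [-2, 15] ppm"
            )
        if not (90.0 <= self.delta_n <= 140.0):
            raise ValueError(
                f"residue {self.residue_index}: delta_N {self.delta_n} ppm "
                "outside [90, 140] ppm"
            )


class TemperatureSeries:
    """Per-residue map ``temperature -> PeakRecord`` over a common grid.

    The temperature grid is the sorted set of distinct temperatures seen in
    the input; a residue without a record at a grid temperature is *missing*
    there.  ``reference_offsets`` documents any chemical-shift referencing
    applied per temperature (1H offset, 15N offset, in ppm).
    """

    def __init__(
        self,
        records: Mapping[tuple[int, float], PeakRecord],
        temperatures: Sequence[float],
        reference_offsets: Mapping[float, tuple[float, float]] | None = None,
    ):
        self._records = dict(records)
        self.temperatures = sorted(float(t) for t in temperatures)
        if any(
            t2 <= t1 for t1, t2 in zip(self.temperatures, self.temperatures[1:])
        ):
            raise ValueError("temperature grid must be strictly increasing")
        grid = set(self.temperatures)
        for (res, t) in self._records:
            if t not in grid:
                raise ValueError(
                    f"record at {t} K for residue {res} is off the grid"
                )
        self.reference_offsets = dict(reference_offsets or {})

    @property
    def residues(self) -> list[int]:
        return sorted({res for res, _ in self._records})

    def get(self, residue: int, temperature: float) -> PeakRecord | None:
        return self._records.get((residue, float(temperature)))

    def observed(self, residue: int) -> list[PeakRecord]:
        """Records for one residue ordered by temperature."""
        return [
            self._records[(residue, t)]
            for t in self.temperatures
            if (residue, t) in self._records
        ]

    def observed_temperatures(self, residue: int) -> list[float]:
        return [t for t in self.temperatures if (residue, t) in self._records]

    def missing_count(self, residue: int) -> int:
        return len(self.temperatures) - len(self.observed_temperatures(residue))

    def iter_records(self) -> Iterable[PeakRecord]:
        for t in self.temperatures:
            for res in self.residues:
                rec = self._records.get((res, t))
                if rec is not None:
                    yield rec

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per observed record."""
        rows = [
            (r.residue_index, r.residue_type, r.temperature, r.delta_h,
             r.delta_n, r.intensity)
            for r in self.iter_records()
        ]
        return pd.DataFrame(rows, columns=TSV_COLUMNS)

    def subset(self, residues: Iterable[int]) -> "TemperatureSeries":
        keep = set(residues)
        recs = {k: v for k, v in self._records.items() if k[0] in keep}
        return TemperatureSeries(recs, self.temperatures, self.reference_offsets)

    def __len__(self) -> int:
        return len(self._records)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<TemperatureSeries: {len(self.residues)} residues x "
            f"{len(self.temperatures)} temperatures, {len(self)} records>"
        )


_SPARKY_ASSIGNMENT = re.compile(
    r"^(?P<type>[A-Za-z])(?P<index>\d+)(?P<atoms>[A-Za-z0-9'\-]*)$"
)


def parse_sparky_assignment(text: str) -> tuple[str, int]:
    """Parse a Sparky assignment label like ``Q134N-H`` into ``('Q', 134)``."""
    m = _SPARKY_ASSIGNMENT.match(text.strip())
    if m is None:
        raise PeakTableError(f"unparsable assignment string {text!r}")
    res_type = m.group("type").upper()
    if res_type not in _AA1 and res_type != "X":
        raise PeakTableError(
            f"assignment {text!r}: unknown residue type {res_type!r}"
        )
    return res_type, int(m.group("index"))


def temperature_from_filename(name: str | Path) -> float:
    """Extract the kelvin value from a ``..._<kelvin>K.list`` filename."""
    m = re.search(r"_(\d+(?:\.\d+)?)K\.list$", str(name))
    if m is None:
        raise PeakTableError(
            f"cannot read a temperature from filename {name!r}; expected a "
            "suffix like '_303K.list'"
        )
    return float(m.group(1))


def _open_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_peak_table(
    source: str | Path | TextIO,
    dialect: str = "tsv",
    *,
    temperature: float | None = None,
    residue_offset: int = 0,
    validate: bool = True,
) -> list[PeakRecord]:
    """Read a peak list into :class:`PeakRecord` objects.

    Parameters
    ----------
    source : path or text stream
    dialect : {'tsv', 'sparky'}
    temperature : float, optional
        Required for the ``sparky`` dialect, which does not carry the
        temperature in the file body.
    residue_offset : int
        Added to every residue index on read, mapping the file's numbering
        onto the pipeline's canonical (mature-sequence) numbering.
    validate : bool
        Range-check each record (see :meth:`PeakRecord.validate`).

    Raises
    ------
    PeakTableError
        On a malformed header (naming the missing column) or on any row
        that cannot be parsed (naming the line number).
    """
    if dialect not in ("tsv", "sparky"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    stream, close = _open_text(source)
    try:
        if dialect == "tsv":
            records = _read_tsv(stream, residue_offset)
        else:
            if temperature is None:
                raise ValueError(
                    "the sparky dialect needs an out-of-band temperature"
                )
            records = _read_sparky(stream, float(temperature), residue_offset)
    finally:
        if close:
            stream.close()
    if validate:
        errors = []
        for i, rec in enumerate(records):
            try:
                rec.validate()
            except ValueError as exc:
                errors.append(str(exc))
        if errors:
            raise PeakTableError(
                "validation failed for {} record(s):\n  {}".format(
                    len(errors), "\n  ".join(errors)
                )
            )
    return records


def _read_tsv(stream: TextIO, residue_offset: int) -> list[PeakRecord]:
    header: list[str] | None = None
    records: list[PeakRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in TSV_COLUMNS if c not in header]
            if missing:
                raise PeakTableError(
                    f"line {lineno}: header is missing column(s) "
                    + ", ".join(missing)
                )
            continue
        if len(fields) != len(header):
            raise PeakTableError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        try:
            records.append(
                PeakRecord(
                    residue_index=int(row["residue_index"]) + residue_offset,
                    residue_type=row["residue_type"].strip().upper(),
                    temperature=float(row["temperature_K"]),
                    delta_h=float(row["delta_H_ppm"]),
                    delta_n=float(row["delta_N_ppm"]),
                    intensity=float(row["intensity"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise PeakTableError(f"line {lineno}: {exc}") from exc
    if header is None:
        raise PeakTableError("empty input: no header line found")
    return records


def _read_sparky(
    stream: TextIO, temperature: float, residue_offset: int
) -> list[PeakRecord]:
    records: list[PeakRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.split()[0].lower() == "assignment":  # Sparky header line
            continue
        fields = line.split()
        if len(fields) < 4:
            raise PeakTableError(
                f"line {lineno}: expected 'assignment w1 w2 intensity', "
                f"got {line!r}"
            )
        try:
            res_type, res_index = parse_sparky_assignment(fields[0])
            # Sparky lists 15N (w1) before 1H (w2)
            delta_n = float(fields[1])
            delta_h = float(fields[2])
            intensity = float(fields[3])
        except (PeakTableError, ValueError) as exc:
            raise PeakTableError(f"line {lineno}: {exc}") from exc
        records.append(
            PeakRecord(
                residue_index=res_index + residue_offset,
                residue_type=res_type,
                temperature=temperature,
                delta_h=delta_h,
                delta_n=delta_n,
                intensity=intensity,
            )
        )
    return records


def write_peak_table(
    records: Iterable[PeakRecord],
    destination: str | Path | TextIO,
    dialect: str = "tsv",
) -> None:
    """Write records in the given dialect (inverse of :func:`read_peak_table`).

    Float fields are written with :func:`repr` so a read/write round trip is
    bit-exact.  For the ``sparky`` dialect all records must share one
    temperature (one ``.list`` file per temperature).
    """
    records = list(records)
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8") as fh:
            write_peak_table(records, fh, dialect)
        return
    out: TextIO = destination
    if dialect == "tsv":
        out.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            out.write(
                f"{int(r.residue_index)}\t{r.residue_type}\t"
                f"{float(r.temperature)!r}\t{float(r.delta_h)!r}\t"
                f"{float(r.delta_n)!r}\t{float(r.intensity)!r}\n"
            )
    elif dialect == "sparky":
        temps = {r.temperature for r in records}
        if len(temps) > 1:
            raise ValueError(
                "sparky .list files hold one temperature each; "
                f"got {sorted(temps)}"
            )
        out.write("      Assignment         w1         w2   Data Height\n")
        for r in records:
            out.write(
                f"{r.residue_type}{int(r.residue_index)}N-H "
                f"{float(r.delta_n)!r} {float(r.delta_h)!r} "
                f"{float(r.intensity)!r}\n"
            )
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


def reference_to_tsp(
    records: Sequence[PeakRecord],
    tsp_shift_h: float,
    *,
    indirect_nitrogen: bool = True,
    frequency_ratio: float = NITROGEN_FREQUENCY_RATIO,
) -> tuple[list[PeakRecord], tuple[float, float]]:
    """Zero the 1H axis to the observed TSP signal, optionally re-zeroing 15N.

    ``tsp_shift_h`` is the apparent ppm position of the TSP 1H signal in this
    spectrum; it is subtracted from every 1H shift.  With
    ``indirect_nitrogen`` the 15N zero is recomputed from the corrected 1H
    reference frequency through the gyromagnetic frequency ratio
    Xi = ``frequency_ratio``: the 15N reference frequency is Xi times the 1H
    reference frequency, so scaling the latter by ``(1 + tsp_shift_h * 1e-6)``
    scales the former identically and shifts every 15N ppm value by

        delta_n' = (delta_n - tsp_shift_h) / (1 + tsp_shift_h * 1e-6)

    (Xi cancels in ppm units; to first order the 15N axis moves by the same
    ppm offset as 1H).  Returns the corrected records and the
    ``(h_offset, n_offset)`` pair actually applied, for logging in
    :attr:`TemperatureSeries.reference_offsets`.
    """
    if not math.isfinite(tsp_shift_h):
        raise ValueError("tsp_shift_h must be finite")
    if frequency_ratio <= 0:
        raise ValueError("frequency_ratio must be positive")
    scale = 1.0 + tsp_shift_h * 1e-6
    out = []
    n_offset = 0.0
    for r in records:
        new_h = r.delta_h - tsp_shift_h
        if indirect_nitrogen:
            new_n = (r.delta_n - tsp_shift_h) / scale
            n_offset = tsp_shift_h
        else:
            new_n = r.delta_n
        out.append(replace(r, delta_h=new_h, delta_n=new_n))
    return out, (tsp_shift_h, n_offset)


def assemble_series(
    records: Iterable[PeakRecord],
    reference_offsets: Mapping[float, tuple[float, float]] | None = None,
) -> TemperatureSeries:
    """Assemble loose records into a :class:`TemperatureSeries`.

    The grid is the sorted set of distinct temperatures.  Bit-identical
    duplicates are collapsed with a warning; records that share
    ``(residue, temperature)`` but differ in any field are a conflict error.
    The result is independent of input order.
    """
    table: dict[tuple[int, float], PeakRecord] = {}
    for rec in records:
        key = (rec.residue_index, float(rec.temperature))
        prev = table.get(key)
        if prev is None:
            table[key] = rec
        elif prev == rec:
            warnings.warn(
                f"duplicate record for residue {key[0]} at {key[1]} K "
                "(identical fields, deduplicated)",
                stacklevel=2,
            )
        else:
            raise PeakTableError(
                f"conflicting records for residue {key[0]} at {key[1]} K:\n"
                f"  {prev}\n  {rec}"
            )
    temps = sorted({t for _, t in table})
    return TemperatureSeries(table, temps, reference_offsets)


def filter_missing(
    series: TemperatureSeries, max_missing: int = 3
) -> TemperatureSeries:
    """Drop residues observed at too few temperatures.

    A residue missing at more than ``max_missing`` grid temperatures is
    removed (the default of 3 keeps a residue absent at exactly three
    points).  Removals are logged.  Idempotent, and monotone in
    ``max_missing``.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    dropped = [
        res for res in series.residues if series.missing_count(res) > max_missing
    ]
    if dropped:
        logger.info(
            "filter_missing: dropped %d residue(s) with > %d missing "
            "temperature points: %s",
            len(dropped), max_missing, dropped,
        )
    keep = [r for r in series.residues if r not in set(dropped)]
    return series.subset(keep)
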