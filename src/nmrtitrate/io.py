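"""Titration data model and CSV round-trip.

A titration experiment is an ordered sequence of aliquot additions.  After
each addition a spectrum and a pH reading are recorded, so the fundamental
record is ``(aliquot, branch, pH, {probe: shift})``: the branch tag says
which titrant produced the point (``initial`` for the spectrum taken before
any titrant, ``base``/``acid`` for the two titration directions), and the
shift map carries the ppm positions of the reporter nuclei that were
actually resolved in that spectrum (entries may be missing per point).

The on-disk format is a plain UTF-8 CSV with header
``aliquot,branch,pH,<probe>,...`` preceded by optional ``#``-comment
metadata lines (``# compound: ...``, ``# temperature_K: ...``).  Shifts are
written with shortest-round-trip precision so that read(write(s)) == s
field by field and a second write is byte-identical.

pH values are meter readings in the deuterated solvent, stored as read
(no pD correction is applied anywhere in the package).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BRANCHES",
    "TitrationPoint",
    "TitrationSeries",
    "TitrationError",
    "TitrationFormatError",
    "TitrationParseError",
    "ValidationError",
    "DegenerateDataError",
    "DegenerateSeriesWarning",
    "read_titration_csv",
    "write_titration_csv",
    "select_branch",
]

#: Recognized branch tags, in the order they normally occur.
BRANCHES = ("initial", "base", "acid")


class TitrationError(Exception):
    """Base class for all errors raised by this package."""


class TitrationFormatError(TitrationError):
    """The file does not have the expected table structure."""


class TitrationParseError(TitrationError):
    """A cell could not be parsed; the message cites the offending row."""


class ValidationError(TitrationError):
    """A series violates a structural invariant."""


class DegenerateDataError(TitrationError):
    """Too few usable points for the requested analysis."""


class DegenerateSeriesWarning(UserWarning):
    """A selection produced a series too small for any downstream fit."""


@dataclass(frozen=True)
class TitrationPoint:
    """One aliquot: a pH reading plus the observed shifts (ppm) per probe."""

    aliquot: int
    branch: str
    pH: float
    shifts: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValidationError(
                f"unknown branch {self.branch!r}; expected one of {BRANCHES}"
            )
        if self.aliquot < 0:
            raise ValidationError("aliquot index must be non-negative")
        if not math.isfinite(self.pH):
            raise ValidationError(f"non-finite pH at aliquot {self.aliquot}")
        for probe, value in self.shifts.items():
            if not probe:
                raise ValidationError("empty probe label")
            if not math.isfinite(value):
                raise ValidationError(
                    f"non-finite shift for probe {probe!r} at aliquot {self.aliquot}"
                )


@dataclass
class TitrationSeries:
    """Ordered titration records for one compound.

    Parameters
    ----------
    compound:
        Free-text metadata (name, substituent, solvent, ...).
    temperature:
        Sample temperature in kelvin.
    points:
        The records, ordered by aliquot.  At most one point may carry the
        ``initial`` tag and, when present, it must come first.
    probes:
        All probe labels used anywhere in ``points``.  Derived automatically
        when omitted.
    """

    compound: str = ""
    temperature: float = 296.15
    points: list[TitrationPoint] = field(default_factory=list)
    probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.points:
            seen.update(p.shifts)
        if not self.probes:
            self.probes = tuple(sorted(seen))
        elif not seen <= set(self.probes):
            missing = sorted(seen - set(self.probes))
            raise ValidationError(f"probes {missing} used but not declared")
        self.validate()

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (kelvin)")
        aliquots = [p.aliquot for p in self.points]
        if any(b >= a for a, b in zip(aliquots[1:], aliquots)):
            raise ValidationError("aliquot indices must be strictly increasing")
        initial = [i for i, p in enumerate(self.points) if p.branch == "initial"]
        if len(initial) > 1:
            raise ValidationError("more than one point tagged 'initial'")
        if initial and initial[0] != 0:
            raise ValidationError("the 'initial' point must come first")

    def __len__(self) -> int:
        return len(self.points)

    def pH_values(self) -> list[float]:
        return [p.pH for p in self.points]

    def shifts_for(self, probe: str) -> list[tuple[float, float]]:
        """(pH, shift) pairs for the points where *probe* was observed."""
        return [(p.pH, p.shifts[probe]) for p in self.points if probe in p.shifts]


_MANDATORY = ("aliquot", "branch", "pH")


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """Read a titration table written in the dialect of this package.

    Raises
    ------
    TitrationFormatError
        If a mandatory column (``aliquot``, ``branch``, ``pH``) is missing.
    TitrationParseError
        If a numeric cell does not parse; the message cites the data row.
    ValidationError
        If the parsed series violates a structural invariant
        (duplicate aliquot indices, misplaced ``initial`` tag, ...).
    """
    path = Path(path)
    compound = ""
    temperature = 296.15
    header: list[str] | None = None
    rows: list[list[str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        for raw in csv.reader(fh):
            if not raw:
                continue
            if raw[0].startswith("#"):
                key, _, value = raw[0].lstrip("# ").partition(":")
                if key.strip() == "compound":
                    compound = value.strip()
                elif key.strip() == "temperature_K":
                    temperature = float(value.strip())
                continue
            if header is None:
                header = [c.strip() for c in raw]
            else:
                rows.append(raw)
    if header is None:
        raise TitrationFormatError(f"{path}: no header row found")
    for column in _MANDATORY:
        if column not in header:
            raise TitrationFormatError(f"{path}: missing mandatory column {column!r}")
    probes = tuple(c for c in header if c not in _MANDATORY)
    idx = {c: header.index(c) for c in header}

    points: list[TitrationPoint] = []
    for n, row in enumerate(rows, start=2):  # row 1 is the header
        def cell(column: str) -> str:
            i = idx[column]
            return row[i].strip() if i < len(row) else ""

        try:
            aliquot = int(cell("aliquot"))
        except ValueError:
            raise TitrationParseError(
                f"{path}: row {n}: non-integer aliquot {cell('aliquot')!r}"
            ) from None
        try:
            pH = float(cell("pH"))
        except ValueError:
            raise TitrationParseError(
                f"{path}: row {n}: non-numeric pH {cell('pH')!r}"
            ) from None
        shifts: dict[str, float] = {}
        for probe in probes:
            text = cell(probe)
            if text == "":
                continue  # absent observation, not an error
            try:
                shifts[probe] = float(text)
            except ValueError:
                raise TitrationParseError(
                    f"{path}: row {n}: non-numeric shift {text!r} for probe {probe!r}"
                ) from None
        points.append(TitrationPoint(aliquot, cell("branch"), pH, shifts))

    aliquots = [p.aliquot for p in points]
    if len(set(aliquots)) != len(aliquots):
        dup = sorted({a for a in aliquots if aliquots.count(a) > 1})
        raise ValidationError(f"{path}: duplicate aliquot index {dup[0]}")
    return TitrationSeries(compound, temperature, points, probes)


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    """Write *series* in the dialect read by :func:`read_titration_csv`.

    Floats are written with ``repr`` (shortest round-trip form), so stored
    precision is at least the full double precision of the values and a
    write→read→write cycle is byte-stable.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if series.compound:
            fh.write(f"# compound: {series.compound}\n")
        fh.write(f"# temperature_K: {series.temperature!r}\n")
        writer.writerow(list(_MANDATORY) + list(series.probes))
        for p in series.points:
            row = [str(p.aliquot), p.branch, repr(p.pH)]
            row += [
                repr(p.shifts[probe]) if probe in p.shifts else ""
                for probe in series.probes
            ]
            writer.writerow(row)


def select_branch(
    series: TitrationSeries, branches: Iterable[str]
) -> TitrationSeries:
    """Restrict a series to the points whose branch tag is in *branches*.

    Ordering and metadata are preserved; the probe declaration is kept even
    if some probes no longer occur.  Selecting fewer than two points emits a
    :class:`DegenerateSeriesWarning` (downstream fits will refuse such a
    series) but still returns it.
    """
    wanted = set(branches)
    if not wanted:
        raise ValueError("branches must be non-empty")
    unknown = wanted - set(BRANCHES)
    if unknown:
        raise ValueError(f"unknown branch tags {sorted(unknown)}")
    points = [p for p in series.points if p.branch in wanted]
    if len(points) < 2:
        warnings.warn(
            f"branch selection {sorted(wanted)} kept only {len(points)} point(s)",
            DegenerateSeriesWarning,
            stacklevel=2,
        )
    return replace(series, points=points)
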