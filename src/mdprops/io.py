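"""Readers and writers for MD-engine tables, coordinate frames and results.

Tabular input comes either in the engine-table dialect (xvg-style: ``#`` and
``@`` lines are comments, whitespace-separated numeric rows) or as delimited
text with a ``name [unit]`` header.  Coordinates come as GRO (fixed width,
nm — parsed with MDAnalysis) or extended XYZ with a ``Lattice="..."``
comment.  All analyses downstream consume only the containers in
:mod:`mdprops.types`; no other module parses files.
"""

from __future__ import annotations

import io as _io
import json
import re
import warnings
from typing import Iterable, Sequence, TextIO

import numpy as np

from .types import (
    DIMENSIONLESS,
    ConfigurationFrame,
    ParseError,
    PropertyResult,
    TimeSeriesTable,
    UnsupportedError,
)

BAR_TO_GPA = 1e-4

_RESULT_FIELDS = ["name", "value", "unit", "error", "provenance"]


def _as_stream(source) -> TextIO:
    if isinstance(source, str):
        return _io.StringIO(source)
    return source


# ---------------------------------------------------------------------------
# tables


def read_table(
    source,
    dialect: str = "engine",
    columns: Sequence[tuple[str, str]] | None = None,
    pressure_bar_columns: Iterable[str] = (),
) -> TimeSeriesTable:
    """Parse a numeric table from a text stream or string.

    dialect "engine": lines starting with '#' or '@' are comments; axis
    labels in ``@ xaxis label`` / ``@ sN legend`` lines are used as column
    names when no explicit ``columns`` are given.  dialect "delimited":
    comma-separated with one ``name [unit]`` header row.

    Columns listed in ``pressure_bar_columns`` are converted from bar to GPa
    on read (1 bar = 1e-4 GPa).
    """
    stream = _as_stream(source)
    if dialect == "engine":
        table = _read_engine_table(stream, columns)
    elif dialect == "delimited":
        table = _read_delimited_table(stream, columns)
    else:
        raise ValueError(f"unknown table dialect {dialect!r}")
    for name in pressure_bar_columns:
        i = table.names.index(name)
        table.values[:, i] *= BAR_TO_GPA
        table.columns[i] = (name, "GPa")
    return table


def _read_engine_table(stream: TextIO, columns) -> TimeSeriesTable:
    rows: list[list[float]] = []
    legends: dict[int, str] = {}
    xlabel = None
    for lineno, line in enumerate(stream, start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith("#"):
            continue
        if text.startswith("@"):
            m = re.match(r'@\s*xaxis\s+label\s+"(.*)"', text)
            if m:
                xlabel = m.group(1)
            m = re.match(r'@\s*s(\d+)\s+legend\s+"(.*)"', text)
            if m:
                legends[int(m.group(1))] = m.group(2)
            continue
        try:
            row = [float(tok) for tok in text.split()]
        except ValueError:
            raise ParseError(f"non-numeric payload on line {lineno}: {text!r}")
        if rows and len(row) != len(rows[0]):
            raise ParseError(
                f"inconsistent arity on line {lineno}: "
                f"expected {len(rows[0])} fields, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise ParseError("no data rows")
    arity = len(rows[0])
    if columns is None:
        names = [xlabel or "x"] + [legends.get(i, f"y{i}") for i in range(arity - 1)]
        columns = [(_strip_unit(n)[0], _strip_unit(n)[1]) for n in names]
    return TimeSeriesTable(columns=list(columns), values=np.array(rows))


def _strip_unit(label: str) -> tuple[str, str]:
    m = re.match(r"(.*?)\s*[\[(]([^\])]+)[\])]\s*$", label)
    if m:
        return m.group(1).strip() or "x", m.group(2).strip()
    return label, DIMENSIONLESS


def _read_delimited_table(stream: TextIO, columns) -> TimeSeriesTable:
    lines = [ln for ln in (raw.strip() for raw in stream) if ln]
    if not lines:
        raise ParseError("no data rows")
    header = [h.strip() for h in lines[0].split(",")]
    if columns is None:
        columns = [_strip_unit(h) for h in header]
    rows = []
    for lineno, text in enumerate(lines[1:], start=2):
        try:
            row = [float(tok) for tok in text.split(",")]
        except ValueError:
            raise ParseError(f"non-numeric payload on line {lineno}: {text!r}")
        if len(row) != len(columns):
            raise ParseError(f"inconsistent arity on line {lineno}")
        rows.append(row)
    if not rows:
        raise ParseError("no data rows")
    return TimeSeriesTable(columns=list(columns), values=np.array(rows))


def write_table(table: TimeSeriesTable, sink) -> None:
    """Write a table as delimited text, full float precision (round-trips)."""
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w")
        close = True
    try:
        sink.write(",".join(f"{n} [{u}]" for n, u in table.columns) + "\n")
        for row in table.values:
            sink.write(",".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            sink.close()


# ---------------------------------------------------------------------------
# coordinate frames


def read_frame(source, format: str = "gro", xyz_unit: str = "nm") -> ConfigurationFrame:
    """Read one coordinate frame (GRO or extended XYZ) into nm.

    Extended-XYZ coordinates are interpreted in ``xyz_unit`` ("nm" or
    "angstrom").  A missing or triclinic box is an error: all periodic
    analyses require an orthorhombic box.
    """
    stream = _as_stream(source)
    if format == "gro":
        return _read_gro(stream)
    if format in ("extxyz", "xyz"):
        return _read_extxyz(stream, xyz_unit)
    raise ValueError(f"unknown frame format {format!r}")


def _read_gro(stream: TextIO) -> ConfigurationFrame:
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    text = stream.read()
    # validate declared atom count before handing to the parser
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("truncated GRO frame")
    try:
        declared = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise ParseError("GRO atom-count line is not an integer")
    box_fields = lines[2 + declared].split() if len(lines) > 2 + declared else None
    if box_fields is None:
        raise ParseError("GRO frame truncated: missing atom lines or box line")
    if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
        raise UnsupportedError("triclinic boxes are unsupported (orthorhombic only)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(NamedStream(_io.StringIO(text), "frame.gro"))
        except Exception as exc:  # MDAnalysis raises assorted types
            raise ParseError(f"cannot parse GRO frame: {exc}") from exc
    if u.atoms.n_atoms != declared:
        raise ParseError(
            f"GRO declares {declared} atoms but {u.atoms.n_atoms} were parsed"
        )
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ParseError("GRO frame has no box; periodic analyses require one")
    names = u.atoms.names.astype(object)
    elements = np.array([_element_from_name(n) for n in names], dtype=object)
    return ConfigurationFrame(
        elements=elements,
        names=names,
        mol_index=u.atoms.resids - u.atoms.resids.min(),
        positions=u.atoms.positions / 10.0,  # A -> nm
        box=dims[:3] / 10.0,
    )


def _element_from_name(name: str) -> str:
    m = re.match(r"[A-Za-z]+", name)
    sym = (m.group(0) if m else name)[:2].capitalize()
    # atom names are mostly element + suffix; two-letter symbols rare here
    if sym[:1] in "HCNOSP" and sym not in ("Cl", "Na", "Si"):
        return sym[0]
    return sym


def _read_extxyz(stream: TextIO, unit: str) -> ConfigurationFrame:
    scale = {"nm": 1.0, "angstrom": 0.1, "A": 0.1}.get(unit)
    if scale is None:
        raise ValueError(f"unknown xyz unit {unit!r}")
    lines = [ln.rstrip("\n") for ln in stream]
    if len(lines) < 2:
        raise ParseError("truncated extended-XYZ frame")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("extended-XYZ count line is not an integer")
    m = re.search(r'Lattice="([^"]+)"', lines[1])
    if not m:
        raise ParseError("extended-XYZ comment has no Lattice; a box is required")
    lat = np.array([float(v) for v in m.group(1).split()])
    if lat.size != 9:
        raise ParseError("Lattice must have 9 components")
    lat = lat.reshape(3, 3) * scale
    off = lat - np.diag(np.diag(lat))
    if np.any(np.abs(off) > 1e-9):
        raise UnsupportedError("triclinic boxes are unsupported (orthorhombic only)")
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise ParseError(f"extended-XYZ declares {n} atoms, found {len(atom_lines)}")
    elements, names, mols, pos = [], [], [], []
    for lineno, ln in enumerate(atom_lines[:n], start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"short atom line {lineno}")
        elements.append(parts[0])
        names.append(parts[0])
        try:
            pos.append([float(v) * scale for v in parts[1:4]])
        except ValueError:
            raise ParseError(f"non-numeric coordinate on line {lineno}")
        mols.append(int(parts[4]) if len(parts) > 4 else 0)
    return ConfigurationFrame(
        elements=np.array(elements, dtype=object),
        names=np.array(names, dtype=object),
        mol_index=np.array(mols),
        positions=np.array(pos),
        box=np.diag(lat),
    )


def write_frame(frame: ConfigurationFrame, sink, format: str = "gro") -> None:
    """Write a frame in GRO (via MDAnalysis) or extended-XYZ (nm)."""
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w")
        close = True
    try:
        if format == "gro":
            _write_gro(frame, sink)
        elif format in ("extxyz", "xyz"):
            _write_extxyz(frame, sink)
        else:
            raise ValueError(f"unknown frame format {format!r}")
    finally:
        if close:
            sink.close()


def _write_gro(frame: ConfigurationFrame, sink: TextIO) -> None:
    import os
    import tempfile

    import MDAnalysis as mda

    n = frame.n_atoms
    resids = frame.mol_index + 1
    u = mda.Universe.empty(
        n, n_residues=max(len(np.unique(resids)), 1), atom_resindex=np.unique(
            resids, return_inverse=True)[1] if n else None, trajectory=True,
    )
    if n:
        u.add_TopologyAttr("names", frame.names.astype(str))
        u.add_TopologyAttr("resids", np.unique(resids))
        u.add_TopologyAttr("resnames", ["MOL"] * u.residues.n_residues)
        u.atoms.positions = frame.positions * 10.0
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    # the MDAnalysis writer closes its target, so go through a scratch file
    fd, path = tempfile.mkstemp(suffix=".gro")
    os.close(fd)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(path)
        with open(path) as fh:
            sink.write(fh.read())
    finally:
        os.unlink(path)


def _write_extxyz(frame: ConfigurationFrame, sink: TextIO) -> None:
    b = [float(v) for v in frame.box]
    lat = f'Lattice="{b[0]!r} 0.0 0.0 0.0 {b[1]!r} 0.0 0.0 0.0 {b[2]!r}"'
    sink.write(f"{frame.n_atoms}\n{lat} Properties=species:S:1:pos:R:3:mol:I:1\n")
    for el, p, m in zip(frame.elements, frame.positions, frame.mol_index):
        sink.write(
            f"{el} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r} {int(m)}\n"
        )


# ---------------------------------------------------------------------------
# results


def write_results(results: list[PropertyResult], sink) -> None:
    """Write results as delimited text: name, value, unit, error, provenance.

    Deterministic column order and full float precision; identical inputs
    produce byte-identical output.
    """
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w")
        close = True
    try:
        sink.write(",".join(_RESULT_FIELDS) + "\n")
        for r in results:
            err = "" if r.error is None else repr(float(r.error))
            prov = json.dumps(r.provenance, sort_keys=True)
            sink.write(
                f'{r.name},{float(r.value)!r},{r.unit},{err},"{prov.replace(chr(34), chr(34) * 2)}"\n'
            )
    finally:
        if close:
            sink.close()


def read_results(source) -> list[PropertyResult]:
    """Read back a results file written by :func:`write_results`."""
    import csv

    stream = _as_stream(source)
    reader = csv.DictReader(stream)
    out = []
    for rec in reader:
        out.append(
            PropertyResult(
                name=rec["name"],
                value=float(rec["value"]),
                unit=rec["unit"],
                error=float(rec["error"]) if rec["error"] else None,
                provenance=json.loads(rec["provenance"]) if rec["provenance"] else {},
            )
        )
    return out
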