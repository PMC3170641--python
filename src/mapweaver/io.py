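"""Readers and writers for the whitespace-delimited map-input dialects.

Six input dialects are supported, one file per chromosome:

========== ======================================================== =========
dialect    columns                                                  landmarks
========== ======================================================== =========
arm        arm(p|q)  size_mb  cm_male  cm_female                    no
band       band_id  size_mb  start_mb  end_mb                       no
fish       locus  band_start  band_end                              no
linkage    locus  cm_male  cm_female                                yes
breakpoints id  kb                                                  yes
orthologue locus  ref_bp  ref_chromosome                            yes
========== ======================================================== =========

Lines starting with ``#`` are comments; fields are tab-separated on output
and split on any whitespace on input.  The FISH-orthologue file shares the
``orthologue`` dialect.  Landmark rows are named ``ptr``, ``cen``, ``qtr``.
"""

from __future__ import annotations

import os
from typing import Sequence

from .errors import FormatError, ValidationError
from .records import (
    ArmSpec,
    BandSpec,
    BreakpointEntry,
    FishAssignment,
    LinkageEntry,
    MapEntry,
    OrthologueRecord,
)

DIALECTS = ("arm", "band", "fish", "linkage", "breakpoints", "orthologue")

_N_COLS = {
    "arm": 4,
    "band": 4,
    "fish": 3,
    "linkage": 3,
    "breakpoints": 2,
    "orthologue": 3,
}

_HEADERS = {
    "arm": "# arm\tsize_mb\tcm_male\tcm_female",
    "band": "# band\tsize_mb\tstart_mb\tend_mb",
    "fish": "# locus\tband_start\tband_end",
    "linkage": "# locus\tcm_male\tcm_female",
    "breakpoints": "# id\tkb",
    "orthologue": "# locus\tref_bp\tref_chromosome",
}


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: expected a number, got {token!r}") from None


def read_input_file(path: str | os.PathLike, dialect: str, *, unit: str = "bp") -> list:
    """Read one input file and return a list of validated records.

    ``unit`` applies to the orthologue dialect only: ``"kb"`` multiplies the
    position column by 1000 so all in-memory reference coordinates are bp.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    ncol = _N_COLS[dialect]
    records: list = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: dialect {dialect!r} needs {ncol} columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = _build_record(dialect, fields, path, lineno, unit)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            key = getattr(rec, "locus", None) or getattr(rec, "id", None) or getattr(
                rec, "band_id", None
            )
            if key is not None and dialect != "arm":
                if key in seen:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate name {key!r} in {dialect} file"
                    )
                seen.add(key)
            records.append(rec)
    return records


def _build_record(dialect: str, f: list[str], path, lineno: int, unit: str):
    num = lambda t: _parse_float(t, str(path), lineno)  # noqa: E731
    if dialect == "arm":
        return ArmSpec(arm=f[0], size_mb=num(f[1]), size_cm_male=num(f[2]), size_cm_female=num(f[3]))
    if dialect == "band":
        return BandSpec(band_id=f[0], size_mb=num(f[1]), start_mb=num(f[2]), end_mb=num(f[3]))
    if dialect == "fish":
        return FishAssignment(locus=f[0], band_start=f[1], band_end=f[2])
    if dialect == "linkage":
        return LinkageEntry(locus=f[0], cm_male=num(f[1]), cm_female=num(f[2]))
    if dialect == "breakpoints":
        return BreakpointEntry(id=f[0], kb=num(f[1]))
    # orthologue
    scale = 1000.0 if unit == "kb" else 1.0
    return OrthologueRecord(locus=f[0], ref_bp=num(f[1]) * scale, ref_chromosome=f[2])


def write_input_file(records: Sequence, dialect: str, path: str | os.PathLike) -> None:
    """Write records in the given dialect; round-trips through read_input_file."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [_HEADERS[dialect]]
    for rec in records:
        lines.append(_format_record(dialect, rec))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _format_record(dialect: str, rec) -> str:
    if dialect == "arm":
        return f"{rec.arm}\t{rec.size_mb:.3f}\t{rec.size_cm_male:.2f}\t{rec.size_cm_female:.2f}"
    if dialect == "band":
        return f"{rec.band_id}\t{rec.size_mb:.3f}\t{rec.start_mb:.3f}\t{rec.end_mb:.3f}"
    if dialect == "fish":
        return f"{rec.locus}\t{rec.band_start}\t{rec.band_end}"
    if dialect == "linkage":
        return f"{rec.locus}\t{rec.cm_male:.6g}\t{rec.cm_female:.6g}"
    if dialect == "breakpoints":
        return f"{rec.id}\t{rec.kb:.6g}"
    return f"{rec.locus}\t{rec.ref_bp:.6g}\t{rec.ref_chromosome}"


# ---------------------------------------------------------------------------
# Integrated / virtual map output

MAP_HEADER = "# locus\texternal_id\tkb\tconfidence\tcm\tband"


def write_map(entries: Sequence[MapEntry], path: str | os.PathLike, format: str = "tsv",
              chromosome: str = "chr", scaffold_rows: Sequence | None = None) -> None:
    """Write a map as TSV (locus, external id, kb, confidence, cM, band),
    BED (0-based half-open bp intervals, score = confidence) or AGP v2.1.

    kb is rounded to integer and cM to 2 dp at serialisation only.
    Entries must already be sorted by kb.
    """
    kbs = [e.kb for e in entries]
    if kbs != sorted(kbs):
        raise ValidationError("map entries must be sorted by kb before writing")
    if format == "tsv":
        lines = [MAP_HEADER]
        for e in entries:
            conf = "NA" if e.confidence is None else str(e.confidence)
            lines.append(
                f"{e.locus}\t{e.external_id or '-'}\t{round(e.kb):d}\t{conf}\t{e.cm:.2f}\t{e.band}"
            )
    elif format == "bed":
        lines = []
        for e in entries:
            start = int(round(e.kb)) * 1000
            score = 0 if e.confidence is None else e.confidence
            lines.append(f"{chromosome}\t{start}\t{start + 1000}\t{e.locus}\t{score}")
    elif format == "agp":
        lines = _agp_lines(entries, chromosome, scaffold_rows or [])
    else:
        raise ValueError(f"unknown map format {format!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _agp_lines(entries, chromosome, scaffold_rows) -> list[str]:
    """One AGP object per chromosome; scaffold_rows are ScaffoldAnchor-like
    objects with scaffold_id/start_kb/end_kb/orientation."""
    lines = ["##agp-version\t2.1"]
    part = 1
    prev_end = 0
    for anchor in sorted(scaffold_rows, key=lambda a: a.start_kb):
        start = int(round(anchor.start_kb)) * 1000 + 1
        end = max(int(round(anchor.end_kb)) * 1000, start)
        if start > prev_end + 1:
            lines.append(
                f"{chromosome}\t{prev_end + 1}\t{start - 1}\t{part}\tN\t{start - 1 - prev_end}"
                "\tscaffold\tyes\tmap"
            )
            part += 1
        orient = {"forward": "+", "reverse": "-"}.get(anchor.orientation, "?")
        lines.append(
            f"{chromosome}\t{start}\t{end}\t{part}\tW\t{anchor.scaffold_id}\t1\t{end - start + 1}\t{orient}"
        )
        part += 1
        prev_end = end
    return lines


def read_map(path: str | os.PathLike) -> list[MapEntry]:
    """Read a TSV map written by write_map."""
    entries: list[MapEntry] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise FormatError(f"{path}:{lineno}: map rows need 6 columns, got {len(f)}")
            conf = None if f[3] == "NA" else int(f[3])
            entries.append(
                MapEntry(
                    locus=f[0],
                    external_id="" if f[1] == "-" else f[1],
                    kb=float(f[2]),
                    confidence=conf,
                    cm=float(f[4]),
                    band=f[5],
                )
            )
    return entries
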