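"""Bundled published tables: tammar wallaby chromosome sizes, breakpoints,
arm sizes, linkage-map anchoring offsets, a worked excerpt of the MEU5
integrated/virtual map, and human chromosome sizes for flow-karyotype
calibration.  These are the published inputs the construction operates on;
loaders return the package's own record types."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .records import ArmSpec, BreakpointEntry, ChromosomeSpec, MapEntry


def _read(name: str) -> pd.DataFrame:
    path = resources.files("mapweaver.data") / name
    with resources.as_file(path) as p:
        with open(p) as fh:
            header = None
            for line in fh:
                if line.startswith("#") and "\t" in line:
                    header = line.lstrip("# ").strip().split("\t")
        return pd.read_csv(p, sep="\t", comment="#", names=header, dtype={"name": str},
                           keep_default_na=False)


def tammar_chromosomes() -> list[ChromosomeSpec]:
    df = _read("tammar_chromosomes.tsv")
    return [ChromosomeSpec(str(r.name), float(r.size_mb), float(r.size_cm))
            for r in df.itertuples(index=False, name="Row")]


def tammar_breakpoints() -> dict[str, list[BreakpointEntry]]:
    df = _read("tammar_breakpoints.tsv")
    out: dict[str, list[BreakpointEntry]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.chromosome), []).append(
            BreakpointEntry(id=f"BREAKPOINT{r.id}", kb=float(r.mb) * 1000.0)
        )
    return out


def tammar_arms() -> list[ArmSpec]:
    df = _read("tammar_arms.tsv")
    return [ArmSpec(arm=str(r.arm), size_mb=float(r.size_mb),
                    size_cm_male=float(r.size_cm), size_cm_female=float(r.size_cm),
                    chromosome=str(r.chromosome))
            for r in df.itertuples(index=False)]


def tammar_linkage_offsets() -> dict[str, float]:
    df = _read("tammar_linkage_offsets.tsv")
    return {str(r.chromosome): float(r.offset_cm) for r in df.itertuples(index=False)}


def tammar_map_excerpt() -> list[MapEntry]:
    """Worked rows of the published MEU5 map (kb, cM, confidence, band)."""
    df = _read("tammar_map_excerpt.tsv")
    entries = []
    for r in df.itertuples(index=False):
        conf = None if str(r.confidence) == "NA" else int(r.confidence)
        entries.append(MapEntry(locus=str(r.locus),
                                external_id="" if str(r.external_id) == "-" else str(r.external_id),
                                kb=float(r.kb), cm=float(r.cm), band=str(r.band),
                                confidence=conf))
    return entries


def human_chromosome_sizes() -> dict[str, float]:
    df = _read("human_chromosomes.tsv")
    return {str(r.name): float(r.size_mb) for r in df.itertuples(index=False)}
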