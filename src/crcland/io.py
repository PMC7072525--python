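"""Readers and writers for the tabular and graph formats the pipeline touches.

Variant input comes either as a MAF-like TSV (the minimal column set
documented in :data:`VARIANT_COLUMNS`; this is this package's own exchange
convention, not the full NCI MAF specification) or as a VCF 4.x file whose
INFO field carries the same annotations (see :data:`VCF_INFO_KEYS`).
Clinical metadata is a plain TSV. Networks go to GML or GraphML through
:mod:`networkx`.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .records import ClinicalRecord, VariantRecord

__all__ = [
    "FormatError",
    "VARIANT_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "read_clinical_table",
    "write_clinical_table",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """Malformed input file (missing column, unparsable cell, ...)."""


#: Column order of the MAF-like TSV dialect. The first eight are mandatory.
VARIANT_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "tumor_vaf",
    "variant_depth",
    "tumor_depth",
    "normal_depth",
    "base_quality",
    "population_af",
    "strand_bias_fail",
    "damage_artifact",
)
_MANDATORY_VARIANT_COLUMNS = VARIANT_COLUMNS[:8]

#: INFO keys used by the VCF dialect. Per-allele keys (Number=A) are
#: expanded one record per ALT allele.
VCF_INFO_KEYS = {
    "gene": "GENE",
    "consequence": "CSQCLASS",
    "tumor_vaf": "TVAF",
    "variant_depth": "VD",
    "tumor_depth": "TDP",
    "normal_depth": "NDP",
    "base_quality": "MBQ",
    "population_af": "PAF",
    "strand_bias_fail": "SBF",
    "damage_artifact": "DMG",
}

_MISSING = {"", "NA", "na", "NaN", ".", "None"}


def _parse_float(text: str, column: str, line: int) -> float | None:
    if text in _MISSING:
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"line {line}: cannot parse {column}={text!r} as a number"
        ) from None


def _parse_int(text: str, column: str, line: int) -> int | None:
    if text in _MISSING:
        return None
    try:
        return int(float(text)) if float(text) == int(float(text)) else None
    except ValueError:
        raise FormatError(
            f"line {line}: cannot parse {column}={text!r} as an integer"
        ) from None


def _parse_bool(text: str, default: bool = False) -> bool:
    if text in _MISSING:
        return default
    return text.strip().lower() in {"1", "true", "yes", "t"}


def read_variant_table(path: str | Path, dialect: str = "maf_tsv") -> list[VariantRecord]:
    """Read somatic variant calls into :class:`VariantRecord` objects.

    Parameters
    ----------
    path : path-like
    dialect : {"maf_tsv", "vcf"}
        ``maf_tsv`` expects the tab-separated column set in
        :data:`VARIANT_COLUMNS`; ``vcf`` expects a VCF 4.x file with the
        INFO annotations in :data:`VCF_INFO_KEYS`, one record emitted per
        ALT allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maf_tsv":
        return _read_maf_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_maf_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _MANDATORY_VARIANT_COLUMNS:
            if col not in header:
                raise FormatError(f"missing mandatory column {col!r} in {path}")
        for i, row in enumerate(reader, start=2):
            vaf = _parse_float(row["tumor_vaf"], "tumor_vaf", i)
            if vaf is None:
                raise FormatError(f"line {i}: tumor_vaf is missing")
            pos = _parse_int(row["pos"], "pos", i)
            if pos is None:
                raise FormatError(f"line {i}: pos is missing")
            records.append(
                VariantRecord(
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    chrom=row["chrom"],
                    pos=pos,
                    ref=row["ref"],
                    alt=row["alt"],
                    consequence=row["consequence"],
                    tumor_vaf=vaf,
                    variant_depth=_parse_int(row.get("variant_depth", ""), "variant_depth", i),
                    tumor_depth=_parse_int(row.get("tumor_depth", ""), "tumor_depth", i),
                    normal_depth=_parse_int(row.get("normal_depth", ""), "normal_depth", i),
                    base_quality=_parse_float(row.get("base_quality", ""), "base_quality", i),
                    population_af=_parse_float(row.get("population_af", ""), "population_af", i),
                    strand_bias_fail=_parse_bool(row.get("strand_bias_fail", "")),
                    damage_artifact=_parse_bool(row.get("damage_artifact", "")),
                )
            )
    return records


def _read_vcf(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    records: list[VariantRecord] = []
    for var in vcf:
        info = dict(var.INFO)
        for key in ("GENE", "CSQCLASS", "TVAF"):
            if key not in info:
                raise FormatError(
                    f"missing mandatory INFO key {key!r} at {var.CHROM}:{var.POS}"
                )
        sample_id = info.get("SAMPLE") or (samples[0] if samples else "unknown")

        def per_alt(key: str, j: int):
            val = info.get(key)
            if val is None:
                return None
            if isinstance(val, tuple):
                return val[j]
            if isinstance(val, str) and "," in val:
                return val.split(",")[j]
            return val

        for j, alt in enumerate(var.ALT):
            records.append(
                VariantRecord(
                    sample_id=str(sample_id),
                    gene=str(per_alt("GENE", j)),
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    consequence=str(per_alt("CSQCLASS", j)),
                    tumor_vaf=float(per_alt("TVAF", j)),
                    variant_depth=_opt_int(per_alt("VD", j)),
                    tumor_depth=_opt_int(per_alt("TDP", j)),
                    normal_depth=_opt_int(per_alt("NDP", j)),
                    base_quality=_opt_float(per_alt("MBQ", j)),
                    population_af=_opt_float(per_alt("PAF", j)),
                    strand_bias_fail=bool(info.get("SBF", False)),
                    damage_artifact=bool(info.get("DMG", False)),
                )
            )
    return records


def _opt_int(v) -> int | None:
    return None if v is None else int(v)


def _opt_float(v) -> float | None:
    return None if v is None else float(v)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the MAF-like TSV dialect (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for r in records:
            writer.writerow([_fmt(getattr(r, col)) for col in VARIANT_COLUMNS])


CLINICAL_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "country",
    "treatment",
    "os_months",
    "event",
    "tumor_side",
    "age_years",
    "gender",
    "msi_score",
    "msi_matched",
)
_MANDATORY_CLINICAL_COLUMNS = CLINICAL_COLUMNS[:5]


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical metadata TSV. Unknown country/treatment values and
    negative survival times are rejected; an empty ``tumor_side`` becomes
    an explicit missing value."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ClinicalRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _MANDATORY_CLINICAL_COLUMNS:
            if col not in header:
                raise FormatError(f"missing mandatory column {col!r} in {path}")
        for i, row in enumerate(reader, start=2):
            os_months = _parse_float(row["os_months"], "os_months", i)
            if os_months is None:
                raise FormatError(f"line {i}: os_months is missing")
            side = row.get("tumor_side", "")
            gender = row.get("gender", "")
            try:
                records.append(
                    ClinicalRecord(
                        sample_id=row["sample_id"],
                        country=row["country"],
                        treatment=row["treatment"],
                        os_months=os_months,
                        event=_parse_bool(row["event"]),
                        tumor_side=None if side in _MISSING else side,
                        age_years=_parse_float(row.get("age_years", ""), "age_years", i),
                        gender=None if gender in _MISSING else gender,
                        msi_score=_parse_float(row.get("msi_score", ""), "msi_score", i),
                        msi_matched=_parse_bool(row.get("msi_matched", ""), default=True),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {i}: {exc}") from exc
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLINICAL_COLUMNS)
        for r in records:
            writer.writerow([_fmt(getattr(r, col)) for col in CLINICAL_COLUMNS])


# -- network serialisation ---------------------------------------------------
#
# Node attributes that survive GML/GraphML round-trips: label (str),
# is_median (0/1), vector ("0101..." string), msi_status and other
# annotations as strings; edge attribute: weight (int Hamming distance).


def _sanitize_graph(graph: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        clean = {}
        for k, v in data.items():
            if isinstance(v, bool):
                clean[k] = int(v)
            elif isinstance(v, (tuple, list)):
                if all(isinstance(x, (int, np.integer)) for x in v):
                    clean[k] = "".join(str(int(x)) for x in v)
                else:
                    clean[k] = "|".join(str(x) for x in v)
            elif v is None:
                clean[k] = "NA"
            else:
                clean[k] = v
        out.add_node(str(node), **clean)
    for u, v, data in graph.edges(data=True):
        out.add_edge(str(u), str(v), **{k: (int(w) if isinstance(w, bool) else w) for k, w in data.items()})
    return out


def write_network(graph: nx.Graph, path: str | Path, format: str = "gml") -> None:
    """Serialise a mutation network to GML or GraphML.

    Boolean attributes become 0/1 integers and binary vectors become
    "0101" strings so that attributes are preserved on re-read.
    """
    clean = _sanitize_graph(graph)
    if format == "gml":
        nx.write_gml(clean, str(path))
    elif format == "graphml":
        nx.write_graphml(clean, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "gml") -> nx.Graph:
    if format == "gml":
        return nx.read_gml(str(path))
    if format == "graphml":
        return nx.read_graphml(str(path))
    raise ValueError(f"unknown network format {format!r}")
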