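"""Readers and writers for every table the pipeline touches.

Two interval dialects are supported:

* ``bed``  — BED3+ with 0-based half-open coordinates;
* ``tsv1`` — header-carrying TSV with 1-based inclusive coordinates, the
  convention of the curated candidate tables.

Internally everything is 1-based inclusive; conversion happens here only.
Writers emit a leading ``#`` header line recording dialect and convention so
a file's convention is never ambiguous on disk.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from .types import (
    AssociationRecord,
    FeatureElement,
    FeatureTrack,
    GenomicInterval,
    Locus,
    Variant,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_NA_STRINGS = {"", "NA", "na", "None", "."}


class TableFormatError(ValueError):
    """Malformed input row, carrying file and line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _parse_opt_str(text: str) -> Optional[str]:
    return None if text in _NA_STRINGS else text


def _parse_opt_float(text: str) -> Optional[float]:
    return None if text in _NA_STRINGS else float(text)


def _fmt(value: object) -> str:
    return "NA" if value is None else str(value)


def _data_lines(path: PathLike):
    """Yield (lineno, stripped line) skipping blanks and '#' comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


_TRACK_ATTR_COLS = ("human_specific", "direction", "cell_type", "cortical_trait", "label")


def read_feature_track(
    path: PathLike, dialect: str, track_class: Optional[str] = None, name: Optional[str] = None
) -> FeatureTrack:
    """Read a feature track from ``path`` in the given dialect.

    ``bed``: columns chrom, start, end[, label[, human_specific, direction,
    cell_type, cortical_trait]] with no header. ``tsv1``: a header row naming
    at least chrom, start, end; attribute columns parsed when present and
    defaulted to NA otherwise. ``track_class`` defaults to the file stem.
    """
    if dialect not in ("bed", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    cls = track_class or path.stem
    elements: list[FeatureElement] = []

    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if dialect == "tsv1" and header is None:
            header = fields
            for required in ("chrom", "start", "end"):
                if required not in header:
                    raise TableFormatError(path, lineno, f"missing column {required!r}")
            continue
        try:
            if dialect == "bed":
                if len(fields) < 3:
                    raise ValueError(f"expected >= 3 columns, got {len(fields)}")
                chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                start, end = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
                attrs = dict(zip(_TRACK_ATTR_COLS, ["", "", "", "", ""]))
                if len(fields) > 3:
                    attrs["label"] = fields[3]
                for col, value in zip(_TRACK_ATTR_COLS[:-1], fields[4:]):
                    attrs[col] = value
            else:
                row = dict(zip(header, fields))
                if len(fields) != len(header):
                    raise ValueError(
                        f"expected {len(header)} columns, got {len(fields)}"
                    )
                chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
                attrs = {col: row.get(col, "") for col in _TRACK_ATTR_COLS}
            hs_text = attrs.get("human_specific", "")
            human_specific = (
                True if hs_text in _NA_STRINGS else hs_text.lower() in ("true", "1", "yes")
            )
            elements.append(
                FeatureElement(
                    interval=GenomicInterval(chrom, start, end),
                    track_class=cls,
                    human_specific=human_specific,
                    direction=_parse_opt_str(attrs.get("direction", "")),
                    cell_type=_parse_opt_str(attrs.get("cell_type", "")),
                    cortical_trait=_parse_opt_str(attrs.get("cortical_trait", "")),
                    label=attrs.get("label", "") if attrs.get("label", "") not in _NA_STRINGS else "",
                )
            )
        except (ValueError, KeyError) as exc:
            raise TableFormatError(path, lineno, str(exc)) from exc
    return FeatureTrack(name or cls, elements)


def write_feature_track(track: FeatureTrack, path: PathLike, dialect: str = "tsv1") -> None:
    if dialect not in ("bed", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    convention = "0-based half-open" if dialect == "bed" else "1-based inclusive"
    with open(path, "w") as fh:
        fh.write(f"# rdscan feature track; dialect={dialect}; coordinates {convention}\n")
        if dialect == "tsv1":
            fh.write("chrom\tstart\tend\thuman_specific\tdirection\tcell_type\tcortical_trait\tlabel\n")
        for e in sorted(track.elements, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end)):
            iv = e.interval
            if dialect == "bed":
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start - 1),
                            str(iv.end),
                            e.label or ".",
                            str(e.human_specific),
                            _fmt(e.direction),
                            _fmt(e.cell_type),
                            _fmt(e.cortical_trait),
                        ]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            str(e.human_specific),
                            _fmt(e.direction),
                            _fmt(e.cell_type),
                            _fmt(e.cortical_trait),
                            e.label or "NA",
                        ]
                    )
                    + "\n"
                )


LOCUS_COLUMNS = (
    "id",
    "chrom",
    "start",
    "end",
    "gene",
    "source",
    "replicated_cohorts",
    "cognitive_replicated",
)


def read_loci(path: PathLike) -> list[Locus]:
    """Read a locus table (TSV with header, 1-based inclusive coordinates)."""
    loci: list[Locus] = []
    seen: set[str] = set()
    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        try:
            locus = Locus(
                id=row["id"],
                interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                source=row["source"],
                gene_symbol=_parse_opt_str(row.get("gene", "")),
                replicated_cohorts=int(row.get("replicated_cohorts", 0) or 0),
                cognitive_replicated=row.get("cognitive_replicated", "").lower()
                in ("true", "1", "yes"),
            )
        except (ValueError, KeyError) as exc:
            raise TableFormatError(path, lineno, str(exc)) from exc
        if locus.id in seen:
            raise TableFormatError(path, lineno, f"duplicate locus id {locus.id!r}")
        seen.add(locus.id)
        loci.append(locus)
    return loci


def write_loci(loci: Sequence[Locus], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# rdscan locus table; coordinates 1-based inclusive\n")
        fh.write("\t".join(LOCUS_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                "\t".join(
                    [
                        l.id,
                        l.interval.chrom,
                        str(l.interval.start),
                        str(l.interval.end),
                        _fmt(l.gene_symbol),
                        l.source,
                        str(l.replicated_cohorts),
                        str(l.cognitive_replicated),
                    ]
                )
                + "\n"
            )


VARIANT_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "freq_eur",
    "freq_afr",
    "age_generations",
    "cadd",
)


def read_variants(path: PathLike) -> list[Variant]:
    """Read a variant table. Duplicate rsIDs keep the first occurrence (warned)."""
    variants: list[Variant] = []
    seen: set[str] = set()
    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        try:
            v = Variant(
                rsid=row["rsid"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref_allele=row.get("ref", ""),
                alt_allele=row.get("alt", ""),
                gene_symbol=_parse_opt_str(row.get("gene", "")),
                freq_eur=_parse_opt_float(row.get("freq_eur", "")),
                freq_afr=_parse_opt_float(row.get("freq_afr", "")),
                age_generations=_parse_opt_float(row.get("age_generations", "")),
                cadd_phred=_parse_opt_float(row.get("cadd", "")),
            )
        except (ValueError, KeyError) as exc:
            raise TableFormatError(path, lineno, str(exc)) from exc
        if v.rsid in seen:
            logger.warning("%s:%d: duplicate rsid %s, keeping first", path, lineno, v.rsid)
            continue
        seen.add(v.rsid)
        variants.append(v)
    return variants


def write_variants(variants: Sequence[Variant], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# rdscan variant table; positions 1-based\n")
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.rsid,
                        v.chrom,
                        str(v.pos),
                        v.ref_allele,
                        v.alt_allele,
                        _fmt(v.gene_symbol),
                        _fmt(v.freq_eur),
                        _fmt(v.freq_afr),
                        _fmt(v.age_generations),
                        _fmt(v.cadd_phred),
                    ]
                )
                + "\n"
            )


def read_associations(path: PathLike, study: str = "") -> list[AssociationRecord]:
    """Read a GWAS summary-statistic table (snp, chrom, pos, p[, study, trait])."""
    records: list[AssociationRecord] = []
    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        try:
            records.append(
                AssociationRecord(
                    snp_id=row["snp"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    p_value=float(row["p"]),
                    study=row.get("study", study) or study,
                    trait=row.get("trait", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise TableFormatError(path, lineno, str(exc)) from exc
    return records


def write_associations(records: Sequence[AssociationRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# rdscan association table; positions 1-based\n")
        fh.write("snp\tchrom\tpos\tp\tstudy\ttrait\n")
        for r in records:
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.p_value:g}\t{r.study}\t{r.trait}\n"
            )


def read_gene_list(path: PathLike) -> list[str]:
    """One gene symbol per line; '#' comments and blanks skipped."""
    return [line.strip() for _, line in _data_lines(path)]


def write_gene_list(genes: Sequence[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# rdscan gene list; one symbol per line\n")
        for g in genes:
            fh.write(g + "\n")
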