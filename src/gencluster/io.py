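"""Readers and writers for the standard formats the pipeline touches.

Supported formats: GFF3 (``gene`` features only, 1-based inclusive), BED4/6
(0-based half-open, converted at this boundary), a plain 4/5-column
annotation TSV, tab-separated expression matrices with a sample-to-group
map, one-id-per-line gene lists and a tidy GO map TSV
(``term_id<TAB>term_name<TAB>gene_id``).  All text is UTF-8 and ``#``
starts a comment line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from gffutils.feature import feature_from_line

from .annotation import ExpressionMatrix, GeneList, GeneRecord, GenomeAnnotation
from .exceptions import ValidationError

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_GO_COLUMNS = ["term_id", "term_name", "gene_id"]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: PathLike) -> GenomeAnnotation:
    """Read ``gene`` features from a GFF3 file.

    Non-gene features are ignored.  Every gene feature must carry an
    ``ID`` attribute; coordinates stay 1-based inclusive; strand is
    preserved.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValidationError(f"{path}: malformed GFF3 line {lineno}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            gene_ids = feat.attributes.get("ID", [])
            if not gene_ids:
                raise ValidationError(
                    f"{path}: gene feature on line {lineno} lacks an ID attribute"
                )
            try:
                records.append(
                    GeneRecord(gene_ids[0], feat.seqid, int(feat.start),
                               int(feat.end), feat.strand or ".")
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    ann = GenomeAnnotation(records)
    log.info("read %d genes from %s", len(ann), path)
    return ann


def write_gff3(ann: GenomeAnnotation, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for row in ann.to_frame().itertuples(index=False):
            fh.write(
                f"{row.chrom}\tgencluster\tgene\t{row.start}\t{row.end}"
                f"\t.\t{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> GenomeAnnotation:
    """Read a BED4/6 file into the internal 1-based inclusive convention.

    BED ``start`` maps to internal ``start + 1``; BED ``end`` maps to the
    internal end unchanged.  An empty file yields an empty annotation with
    a logged warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("BED file %s is empty", path)
        return GenomeAnnotation([])
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: BED needs >= 4 columns, found {df.shape[1]}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        chrom, bed_start, bed_end, name = row[0], int(row[1]), int(row[2]), str(row[3])
        if bed_start < 0 or bed_end < 0:
            raise ValidationError(f"{path}: negative coordinate on record {i}")
        strand = str(row[5]) if df.shape[1] >= 6 else "."
        try:
            records.append(GeneRecord(name, str(chrom), bed_start + 1, bed_end, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {i}: {exc}") from exc
    return GenomeAnnotation(records)


def write_bed(ann: GenomeAnnotation, path: PathLike) -> None:
    """Write BED6; internal ``start`` becomes ``start - 1`` (half-open)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in ann.to_frame().itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}"
                f"\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# plain annotation TSV
# ---------------------------------------------------------------------------

def read_annotation_tsv(path: PathLike) -> GenomeAnnotation:
    """Read a headered TSV with columns ``gene_id chrom start end [strand]``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ("gene_id", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: annotation TSV missing columns {missing}")
    return GenomeAnnotation(df)


def write_annotation_tsv(ann: GenomeAnnotation, path: PathLike) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path: PathLike) -> GenomeAnnotation:
    """Dispatch on file suffix: ``.gff3``/``.gff``, ``.bed``, else TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff3", ".gff"):
        return read_gff3(path)
    if suffix == ".bed":
        return read_bed(path)
    return read_annotation_tsv(path)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(matrix_path: PathLike, groups_path: PathLike) -> ExpressionMatrix:
    """Read a log2 expression TSV plus its sample-to-group map.

    The matrix's first column is ``gene_id``; the group map is a headered
    two-column TSV ``sample<TAB>group``.  Duplicate gene rows are averaged
    (replicate probes); a non-numeric cell raises with its coordinates;
    a sample column absent from the group map raises.
    """
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0, dtype=str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    blank = values.isna() & ~bad
    for mask, what in ((bad, "non-numeric"), (blank, "missing")):
        if mask.to_numpy().any():
            rows, cols = mask.to_numpy().nonzero()
            raise ValidationError(
                f"{matrix_path}: {what} value at gene {values.index[rows[0]]!r}, "
                f"sample {values.columns[cols[0]]!r}"
            )
    gmap = pd.read_csv(groups_path, sep="\t", comment="#", dtype=str)
    if not {"sample", "group"}.issubset(gmap.columns):
        raise ValidationError(
            f"{groups_path}: group map needs headered columns 'sample' and 'group'"
        )
    groups = pd.Series(gmap["group"].values, index=gmap["sample"].values)
    extra = [s for s in groups.index if s not in values.columns]
    if extra:
        log.info("group map lists %d samples absent from the matrix", len(extra))
    return ExpressionMatrix(values, groups)


def write_expression(em: ExpressionMatrix, matrix_path: PathLike,
                     groups_path: PathLike) -> None:
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.6f", lineterminator="\n")
    gmap = pd.DataFrame({"sample": em.groups.index, "group": em.groups.values})
    gmap.to_csv(groups_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: PathLike, name: Optional[str] = None,
                   direction: str = "all") -> GeneList:
    """Read a one-id-per-line gene list; blank lines and comments ignored.

    Duplicates are removed with a logged count.  An empty file yields an
    empty list with a warning (downstream ratios will be undefined), not
    an error.
    """
    if name is None:
        name = Path(path).stem
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    if not ids:
        log.warning("gene list %s is empty", path)
    return GeneList(name, direction, tuple(ids))


def write_gene_list(gl: GeneList, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in gl.ids:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# GO map
# ---------------------------------------------------------------------------

def read_go_map(path: PathLike) -> pd.DataFrame:
    """Read a tidy GO map TSV with columns ``term_id term_name gene_id``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _GO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: GO map missing columns {missing}")
    return df[_GO_COLUMNS]


def write_go_map(go_map: pd.DataFrame, path: PathLike) -> None:
    go_map[_GO_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")
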