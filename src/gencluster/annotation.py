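"""Core containers: gene annotations, expression matrices and gene lists.

Coordinates are 1-based and inclusive throughout (the GFF convention).  Conversion to BED's 0-based half-open system happens only at
the file boundary in :mod:`gencluster.io`.  Strand is carried so that
formats round-trip, but every distance computation in the package ignores
it: the clustering criterion is purely positional.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError

log = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")
VALID_DIRECTIONS = ("up", "down", "all")

_ANN_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """A single gene interval, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be a non-empty string")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be one of {VALID_STRANDS}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeAnnotation:
    """Ordered collection of :class:`GeneRecord` with positional indexes.

    The collection preserves input order (so file round trips are
    byte-stable) and additionally maintains a canonical per-chromosome
    index sorted by start coordinate, which the clustering statistics use
    for their sweep algorithms and for uniform sampling of random gene
    lists from the "chip" universe.

    Parameters
    ----------
    records
        Iterable of :class:`GeneRecord`, or a DataFrame with columns
        ``gene_id, chrom, start, end[, strand]``.
    """

    def __init__(self, records: Union[Iterable[GeneRecord], pd.DataFrame]):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
            if "strand" not in df.columns:
                df["strand"] = "."
            missing = [c for c in _ANN_COLUMNS if c not in df.columns]
            if missing:
                raise ValidationError(f"annotation frame missing columns {missing}")
            df = df[_ANN_COLUMNS].reset_index(drop=True)
            df["gene_id"] = df["gene_id"].astype(str)
            df["chrom"] = df["chrom"].astype(str)
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            df["strand"] = df["strand"].astype(str)
            # route every row through GeneRecord validation
            for row in df.itertuples(index=False):
                GeneRecord(*row)
        else:
            rows = list(records)
            for r in rows:
                if not isinstance(r, GeneRecord):
                    raise ValidationError(f"expected GeneRecord, got {type(r)!r}")
            df = pd.DataFrame(
                [dataclasses.asdict(r) for r in rows], columns=_ANN_COLUMNS
            )
            if df.empty:
                df = df.astype(
                    {"gene_id": str, "chrom": str, "start": np.int64,
                     "end": np.int64, "strand": str}
                )
        dup = df["gene_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate gene ids in annotation: {sorted(df.loc[dup, 'gene_id'])[:5]}"
            )
        self._df = df
        self._row_of = {g: i for i, g in enumerate(df["gene_id"])}

        # canonical order: (chrom, start); used by cluster statistics
        order = df.sort_values(["chrom", "start"], kind="mergesort").index.to_numpy()
        self._canon_order = order
        self._canon_starts = df["start"].to_numpy()[order]
        self._canon_ends = df["end"].to_numpy()[order]
        self._canon_ids = df["gene_id"].to_numpy()[order]
        canon_chroms = df["chrom"].to_numpy()[order]
        self._canon_pos = {g: i for i, g in enumerate(self._canon_ids)}
        # contiguous [lo, hi) slices of the canonical arrays per chromosome
        self._chrom_slices: dict[str, tuple[int, int]] = {}
        if len(df):
            bounds = np.flatnonzero(canon_chroms[1:] != canon_chroms[:-1]) + 1
            los = np.concatenate([[0], bounds])
            his = np.concatenate([bounds, [len(df)]])
            for lo, hi in zip(los, his):
                self._chrom_slices[canon_chroms[lo]] = (int(lo), int(hi))
        self._chrom_breaks = np.array(
            sorted(hi for _, hi in self._chrom_slices.values()), dtype=np.int64
        )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row_of

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"GenomeAnnotation({len(self)} genes on "
            f"{len(self._chrom_slices)} chromosomes)"
        )

    # -- accessors ---------------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        """Gene ids in input order."""
        return tuple(self._df["gene_id"])

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._chrom_slices))

    def get(self, gene_id: str) -> GeneRecord:
        try:
            i = self._row_of[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None
        return GeneRecord(*self._df.iloc[i])

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        """Genes on one chromosome, sorted by start coordinate."""
        lo, hi = self._chrom_slices.get(chrom, (0, 0))
        return [
            GeneRecord(self._canon_ids[i], chrom,
                       int(self._canon_starts[i]), int(self._canon_ends[i]))
            for i in range(lo, hi)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying table, input order preserved."""
        return self._df.copy()


class ExpressionMatrix:
    """Log2 expression values (genes x samples) with a sample-to-group map.

    Duplicate gene rows (replicate probes) are collapsed to their
    unweighted per-column mean on construction; the number collapsed is
    logged.  All values must be finite and every sample column must carry
    a group label.
    """

    def __init__(self, values: pd.DataFrame,
                 groups: Union[Mapping[str, str], pd.Series]):
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        bad = ~np.isfinite(values.to_numpy())
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value at gene {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        n_dup = int(values.index.duplicated().sum())
        if n_dup:
            log.info("collapsing %d duplicate gene rows by mean", n_dup)
            values = values.groupby(level=0, sort=False).mean()

        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series)
                           else groups).astype(str)
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        groups = groups.reindex(values.columns)
        if groups.nunique() < 2:
            raise ValidationError("expression matrix must span at least 2 groups")
        self.values = values
        self.groups = groups

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def __repr__(self) -> str:
        return (f"ExpressionMatrix({self.values.shape[0]} genes x "
                f"{self.values.shape[1]} samples, "
                f"groups={sorted(self.groups.unique())})")


@dataclasses.dataclass(frozen=True)
class GeneList:
    """A named, ordered, duplicate-free list of gene ids.

    ``direction`` records provenance: ``up``/``down`` for significance
    lists split by fold-change sign, ``all`` otherwise.  Duplicates in the
    input are removed (first occurrence wins) with a logged count.
    """

    name: str
    direction: str
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {VALID_DIRECTIONS}, got {self.direction!r}"
            )
        seen: dict[str, None] = {}
        for g in self.ids:
            seen.setdefault(str(g))
        deduped = tuple(seen)
        if len(deduped) != len(self.ids):
            log.info("gene list %r: removed %d duplicate ids",
                     self.name, len(self.ids) - len(deduped))
        object.__setattr__(self, "ids", deduped)
        object.__setattr__(self, "_idset", frozenset(deduped))

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._idset  # type: ignore[attr-defined]

    @property
    def idset(self) -> frozenset:
        return self._idset  # type: ignore[attr-defined]
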