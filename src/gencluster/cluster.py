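"""Positional clustering of gene lists and its random-list permutation null.

Two genes are *clustered* when they sit on the same chromosome and either
overlap (or touch) or are separated by at most ``window`` intervening base
pairs (default 10,000).  For a gene list resolved against an annotation,
two observed statistics are defined:

``pairs``
    the number of unordered clustered pairs among the listed genes;
``genes``
    the number of listed genes participating in at least one clustered
    pair.

The null distribution is built by scoring ``n_random`` (default 500)
lists of the same length drawn uniformly without replacement from the
whole annotation universe ("the chip").  The enrichment ratio is
observed / mean(null) and the empirical p-value uses the add-one
estimator ``(1 + #{null >= observed}) / (1 + n_random)``, so the smallest
attainable p is ``1/(n_random+1)``.

Counting uses a per-chromosome sorted sweep (binary search on start
coordinates), which is exactly equivalent to brute-force enumeration of
all pairs; groupings are the connected components of the clustered-pair
relation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Iterable, Sequence
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GeneList, GeneRecord, GenomeAnnotation
from .de import bh_adjust
from .exceptions import ValidationError

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
DEFAULT_N_RANDOM = 500

METRICS = ("pairs", "genes")


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Knobs of the clustering statistic.

    window
        maximum number of intervening base pairs for two genes to count
        as clustered (overlapping or touching genes always count).
    n_random
        number of random same-length gene lists scored for the null.
    metric
        ``pairs`` (clustered-pair count) or ``genes`` (genes in >= 1 pair).
    seed
        seed of the random-list generator; required for reproducibility.
    """

    window: int = DEFAULT_WINDOW
    n_random: int = DEFAULT_N_RANDOM
    metric: str = "pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValidationError("window must be >= 0")
        if self.n_random < 1:
            raise ValidationError("n_random must be >= 1")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")


@dataclasses.dataclass(frozen=True)
class ClusterEnrichmentResult:
    """Observed clustering of one list against its random-list null."""

    list_name: str
    n_genes_used: int
    n_dropped: int
    observed: int
    observed_pairs: int
    observed_genes: int
    null_mean: float
    null_sd: float
    ratio: Optional[float]          # None when null_mean == 0
    p_emp: float
    metric: str
    window: int
    n_random: int
    fdr: Optional[float] = None     # filled by fdr_over_lists


@dataclasses.dataclass(frozen=True)
class ClusterGrouping:
    """Connected components of the clustered-pair graph of one list.

    ``assignments`` maps gene id to a 1-based component index; singleton
    genes are omitted.  Components are numbered by chromosome then by the
    leftmost member's start coordinate.
    """

    list_name: str
    assignments: dict[str, int]
    components: tuple[tuple[str, ...], ...]

    @property
    def n_components(self) -> int:
        return len(self.components)


# ---------------------------------------------------------------------------
# primitive gap
# ---------------------------------------------------------------------------

def gene_gap(g1: GeneRecord, g2: GeneRecord) -> Optional[int]:
    """Intervening base pairs between two genes, or None across chromosomes.

    Overlapping or touching intervals give 0; otherwise the count of
    bases strictly between them, ``later_start - earlier_end - 1``.
    """
    if g1.chrom != g2.chrom:
        return None
    if g1.start <= g2.start:
        earlier_end, later_start = g1.end, g2.start
    else:
        earlier_end, later_start = g2.end, g1.start
    return max(0, later_start - earlier_end - 1)


# ---------------------------------------------------------------------------
# sweep kernels over start-sorted coordinate arrays of a single chromosome
# ---------------------------------------------------------------------------

def _reach(starts: np.ndarray, ends: np.ndarray, window: int) -> np.ndarray:
    """For each gene i, index one past the last j pairing with i (j > i)."""
    thresholds = ends + window + 1
    return np.searchsorted(starts, thresholds, side="right")


def _count_pairs_sorted(starts: np.ndarray, ends: np.ndarray, window: int) -> int:
    n = starts.size
    if n < 2:
        return 0
    reach = _reach(starts, ends, window)
    return int((reach - np.arange(1, n + 1)).sum())


def _clustered_mask_sorted(starts: np.ndarray, ends: np.ndarray,
                           window: int) -> np.ndarray:
    n = starts.size
    if n < 2:
        return np.zeros(n, dtype=bool)
    reach = _reach(starts, ends, window)
    idx = np.arange(n)
    has_partner = reach - 1 > idx
    # gene i pairs with every j in (i, reach_i); mark those ranges
    delta = np.zeros(n + 1, dtype=np.int64)
    src = np.flatnonzero(has_partner)
    np.add.at(delta, src, 1)
    np.add.at(delta, reach[src], -1)
    return np.cumsum(delta[:-1]) > 0


def _count_genes_sorted(starts: np.ndarray, ends: np.ndarray, window: int) -> int:
    return int(_clustered_mask_sorted(starts, ends, window).sum())


def _component_bounds_sorted(starts: np.ndarray, ends: np.ndarray,
                             window: int) -> list[tuple[int, int]]:
    """[lo, hi) ranges of the connected components with >= 2 members.

    A break occurs before gene i when no earlier gene reaches within
    ``window`` of it, i.e. ``start_i - max(end_{<i}) - 1 > window``;
    within a maximal unbroken run every gene is linked (transitively) to
    every other, so runs are exactly the connected components.
    """
    n = starts.size
    if n == 0:
        return []
    cummax_end = np.maximum.accumulate(ends)
    gaps = starts[1:] - cummax_end[:-1] - 1
    breaks = np.flatnonzero(gaps > window) + 1
    bounds = np.concatenate([[0], breaks, [n]])
    return [(int(lo), int(hi)) for lo, hi in zip(bounds[:-1], bounds[1:])
            if hi - lo >= 2]


# ---------------------------------------------------------------------------
# resolution of a list against the annotation's canonical order
# ---------------------------------------------------------------------------

def _resolve_positions(gene_list: GeneList,
                       ann: GenomeAnnotation) -> tuple[np.ndarray, int]:
    """Sorted canonical positions of the list's resolvable ids."""
    pos = [ann._canon_pos[g] for g in gene_list.ids if g in ann]
    n_dropped = len(gene_list.ids) - len(pos)
    if n_dropped:
        log.warning("list %r: dropped %d ids absent from the annotation",
                    gene_list.name, n_dropped)
    positions = np.asarray(sorted(pos), dtype=np.int64)
    return positions, n_dropped


def _split_by_chrom(positions: np.ndarray,
                    ann: GenomeAnnotation) -> Iterable[np.ndarray]:
    """Split sorted canonical positions at chromosome boundaries."""
    cuts = np.searchsorted(positions, ann._chrom_breaks)
    lo = 0
    for hi in cuts:
        if hi > lo:
            yield positions[lo:hi]
        lo = hi


def _score_positions(positions: np.ndarray, ann: GenomeAnnotation,
                     window: int, metric: str) -> int:
    kernel = _count_pairs_sorted if metric == "pairs" else _count_genes_sorted
    total = 0
    for chunk in _split_by_chrom(positions, ann):
        total += kernel(ann._canon_starts[chunk], ann._canon_ends[chunk], window)
    return total


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def count_clustered_pairs(gene_list: GeneList, ann: GenomeAnnotation,
                          params: ClusterParams = ClusterParams()) -> int:
    """Number of unordered clustered pairs among the list's genes."""
    positions, _ = _resolve_positions(gene_list, ann)
    if positions.size == 0:
        log.warning("list %r resolves to no genes; observed count is 0",
                    gene_list.name)
    return _score_positions(positions, ann, params.window, "pairs")


def count_clustered_genes(gene_list: GeneList, ann: GenomeAnnotation,
                          params: ClusterParams = ClusterParams()) -> int:
    """Number of listed genes participating in at least one clustered pair."""
    positions, _ = _resolve_positions(gene_list, ann)
    if positions.size == 0:
        log.warning("list %r resolves to no genes; observed count is 0",
                    gene_list.name)
    return _score_positions(positions, ann, params.window, "genes")


def null_distribution(list_size: int, ann: GenomeAnnotation,
                      params: ClusterParams = ClusterParams()) -> np.ndarray:
    """Clustering scores of ``n_random`` uniform random same-size lists.

    Each draw samples ``list_size`` genes without replacement from the
    full annotation; draws are independent and deterministic under
    ``params.seed``.
    """
    n_universe = len(ann)
    if list_size < 0:
        raise ValidationError("list_size must be >= 0")
    if list_size > n_universe:
        raise ValidationError(
            f"list_size {list_size} exceeds universe size {n_universe}"
        )
    rng = np.random.default_rng(params.seed)
    counts = np.empty(params.n_random, dtype=np.int64)
    for r in range(params.n_random):
        draw = rng.choice(n_universe, size=list_size, replace=False)
        draw.sort()
        counts[r] = _score_positions(draw, ann, params.window, params.metric)
    return counts


def enrichment(gene_list: GeneList, ann: GenomeAnnotation,
               params: ClusterParams = ClusterParams()
               ) -> ClusterEnrichmentResult:
    """Observed clustering, permutation null and enrichment ratio for a list.

    Random lists are matched to the *resolved* list length (ids the
    annotation does not know are dropped first, with a logged count).
    """
    positions, n_dropped = _resolve_positions(gene_list, ann)
    if positions.size == 0:
        log.warning("list %r resolves to no genes", gene_list.name)
    observed_pairs = _score_positions(positions, ann, params.window, "pairs")
    observed_genes = _score_positions(positions, ann, params.window, "genes")
    observed = observed_pairs if params.metric == "pairs" else observed_genes
    null = null_distribution(int(positions.size), ann, params)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    ratio = None if null_mean == 0 else observed / null_mean
    p_emp = (1 + int((null >= observed).sum())) / (1 + params.n_random)
    return ClusterEnrichmentResult(
        list_name=gene_list.name, n_genes_used=int(positions.size),
        n_dropped=n_dropped, observed=observed,
        observed_pairs=observed_pairs, observed_genes=observed_genes,
        null_mean=null_mean, null_sd=null_sd, ratio=ratio, p_emp=p_emp,
        metric=params.metric, window=params.window, n_random=params.n_random,
    )


def fdr_over_lists(results: Sequence[ClusterEnrichmentResult]
                   ) -> list[ClusterEnrichmentResult]:
    """BH adjustment of the empirical p-values across a result collection."""
    if not results:
        raise ValidationError("need at least one enrichment result")
    fdr = bh_adjust([r.p_emp for r in results])
    return [dataclasses.replace(r, fdr=float(q)) for r, q in zip(results, fdr)]


def cluster_groupings(gene_list: GeneList, ann: GenomeAnnotation,
                      params: ClusterParams = ClusterParams()
                      ) -> ClusterGrouping:
    """Connected components (size >= 2) of the list's clustered-pair graph."""
    positions, _ = _resolve_positions(gene_list, ann)
    components: list[tuple[str, ...]] = []
    for chunk in _split_by_chrom(positions, ann):
        starts = ann._canon_starts[chunk]
        ends = ann._canon_ends[chunk]
        for lo, hi in _component_bounds_sorted(starts, ends, params.window):
            components.append(tuple(ann._canon_ids[chunk[lo:hi]]))
    # canonical positions are (chrom, start)-sorted, so components emerge
    # ordered by chromosome then leftmost gene already
    assignments = {g: k for k, comp in enumerate(components, start=1)
                   for g in comp}
    return ClusterGrouping(gene_list.name, assignments, tuple(components))


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def enrichment_table(results: Sequence[ClusterEnrichmentResult]) -> pd.DataFrame:
    """Summary table of enrichment results, one row per gene list."""
    rows = []
    for r in results:
        rows.append({
            "list_name": r.list_name, "n_genes": r.n_genes_used,
            "n_dropped": r.n_dropped, "metric": r.metric,
            "observed": r.observed, "observed_pairs": r.observed_pairs,
            "observed_genes": r.observed_genes,
            "expected": r.null_mean, "null_sd": r.null_sd,
            "ratio": math.nan if r.ratio is None else r.ratio,
            "p_emp": r.p_emp,
            "fdr": math.nan if r.fdr is None else r.fdr,
        })
    return pd.DataFrame(rows)


def grouping_table(grouping: ClusterGrouping,
                   ann: GenomeAnnotation) -> pd.DataFrame:
    """Long-form cluster membership table for one list."""
    rows = []
    for k, comp in enumerate(grouping.components, start=1):
        for g in comp:
            rec = ann.get(g)
            rows.append({"list_name": grouping.list_name, "cluster": k,
                         "gene_id": g, "chrom": rec.chrom,
                         "start": rec.start, "end": rec.end})
    return pd.DataFrame(
        rows, columns=["list_name", "cluster", "gene_id", "chrom", "start", "end"]
    )
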