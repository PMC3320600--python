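"""Synthetic genomes, expression matrices, gene lists and GO maps.

Every generator plants known structure and records it in a
:class:`SimTruth`, so downstream statistics can be scored against ground
truth.  The emulated design is a two-group (wild-type vs mutant) log2
expression study over a multi-chromosome genome of non-overlapping genes:

* gene lengths and intergenic gaps are drawn from truncated normals
  (floored at 100 bp), giving controllable neighbour distances;
* per-gene variances follow a scaled-inverse-chi-square prior
  ``sigma_g^2 = d0 * s0^2 / chi2_{d0}``, the model family whose
  hyperparameters the moderated-t estimator recovers;
* differentially expressed genes get a group-mean shift of
  ``+/- de_effect`` log2 units and may be arranged in runs of consecutive
  genes to form positional clusters;
* one GO term is planted to contain a chosen significant set.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import ExpressionMatrix, GeneList, GenomeAnnotation
from .exceptions import ValidationError

log = logging.getLogger(__name__)

_MIN_BP = 100  # floor for truncated-normal lengths and gaps


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Simulation hyperparameters; defaults define the benchmark conditions.

    The genome defaults (5 chromosome arms x 2,000 genes, ~2 kb genes
    separated by ~6 kb gaps) give a fly-scale gene density of roughly one
    gene per 8 kb, so a 10 kb window links most immediate neighbours but
    few second neighbours.  Expression defaults (3 replicates per group,
    1.0 log2-unit effects, variance prior d0=4, s0=0.25) describe a
    modestly powered two-group microarray comparison.
    """

    n_chrom: int = 5
    genes_per_chrom: int = 2000
    gene_length_mean: float = 2000.0
    gene_length_sd: float = 1000.0
    intergenic_gap_mean: float = 6000.0
    intergenic_gap_sd: float = 4000.0
    n_replicates_per_group: int = 3
    de_effect: float = 1.0
    gene_sd_prior_d0: float = 4.0
    gene_sd_prior_s0: float = 0.25
    n_planted_clusters: int = 40
    cluster_size: int = 5
    n_singleton_de: int = 40
    overlap_fraction: float = 0.5
    go_n_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chrom": self.n_chrom,
            "genes_per_chrom": self.genes_per_chrom,
            "n_replicates_per_group": self.n_replicates_per_group,
            "n_planted_clusters": self.n_planted_clusters,
            "cluster_size": self.cluster_size,
            "n_singleton_de": self.n_singleton_de,
            "go_n_terms": self.go_n_terms,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        for name in ("gene_length_sd", "intergenic_gap_sd", "gene_sd_prior_s0"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.gene_sd_prior_d0 <= 0:
            raise ValidationError("gene_sd_prior_d0 must be > 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValidationError("overlap_fraction must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation fields: {sorted(unknown)}")
        if "seed" not in d:
            raise ValidationError("simulation config requires a seed")
        return cls(**d)


@dataclasses.dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    planted_de_ids: dict[str, tuple[str, ...]] = dataclasses.field(
        default_factory=dict)                       # direction -> ids
    planted_cluster_map: dict[str, int] = dataclasses.field(
        default_factory=dict)                       # gene_id -> cluster index
    planted_overlap_ids: tuple[str, ...] = ()
    planted_go_term: Optional[str] = None

    def to_json(self, path) -> None:
        payload = {
            "planted_de_ids": {k: list(v) for k, v in
                               sorted(self.planted_de_ids.items())},
            "planted_cluster_map": dict(sorted(self.planted_cluster_map.items())),
            "planted_overlap_ids": list(self.planted_overlap_ids),
            "planted_go_term": self.planted_go_term,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _trunc_lengths(rng: np.random.Generator, mean: float, sd: float,
                   n: int) -> np.ndarray:
    draws = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.maximum(draws, _MIN_BP)


def simulate_genome(cfg: SimConfig) -> GenomeAnnotation:
    """Lay non-overlapping genes left-to-right along each chromosome.

    Coordinates are 1-based inclusive; the gap recorded between
    consecutive genes is exactly the count of intervening bases.
    """
    if cfg.n_chrom < 1 or cfg.genes_per_chrom < 1:
        raise ValidationError("need at least one chromosome and one gene")
    rng = np.random.default_rng(cfg.seed)
    frames = []
    gene_no = 0
    for c in range(cfg.n_chrom):
        n = cfg.genes_per_chrom
        lengths = _trunc_lengths(rng, cfg.gene_length_mean,
                                 cfg.gene_length_sd, n)
        gaps = _trunc_lengths(rng, cfg.intergenic_gap_mean,
                              cfg.intergenic_gap_sd, n)
        cum = np.cumsum(gaps + lengths)
        ends = cum
        starts = cum - lengths + 1
        ids = [f"G{gene_no + i:06d}" for i in range(n)]
        gene_no += n
        frames.append(pd.DataFrame({
            "gene_id": ids, "chrom": f"chr{c + 1}",
            "start": starts, "end": ends,
            "strand": rng.choice(np.array(["+", "-"]), size=n),
        }))
    return GenomeAnnotation(pd.concat(frames, ignore_index=True))


def plant_clustered_list(ann: GenomeAnnotation, n_clusters: int,
                         cluster_size: int, n_singletons: int,
                         window: int = 10_000, seed: int = 0,
                         name: str = "planted"
                         ) -> tuple[GeneList, SimTruth]:
    """Select runs of consecutive genes as planted clusters plus singletons.

    Every intra-cluster neighbour gap is <= ``window``; distinct planted
    clusters and singletons are separated by > ``window`` so the clusters
    are exactly the connected components of the list.  Raises when the
    annotation cannot satisfy those spacing constraints.
    """
    if n_clusters > 0 and cluster_size < 2:
        raise ValidationError("cluster_size must be >= 2 when planting clusters")
    rng = np.random.default_rng(seed)

    per_chrom = []
    for chrom in ann.chromosomes:
        lo, hi = ann._chrom_slices[chrom]
        per_chrom.append((chrom, lo, hi))

    # candidate cluster anchors: canonical position p such that genes
    # p..p+cluster_size-1 share a chromosome with all neighbour gaps <= window
    candidates = []
    if n_clusters > 0:
        for chrom, lo, hi in per_chrom:
            starts = ann._canon_starts[lo:hi]
            ends = ann._canon_ends[lo:hi]
            gaps = starts[1:] - ends[:-1] - 1
            ok = gaps <= window
            need = cluster_size - 1
            if ok.size >= need:
                run_ok = np.convolve(ok.astype(int), np.ones(need, dtype=int),
                                     mode="valid") == need
                candidates.extend(lo + int(i) for i in np.flatnonzero(run_ok))
        rng.shuffle(candidates)

    chosen_spans: list[tuple[str, int, int]] = []  # (chrom, span_start, span_end)
    chosen_members: list[np.ndarray] = []
    taken: set[int] = set()

    def far_enough(chrom: str, s: int, e: int) -> bool:
        for c, cs, ce in chosen_spans:
            if c != chrom:
                continue
            gap = max(0, max(cs, s) - min(ce, e) - 1)
            if not (s > ce or e < cs):   # overlapping spans
                return False
            if gap <= window:
                return False
        return True

    bounds = sorted((lo, hi, chrom) for chrom, lo, hi in per_chrom)

    def chrom_at(p: int) -> str:
        for lo, hi, chrom in bounds:
            if lo <= p < hi:
                return chrom
        raise IndexError(p)

    for p in candidates:
        if len(chosen_spans) == n_clusters:
            break
        members = np.arange(p, p + cluster_size)
        if any(int(m) in taken for m in members):
            continue
        chrom = chrom_at(p)
        s = int(ann._canon_starts[p])
        e = int(ann._canon_ends[p + cluster_size - 1])
        if not far_enough(chrom, s, e):
            continue
        chosen_spans.append((chrom, s, e))
        chosen_members.append(members)
        taken.update(int(m) for m in members)
    if len(chosen_spans) < n_clusters:
        raise ValidationError(
            f"could only place {len(chosen_spans)} of {n_clusters} clusters "
            f"of size {cluster_size} with pairwise separation > {window} bp"
        )

    singles: list[int] = []
    if n_singletons > 0:
        order = rng.permutation(len(ann))
        for p in order:
            if len(singles) == n_singletons:
                break
            p = int(p)
            if p in taken:
                continue
            chrom = chrom_at(p)
            s, e = int(ann._canon_starts[p]), int(ann._canon_ends[p])
            if not far_enough(chrom, s, e):
                continue
            chosen_spans.append((chrom, s, e))
            singles.append(p)
            taken.add(p)
        if len(singles) < n_singletons:
            raise ValidationError(
                f"could only place {len(singles)} of {n_singletons} singletons "
                f"with separation > {window} bp"
            )

    truth = SimTruth()
    ids: list[str] = []
    for k, members in enumerate(chosen_members, start=1):
        for m in members:
            gid = str(ann._canon_ids[m])
            ids.append(gid)
            truth.planted_cluster_map[gid] = k
    ids.extend(str(ann._canon_ids[p]) for p in singles)
    return GeneList(name, "all", tuple(ids)), truth


def simulate_expression(ann: GenomeAnnotation, de_ids_up, de_ids_down,
                        cfg: SimConfig
                        ) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-group log2 expression with planted mean shifts.

    Per gene, the true variance is drawn from the scaled-inverse-chi-square
    prior ``d0 * s0^2 / chi2_{d0}``; replicate values are normal around the
    group means; the mutant-minus-wild-type mean difference is
    ``+de_effect`` for up ids, ``-de_effect`` for down ids, 0 otherwise.
    """
    up = tuple(dict.fromkeys(de_ids_up))
    down = tuple(dict.fromkeys(de_ids_down))
    if set(up) & set(down):
        raise ValidationError("up and down DE sets must be disjoint")
    missing = [g for g in (*up, *down) if g not in ann]
    if missing:
        raise ValidationError(f"DE ids absent from annotation: {missing[:5]}")
    if cfg.n_replicates_per_group < 2:
        raise ValidationError(
            "need >= 2 replicates per group (variance undefined otherwise)"
        )
    rng = np.random.default_rng(cfg.seed)
    genes = list(ann.ids)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(8.0, 1.5, size=n)
    d0 = cfg.gene_sd_prior_d0
    sigma_sq = d0 * cfg.gene_sd_prior_s0 ** 2 / rng.chisquare(d0, size=n)
    effect = np.zeros(n)
    effect[[idx[g] for g in up]] = cfg.de_effect
    effect[[idx[g] for g in down]] = -cfg.de_effect

    reps = cfg.n_replicates_per_group
    sd = np.sqrt(sigma_sq)[:, None]
    wt = base[:, None] + rng.normal(0.0, 1.0, size=(n, reps)) * sd
    mut = (base + effect)[:, None] + rng.normal(0.0, 1.0, size=(n, reps)) * sd
    values = pd.DataFrame(
        np.hstack([wt, mut]), index=pd.Index(genes, name="gene_id"),
        columns=[f"wt_{j + 1}" for j in range(reps)]
                + [f"mut_{j + 1}" for j in range(reps)],
    )
    groups = pd.Series({f"wt_{j + 1}": "wt" for j in range(reps)}
                       | {f"mut_{j + 1}": "mut" for j in range(reps)})
    truth = SimTruth(planted_de_ids={"up": up, "down": down})
    return ExpressionMatrix(values, groups), truth


def simulate_go(ann: GenomeAnnotation, sig_ids, go_n_terms: int,
                seed: int = 0, term_size_range: tuple[int, int] = (10, 100),
                planted_extra_frac: float = 0.0
                ) -> tuple[pd.DataFrame, SimTruth]:
    """Random GO map with one planted, genuinely enriched term.

    The planted term (``GO:0000001``) contains every id in ``sig_ids``
    plus ``planted_extra_frac * len(sig_ids)`` random background genes
    (0 by default, i.e. exactly the significant set); the remaining
    ``go_n_terms - 1`` terms are uniform random gene sets with sizes
    drawn from ``term_size_range``.
    """
    if go_n_terms < 1:
        raise ValidationError("go_n_terms must be >= 1")
    sig_ids = tuple(dict.fromkeys(sig_ids))
    outside = [g for g in sig_ids if g not in ann]
    if outside:
        raise ValidationError(f"sig ids absent from annotation: {outside[:5]}")
    rng = np.random.default_rng(seed)
    universe = np.array(ann.ids, dtype=object)
    rows = []
    planted_id = "GO:0000001"
    planted_members = list(sig_ids)
    n_extra = int(round(planted_extra_frac * len(sig_ids)))
    if n_extra:
        background = np.array([g for g in universe if g not in set(sig_ids)],
                              dtype=object)
        planted_members += list(rng.choice(background, size=n_extra,
                                           replace=False))
    for g in planted_members:
        rows.append((planted_id, "planted response", g))
    lo, hi = term_size_range
    for t in range(2, go_n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        members = rng.choice(universe, size=size, replace=False)
        term_id = f"GO:{t:07d}"
        rows.extend((term_id, f"random process {t}", g) for g in members)
    go_map = pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])
    truth = SimTruth(planted_go_term=planted_id)
    return go_map, truth
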