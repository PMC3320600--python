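"""End-to-end orchestration: config, pipeline stages and the benchmark.

The pipeline chains differential expression per comparison, significance
filtering, Venn/overlap analysis of the first two comparisons, positional
cluster enrichment of every significant (and shared) list, cluster
groupings, and GO over-representation.  Every stochastic stage receives a
sub-seed derived deterministically from the single global seed, so a
config reruns byte-identically.  The benchmark wraps the pipeline around
the synthetic generators and scores recovery of the planted structure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster, de, io, overlap, synthetic
from .annotation import GeneList
from .exceptions import PipelineError, ValidationError

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ComparisonSpec:
    """One two-group contrast: a matrix, its group map and the group pair."""

    name: str
    matrix: str
    groups: str
    group_a: str
    group_b: str


@dataclasses.dataclass(frozen=True)
class Thresholds:
    fdr_max: float = de.DEFAULT_FDR_MAX
    lfc_min: float = de.DEFAULT_LFC_MIN
    window: int = cluster.DEFAULT_WINDOW
    n_random: int = cluster.DEFAULT_N_RANDOM
    metric: str = "pairs"
    go_fdr_max: float = overlap.DEFAULT_GO_FDR_MAX


@dataclasses.dataclass(frozen=True)
class GeneListSpec:
    name: str
    path: str
    direction: str = "all"


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    annotation: str
    comparisons: tuple[ComparisonSpec, ...]
    seed: int
    out_dir: str
    go_map: Optional[str] = None
    gene_lists: tuple[GeneListSpec, ...] = ()
    thresholds: Thresholds = Thresholds()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "seed" not in d or d["seed"] is None:
            raise ValidationError("pipeline config requires a seed")
        comps = tuple(ComparisonSpec(**c) for c in d.pop("comparisons", []))
        lists = tuple(GeneListSpec(**g) for g in d.pop("gene_lists", []))
        thr = Thresholds(**d.pop("thresholds", {}))
        try:
            return cls(comparisons=comps, gene_lists=lists, thresholds=thr, **d)
        except TypeError as exc:
            raise ValidationError(f"bad pipeline config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: pipeline config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate_paths(self) -> None:
        paths = [self.annotation]
        for c in self.comparisons:
            paths += [c.matrix, c.groups]
        if self.go_map:
            paths.append(self.go_map)
        paths += [g.path for g in self.gene_lists]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"input paths do not exist: {missing}")
        if not self.comparisons and not self.gene_lists:
            raise ValidationError(
                "config needs at least one comparison or gene list"
            )


@dataclasses.dataclass
class ReportBundle:
    """In-memory handles plus on-disk paths of everything a run produced."""

    out_dir: Path
    de_tables: dict[str, pd.DataFrame]
    gene_lists: dict[str, GeneList]
    comparison: Optional[de.ComparisonResult]
    overlaps: list[overlap.OverlapResult]
    cluster_results: list[cluster.ClusterEnrichmentResult]
    groupings: dict[str, cluster.ClusterGrouping]
    go_tables: dict[str, pd.DataFrame]
    manifest: dict


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = sum(ord(c) * 1000003 ** i for i, c in enumerate(stage))
    ss = np.random.SeedSequence([root_seed, digest % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every stage of the analysis and write the report bundle."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    drop_counts: dict[str, int] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValidationError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    ann = _stage("annotation", io.read_annotation, cfg.annotation)

    # -- differential expression per comparison --------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    lists: dict[str, GeneList] = {}
    for comp in cfg.comparisons:
        em = _stage(f"read:{comp.name}", io.read_expression,
                    comp.matrix, comp.groups)
        det, params = _stage(f"de:{comp.name}", de.fit_moderated_t,
                             em, comp.group_a, comp.group_b)
        de.write_de_table(det, out / f"de_{comp.name}.tsv")
        up, down = de.select_significant(det, thr.fdr_max, thr.lfc_min,
                                         name=comp.name)
        for gl in (up, down):
            lists[gl.name] = gl
            io.write_gene_list(gl, out / f"list_{gl.name}.txt")
        de_tables[comp.name] = det
        log.info("comparison %s: %d up, %d down (d0=%.3g)",
                 comp.name, len(up), len(down), params.d0)

    for spec in cfg.gene_lists:
        gl = _stage(f"list:{spec.name}", io.read_gene_list,
                    spec.path, spec.name, spec.direction)
        lists[gl.name] = gl

    # -- Venn / overlap of the first two comparisons ----------------------
    comparison = None
    overlaps: list[overlap.OverlapResult] = []
    if len(cfg.comparisons) >= 2:
        a, b = cfg.comparisons[0].name, cfg.comparisons[1].name
        comparison = _stage("venn", de.compare_conditions,
                            de_tables[a], de_tables[b],
                            thr.fdr_max, thr.lfc_min, a, b)
        for gl in (comparison.shared_up, comparison.shared_down):
            lists[gl.name] = gl
            io.write_gene_list(gl, out / f"list_{gl.name}.txt")
        for direction in ("up", "down"):
            la = lists[f"{a}_{direction}"]
            lb = lists[f"{b}_{direction}"]
            overlaps.append(_stage("overlap", overlap.overlap_test, la, lb, ann))
        venn = {"up": dict(zip(("a_only", "b_only", "shared"),
                               comparison.venn_up)),
                "down": dict(zip(("a_only", "b_only", "shared"),
                                 comparison.venn_down))}
        with open(out / "venn_counts.json", "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
            fh.write("\n")
        overlap.shared_fraction_report(overlaps).to_csv(
            out / "overlap.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n")

    # -- positional cluster enrichment ------------------------------------
    results = []
    grouping_frames = []
    groupings: dict[str, cluster.ClusterGrouping] = {}
    for name in sorted(lists):
        gl = lists[name]
        params = cluster.ClusterParams(
            window=thr.window, n_random=thr.n_random, metric=thr.metric,
            seed=_stage_seed(cfg.seed, f"cluster:{name}"))
        results.append(_stage(f"cluster:{name}", cluster.enrichment,
                              gl, ann, params))
        grouping = _stage(f"grouping:{name}", cluster.cluster_groupings,
                          gl, ann, params)
        groupings[name] = grouping
        grouping_frames.append(cluster.grouping_table(grouping, ann))
        drop_counts[name] = results[-1].n_dropped
    if results:
        results = cluster.fdr_over_lists(results)
        cluster.enrichment_table(results).to_csv(
            out / "cluster_enrichment.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n")
        pd.concat(grouping_frames, ignore_index=True).to_csv(
            out / "cluster_groupings.tsv", sep="\t", index=False,
            lineterminator="\n")

    # -- GO over-representation -------------------------------------------
    go_tables: dict[str, pd.DataFrame] = {}
    if cfg.go_map:
        go_map = _stage("go:read", io.read_go_map, cfg.go_map)
        frames = []
        for name in sorted(lists):
            gl = lists[name]
            table = _stage(f"go:{name}", overlap.go_enrichment,
                           gl, ann, go_map, thr.go_fdr_max)
            go_tables[name] = table
            if not table.empty:
                frames.append(table.assign(list_name=name))
        if frames:
            combined = pd.concat(frames, ignore_index=True)
            cols = ["list_name"] + overlap.GO_TABLE_COLUMNS
            combined[cols].to_csv(out / "go_enrichment.tsv", sep="\t",
                                  index=False, float_format="%.6g",
                                  lineterminator="\n")

    manifest = {
        "package": {"name": "gencluster", "version": __version__},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_genes_annotation": len(ann),
        "list_sizes": {k: len(v) for k, v in sorted(lists.items())},
        "drop_counts": dict(sorted(drop_counts.items())),
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ReportBundle(out_dir=out, de_tables=de_tables, gene_lists=lists,
                        comparison=comparison, overlaps=overlaps,
                        cluster_results=results, groupings=groupings,
                        go_tables=go_tables, manifest=manifest)


# ---------------------------------------------------------------------------
# synthetic benchmark
# ---------------------------------------------------------------------------

def _derive_cfg(cfg: synthetic.SimConfig, stage: str) -> synthetic.SimConfig:
    return dataclasses.replace(cfg, seed=_stage_seed(cfg.seed, stage))


def run_benchmark(sim_cfg: synthetic.SimConfig, out_dir,
                  thresholds: Thresholds = Thresholds()
                  ) -> tuple[ReportBundle, dict]:
    """Generate a planted dataset, run the pipeline, score the recovery.

    Two mutant-vs-wild-type conditions are simulated over one genome.
    Condition A's upregulated genes are the planted positional clusters
    plus singletons; its downregulated genes are random singletons.
    Condition B reuses ``overlap_fraction`` of a smaller list (about a
    third of A's, so the planted shared fractions echo an asymmetric
    regulator pair) and the planted GO term marks the shared up set.
    Returns the pipeline bundle plus a recovery summary, also written to
    ``recovery.json``.
    """
    out = Path(out_dir)
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    ann = synthetic.simulate_genome(_derive_cfg(sim_cfg, "genome"))
    io.write_gff3(ann, data_dir / "annotation.gff3")

    planted_list, cluster_truth = synthetic.plant_clustered_list(
        ann, sim_cfg.n_planted_clusters, sim_cfg.cluster_size,
        sim_cfg.n_singleton_de, window=thresholds.window,
        seed=_stage_seed(sim_cfg.seed, "plant"), name="planted_up_A")
    up_a = planted_list.ids

    rng = np.random.default_rng(_stage_seed(sim_cfg.seed, "lists"))
    pool = [g for g in ann.ids if g not in planted_list]
    n_down = sim_cfg.n_singleton_de
    down_a = tuple(rng.choice(np.array(pool, dtype=object),
                              size=min(n_down, len(pool)), replace=False))

    # condition B: smaller lists sharing overlap_fraction of their ids with A
    def derive_b(ids_a: tuple[str, ...], exclude: set[str]) -> tuple[str, ...]:
        size_b = max(1, int(round(0.32 * len(ids_a)))) if ids_a else 0
        n_shared = int(round(sim_cfg.overlap_fraction * size_b))
        shared = tuple(rng.choice(np.array(ids_a, dtype=object),
                                  size=min(n_shared, len(ids_a)),
                                  replace=False)) if ids_a else ()
        fresh_pool = [g for g in ann.ids
                      if g not in exclude and g not in set(ids_a)]
        fresh = tuple(rng.choice(np.array(fresh_pool, dtype=object),
                                 size=size_b - len(shared), replace=False))
        return shared + fresh

    up_b = derive_b(up_a, set(down_a))
    down_b = derive_b(down_a, set(up_a) | set(up_b))

    em_a, truth_a = synthetic.simulate_expression(
        ann, up_a, down_a, _derive_cfg(sim_cfg, "expr_A"))
    em_b, truth_b = synthetic.simulate_expression(
        ann, up_b, down_b, _derive_cfg(sim_cfg, "expr_B"))
    io.write_expression(em_a, data_dir / "expr_A.tsv", data_dir / "groups_A.tsv")
    io.write_expression(em_b, data_dir / "expr_B.tsv", data_dir / "groups_B.tsv")

    shared_up = tuple(g for g in up_a if g in set(up_b))
    go_map, go_truth = synthetic.simulate_go(
        ann, shared_up if shared_up else up_a, sim_cfg.go_n_terms,
        seed=_stage_seed(sim_cfg.seed, "go"))
    io.write_go_map(go_map, data_dir / "go_map.tsv")

    truth = synthetic.SimTruth(
        planted_de_ids={"up_A": up_a, "down_A": down_a,
                        "up_B": up_b, "down_B": down_b},
        planted_cluster_map=cluster_truth.planted_cluster_map,
        planted_overlap_ids=shared_up,
        planted_go_term=go_truth.planted_go_term)
    truth.to_json(data_dir / "truth.json")

    cfg = PipelineConfig(
        annotation=str(data_dir / "annotation.gff3"),
        comparisons=(
            ComparisonSpec("A", str(data_dir / "expr_A.tsv"),
                           str(data_dir / "groups_A.tsv"), "wt", "mut"),
            ComparisonSpec("B", str(data_dir / "expr_B.tsv"),
                           str(data_dir / "groups_B.tsv"), "wt", "mut"),
        ),
        seed=_stage_seed(sim_cfg.seed, "pipeline"),
        out_dir=str(out), go_map=str(data_dir / "go_map.tsv"),
        thresholds=thresholds)
    bundle = run_pipeline(cfg)

    summary = score_recovery(bundle, truth, ann, thresholds)
    with open(out / "recovery.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle, summary


def score_recovery(bundle: ReportBundle, truth: synthetic.SimTruth,
                   ann, thresholds: Thresholds) -> dict:
    """Compare pipeline output against planted truth."""
    summary: dict = {}
    n_genes = len(ann)

    for comp, key_up, key_down in (("A", "up_A", "down_A"),
                                   ("B", "up_B", "down_B")):
        planted = set(truth.planted_de_ids.get(key_up, ())) | \
                  set(truth.planted_de_ids.get(key_down, ()))
        called = set(bundle.gene_lists[f"{comp}_up"].ids) | \
                 set(bundle.gene_lists[f"{comp}_down"].ids)
        tp = len(planted & called)
        fp = len(called - planted)
        summary[f"de_{comp}"] = {
            "n_planted": len(planted), "n_called": len(called),
            "sensitivity": tp / len(planted) if planted else None,
            "false_discovery_proportion": fp / len(called) if called else None,
            "specificity": 1.0 - fp / (n_genes - len(planted))
                           if n_genes > len(planted) else None,
        }

    by_name = {r.list_name: r for r in bundle.cluster_results}
    if "A_up" in by_name:
        r = by_name["A_up"]
        summary["cluster_A_up"] = {"ratio": r.ratio, "p_emp": r.p_emp,
                                   "observed": r.observed,
                                   "expected": r.null_mean}
    if "A_up" in bundle.groupings:
        comps = bundle.groupings["A_up"].components
        planted_clusters: dict[int, set] = {}
        for g, k in truth.planted_cluster_map.items():
            planted_clusters.setdefault(k, set()).add(g)
        recovered = sum(
            1 for members in planted_clusters.values()
            if any(members <= set(c) for c in comps))
        summary["groupings_A_up"] = {
            "n_components": len(comps),
            "n_planted_clusters": len(planted_clusters),
            "n_planted_recovered": recovered,
        }

    if bundle.overlaps:
        rep = overlap.shared_fraction_report(bundle.overlaps)
        summary["overlap"] = rep.to_dict(orient="records")

    go = bundle.go_tables.get("A_B_shared_up")
    if go is not None and not go.empty and truth.planted_go_term:
        row = go[go["term_id"] == truth.planted_go_term]
        summary["go"] = {
            "planted_term": truth.planted_go_term,
            "planted_significant": bool(row["significant"].any()),
            "planted_fdr": float(row["fdr"].iloc[0]) if len(row) else None,
            "n_other_significant": int(
                go[go["term_id"] != truth.planted_go_term]["significant"].sum()),
        }
    return summary
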