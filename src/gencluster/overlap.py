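"""Hypergeometric gene-set statistics: list overlap and GO enrichment.

Both analyses model a gene list as a draw without replacement from the
universe of annotated genes ("the chip") and ask whether it captures more
marked genes than chance allows, via the upper tail
:math:`P(X \\ge k)` of the hypergeometric distribution.  GO term
p-values are BH-adjusted across all tested terms and a term is called
significant when its FDR falls strictly below the threshold (default
0.05).  Terms are tested exactly as annotated — no propagation up the
ontology graph.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import pandas as pd
from scipy import stats

from .annotation import GeneList, GenomeAnnotation
from .de import bh_adjust
from .exceptions import ValidationError

log = logging.getLogger(__name__)

DEFAULT_GO_FDR_MAX = 0.05

GO_TABLE_COLUMNS = ["term_id", "term_name", "k_sig_in_term", "n_term",
                    "n_sig", "universe_n", "p", "fdr", "significant"]


def hypergeom_upper_tail(universe_n: int, n_draws: int, n_marked: int,
                         k: int) -> float:
    """P(X >= k) drawing ``n_draws`` without replacement from a universe
    of ``universe_n`` genes of which ``n_marked`` are marked."""
    if not (0 <= n_draws <= universe_n and 0 <= n_marked <= universe_n):
        raise ValidationError(
            f"invalid configuration: N={universe_n}, draws={n_draws}, "
            f"marked={n_marked}"
        )
    if not (0 <= k <= min(n_draws, n_marked)):
        raise ValidationError(
            f"impossible overlap k={k} for draws={n_draws}, marked={n_marked}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_n, n_marked, n_draws))


@dataclasses.dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two gene lists within one universe."""

    name_a: str
    name_b: str
    universe_n: int
    n_a: int
    n_b: int
    k_shared: int
    expected_shared: float
    p_hyper: float
    fold: float                    # NaN when expected_shared == 0
    shared_fraction_a: float       # k / n_a (0 when n_a == 0)
    shared_fraction_b: float


def overlap_test(list_a: GeneList, list_b: GeneList,
                 universe: GenomeAnnotation) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two lists.

    Ids outside the universe are dropped with a warning.  Swapping the
    lists changes only which fraction is labelled a/b.
    """
    n_universe = len(universe)
    if n_universe == 0:
        raise ValidationError("empty universe")
    set_a = {g for g in list_a.ids if g in universe}
    set_b = {g for g in list_b.ids if g in universe}
    for gl, kept in ((list_a, set_a), (list_b, set_b)):
        dropped = len(gl) - len(kept)
        if dropped:
            log.warning("list %r: dropped %d ids outside the universe",
                        gl.name, dropped)
    n_a, n_b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n_a * n_b / n_universe
    p = hypergeom_upper_tail(n_universe, n_a, n_b, k)
    return OverlapResult(
        name_a=list_a.name, name_b=list_b.name, universe_n=n_universe,
        n_a=n_a, n_b=n_b, k_shared=k, expected_shared=expected, p_hyper=p,
        fold=(k / expected if expected > 0 else math.nan),
        shared_fraction_a=(k / n_a if n_a else 0.0),
        shared_fraction_b=(k / n_b if n_b else 0.0),
    )


def go_enrichment(sig: GeneList, universe: GenomeAnnotation,
                  go_map: pd.DataFrame,
                  fdr_max: float = DEFAULT_GO_FDR_MAX) -> pd.DataFrame:
    """One hypergeometric upper-tail test per GO term, BH-corrected.

    ``go_map`` is a tidy frame with columns ``term_id, term_name,
    gene_id``.  Annotations to genes outside the universe are dropped;
    terms left with no genes are skipped.  Returns a table sorted by
    (p, term_id) with a strict ``fdr < fdr_max`` significance call.
    """
    if len(universe) == 0:
        raise ValidationError("empty universe")
    universe_ids = set(universe.ids)
    go = go_map.drop_duplicates(["term_id", "gene_id"])
    n_outside = int((~go["gene_id"].isin(universe_ids)).sum())
    if n_outside:
        log.warning("GO map: dropped %d annotations outside the universe",
                    n_outside)
        go = go[go["gene_id"].isin(universe_ids)]
    sig_in = {g for g in sig.ids if g in universe_ids}
    n_dropped_sig = len(sig) - len(sig_in)
    if n_dropped_sig:
        log.warning("significant list %r: dropped %d ids outside the universe",
                    sig.name, n_dropped_sig)
    if not sig_in:
        log.warning("significant list %r is empty; GO table is empty", sig.name)
        return pd.DataFrame(columns=GO_TABLE_COLUMNS)
    n_sig = len(sig_in)
    n_universe = len(universe_ids)
    rows = []
    for (term_id, term_name), members in go.groupby(
            ["term_id", "term_name"], sort=True)["gene_id"]:
        term_genes = set(members)
        n_term = len(term_genes)
        if n_term == 0:
            continue
        k = len(term_genes & sig_in)
        p = hypergeom_upper_tail(n_universe, n_sig, n_term, k)
        rows.append({"term_id": term_id, "term_name": term_name,
                     "k_sig_in_term": k, "n_term": n_term, "n_sig": n_sig,
                     "universe_n": n_universe, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=GO_TABLE_COLUMNS)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr"] < fdr_max
    table = table.sort_values(["p", "term_id"], kind="mergesort")
    return table.reset_index(drop=True)[GO_TABLE_COLUMNS]


def shared_fraction_report(results) -> pd.DataFrame:
    """Percent shared-target fractions for a collection of overlap results.

    One row per comparison/stage with the shared counts and the shared
    fraction of each list expressed as a percentage, mirroring
    "shared targets as a share of each regulator's target list".
    """
    rows = []
    for r in results:
        rows.append({
            "name_a": r.name_a, "name_b": r.name_b,
            "n_a": r.n_a, "n_b": r.n_b, "k_shared": r.k_shared,
            "pct_of_a": 100.0 * r.shared_fraction_a,
            "pct_of_b": 100.0 * r.shared_fraction_b,
            "p_hyper": r.p_hyper,
        })
    return pd.DataFrame(
        rows, columns=["name_a", "name_b", "n_a", "n_b", "k_shared",
                       "pct_of_a", "pct_of_b", "p_hyper"]
    )
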