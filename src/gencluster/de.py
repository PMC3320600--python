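"""Two-group differential expression with an empirical-Bayes moderated t.

The model is the standard hierarchical one for gene-wise variances: the
sample variance :math:`s_g^2` on :math:`d_g` residual degrees of freedom
is shrunk toward a prior value :math:`s_0^2` carrying :math:`d_0` prior
degrees of freedom,

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},

and the moderated t-statistic ``logFC / sqrt(post_var * (1/n_a + 1/n_b))``
is referred to a t distribution on :math:`d_0 + d_g` degrees of freedom.
The hyperparameters are estimated by moment matching on the log sample
variances (digamma/trigamma matching of the log-F distribution implied by
the scaled-inverse-chi-square prior).  ``d0 = 0`` reduces exactly to the
ordinary pooled two-sample t-test; ``d0 = inf`` pins every variance at
``s0_sq``.

Significance filtering uses strict inequalities: FDR < ``fdr_max`` and
|log2 fold change| > ``lfc_min`` (defaults 0.15 and 0.1).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .annotation import ExpressionMatrix, GeneList
from .exceptions import ValidationError

log = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.15
DEFAULT_LFC_MIN = 0.1

DE_COLUMNS = ["logFC", "s_sq", "t_mod", "p", "fdr"]


@dataclasses.dataclass(frozen=True)
class ModeratedTParams:
    """Fitted variance-prior hyperparameters.

    ``d0`` may be ``math.inf`` when the log-variance moments admit no
    finite solution (observed variances no more dispersed than a single
    shared variance would produce); ``s0_sq`` is NaN when shrinkage was
    disabled with ``d0=0``.
    """

    d0: float
    s0_sq: float
    d_g: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_var_prior(s_sq: np.ndarray, d_g: float) -> tuple[float, float]:
    """Method-of-moments estimate of ``(d0, s0_sq)`` from sample variances.

    Matches the mean and variance of ``log(s_sq)`` to those of a log-F
    distribution with ``(d_g, d0)`` degrees of freedom.  When the excess
    variance of the log variances is non-positive the prior is treated as
    infinitely informative (``d0 = inf``) rather than failing.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.ndim != 1 or s_sq.size < 2:
        raise ValidationError("need a 1-d vector of >= 2 variances")
    if np.any(s_sq <= 0):
        raise ValidationError("variances must be positive (apply the floor first)")
    half_dg = d_g / 2.0
    e = np.log(s_sq) - special.digamma(half_dg) + math.log(half_dg)
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (e.size - 1))
    excess = e_var - float(special.polygamma(1, half_dg))
    if excess > 0:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(e_mean + special.digamma(half_d0) - math.log(half_d0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def fit_moderated_t(matrix: ExpressionMatrix, group_a: str, group_b: str, *,
                    d0: Optional[float] = None, s0_sq: Optional[float] = None,
                    var_floor: float = 1e-8
                    ) -> tuple[pd.DataFrame, ModeratedTParams]:
    """Moderated two-sample t-test of ``group_b`` against ``group_a``.

    Returns a per-gene table (``logFC, s_sq, t_mod, p, fdr``, indexed by
    gene id; logFC = mean(b) - mean(a)) and the fitted prior.  Passing
    ``d0`` explicitly bypasses estimation: ``d0=0`` gives the ordinary
    pooled t-test, any other value also requires ``s0_sq``.

    Genes whose pooled variance falls below ``var_floor`` are floored
    there with a logged warning so the statistic stays defined.
    """
    samples_a = matrix.samples_in(group_a)
    samples_b = matrix.samples_in(group_b)
    for grp, smp in ((group_a, samples_a), (group_b, samples_b)):
        if len(smp) < 2:
            raise ValidationError(
                f"group {grp!r} has {len(smp)} samples; need >= 2"
            )
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    logfc = mean_b - mean_a
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + \
         ((b - mean_b[:, None]) ** 2).sum(axis=1)
    d_g = float(n_a + n_b - 2)
    s_sq = ss / d_g
    n_floored = int((s_sq < var_floor).sum())
    if n_floored:
        log.warning("flooring %d gene variances at %g", n_floored, var_floor)
        s_sq = np.maximum(s_sq, var_floor)

    if d0 is None:
        d0, s0_sq = estimate_var_prior(s_sq, d_g)
        log.info("estimated variance prior: d0=%.4g, s0_sq=%.4g", d0, s0_sq)
    elif d0 < 0:
        raise ValidationError("d0 must be >= 0")
    elif d0 == 0:
        s0_sq = math.nan
    elif s0_sq is None:
        raise ValidationError("an explicit d0 > 0 also requires s0_sq")

    if d0 == 0:
        post_var = s_sq
    elif math.isinf(d0):
        post_var = np.full_like(s_sq, s0_sq)
    else:
        post_var = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
    se = np.sqrt(post_var * (1.0 / n_a + 1.0 / n_b))
    t_mod = logfc / se
    df_total = d_g + d0
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {"logFC": logfc, "s_sq": s_sq, "t_mod": t_mod, "p": p,
         "fdr": bh_adjust(p)},
        index=pd.Index(matrix.genes, name="gene_id"),
    )
    return table, ModeratedTParams(d0=float(d0), s0_sq=float(s0_sq), d_g=d_g)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("p-values must be a 1-d vector")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any():
        raise ValidationError("NaN p-values are not allowed")
    if arr.min() < 0 or arr.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def select_significant(det: pd.DataFrame, fdr_max: float = DEFAULT_FDR_MAX,
                       lfc_min: float = DEFAULT_LFC_MIN, name: str = "de"
                       ) -> tuple[GeneList, GeneList]:
    """Split a DE table into up and down significance lists.

    Strict inequalities on both thresholds: a gene enters the up list iff
    ``fdr < fdr_max`` and ``logFC > +lfc_min``, the down list iff
    ``fdr < fdr_max`` and ``logFC < -lfc_min``.
    """
    if fdr_max <= 0 or lfc_min <= 0:
        raise ValidationError("thresholds must be positive")
    sig = det["fdr"] < fdr_max
    up = det.index[sig & (det["logFC"] > lfc_min)]
    down = det.index[sig & (det["logFC"] < -lfc_min)]
    return (GeneList(f"{name}_up", "up", tuple(up)),
            GeneList(f"{name}_down", "down", tuple(down)))


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Venn-style comparison of two DE tables over one gene universe."""

    up_a: GeneList
    up_b: GeneList
    down_a: GeneList
    down_b: GeneList
    shared_up: GeneList
    shared_down: GeneList
    venn_up: tuple[int, int, int]    # (A-only, B-only, shared)
    venn_down: tuple[int, int, int]


def compare_conditions(det_a: pd.DataFrame, det_b: pd.DataFrame,
                       fdr_max: float = DEFAULT_FDR_MAX,
                       lfc_min: float = DEFAULT_LFC_MIN,
                       name_a: str = "A", name_b: str = "B"
                       ) -> ComparisonResult:
    """Intersect the significant up/down lists of two comparisons.

    Both tables must cover the same gene universe.  Shared lists keep the
    gene order of table A.
    """
    if set(det_a.index) != set(det_b.index):
        raise ValidationError(
            "DE tables cover different gene universes; comparison is undefined"
        )
    up_a, down_a = select_significant(det_a, fdr_max, lfc_min, name=name_a)
    up_b, down_b = select_significant(det_b, fdr_max, lfc_min, name=name_b)
    shared_up = GeneList(f"{name_a}_{name_b}_shared_up", "up",
                         tuple(g for g in up_a.ids if g in up_b))
    shared_down = GeneList(f"{name_a}_{name_b}_shared_down", "down",
                           tuple(g for g in down_a.ids if g in down_b))
    venn_up = (len(up_a) - len(shared_up), len(up_b) - len(shared_up),
               len(shared_up))
    venn_down = (len(down_a) - len(shared_down), len(down_b) - len(shared_down),
                 len(shared_down))
    return ComparisonResult(up_a, up_b, down_a, down_b, shared_up, shared_down,
                            venn_up, venn_down)


def write_de_table(det: pd.DataFrame, path) -> None:
    out = det.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
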