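"""Two-group differential expression with quantile normalization.

The comparison is a Welch unequal-variance t-test on log2(x + pseudocount)
between two replicated groups (e.g. fresh vs postmortem tissue, or high vs
low electrical-activity cortex), with Benjamini-Hochberg FDR across all
tested genes. A gene is tested when it is expressed (value > 0) in at
least one replicate of each group.

Fold change is reported as the A/B ratio of group means (pseudocounted)
and additionally sign-encoded: ``fc = ratio`` when ratio >= 1, else
``-1/ratio``, so ``|fc| >= 1.5`` means at least a 1.5-fold change in
either direction.

Two filter conventions used in postmortem-decay studies are exposed as
presets rather than reconciled: (|FC| >= 1.5, FDR <= 12%) for calling
differential genes, and (p < 0.05, A/B ratio > 2.6) for ranking the most
downregulated genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GroupedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "quantile_normalize",
    "test_two_group",
    "bh_adjust",
    "significant_genes",
    "select_top_downregulated",
    "FILTER_PRESETS",
]

#: named DE filter presets: (min |fc|, max q) or (max p, min A/B ratio)
FILTER_PRESETS = {
    "fc_fdr": {"min_abs_fc": 1.5, "fdr_max": 0.12},
    "ratio_p": {"p_max": 0.05, "min_ratio": 2.6},
}


@dataclass(frozen=True)
class DEResult:
    """Per-gene two-group test result."""

    gene_id: str
    mean_a: float
    mean_b: float
    ratio: float  #: (mean_a + c) / (mean_b + c)
    fc: float  #: sign-encoded fold change (>= 1 up in A, <= -1 up in B)
    log2fc: float
    p: float
    q: float


def quantile_normalize(m: GroupedMatrix) -> GroupedMatrix:
    """Force every sample column onto the common rank-mean distribution.

    The reference distribution is the per-rank mean across sorted columns.
    Tied values within a column all receive the mean of the reference
    values spanned by their ranks. Idempotent; preserves the per-column
    value multiset equality and the per-column sum.
    """
    if m.data.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = m.values
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sv = col[order]
        grp = np.concatenate([[0], np.cumsum(sv[1:] != sv[:-1])])
        sums = np.bincount(grp, weights=ref)
        counts = np.bincount(grp)
        out[order, j] = (sums / counts)[grp]
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return GroupedMatrix(df, group_of=m.group_of, levels=m.levels)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def test_two_group(m: GroupedMatrix, pseudocount: float = 1.0) -> list[DEResult]:
    """Welch t-test of group A vs group B on log2(x + pseudocount).

    Genes expressed in neither group (or only one) are excluded from the
    tested universe and from FDR adjustment. Zero-variance degenerate
    cases are guarded: equal constant groups get p = 1, unequal constant
    groups p = 0.
    """
    lev_a, lev_b = m.levels
    xa = m.group_values(lev_a)
    xb = m.group_values(lev_b)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    tested = (xa > 0).any(axis=1) & (xb > 0).any(axis=1)
    genes = np.asarray(m.gene_ids, dtype=object)[tested]
    la = np.log2(xa[tested] + pseudocount)
    lb = np.log2(xb[tested] + pseudocount)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups trigger a benign precision warning; the
        # resulting nan p-values are guarded explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    diff = la.mean(axis=1) - lb.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(diff) < 1e-12)] = 1.0
    p[degenerate & (np.abs(diff) >= 1e-12)] = 0.0
    q = bh_adjust(p)

    mean_a = xa[tested].mean(axis=1)
    mean_b = xb[tested].mean(axis=1)
    ratio = (mean_a + pseudocount) / (mean_b + pseudocount)
    log2fc = np.log2(ratio)
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    return [
        DEResult(
            gene_id=str(genes[i]),
            mean_a=float(mean_a[i]),
            mean_b=float(mean_b[i]),
            ratio=float(ratio[i]),
            fc=float(fc[i]),
            log2fc=float(log2fc[i]),
            p=float(p[i]),
            q=float(q[i]),
        )
        for i in range(genes.size)
    ]


def significant_genes(res: list[DEResult], min_abs_fc: float = 1.5,
                      fdr_max: float = 0.12) -> list[str]:
    """Genes passing the |FC|/FDR preset, sorted by gene ID."""
    return sorted(r.gene_id for r in res if abs(r.fc) >= min_abs_fc and r.q <= fdr_max)


def select_top_downregulated(res: list[DEResult], n_top: int = 2000,
                             p_max: float = 0.05, min_ratio: float = 2.6) -> list[str]:
    """The most B-downregulated genes, ordered by decreasing A/B ratio.

    Keeps genes with p < p_max and ratio > min_ratio, sorts by decreasing
    ratio (ties broken by gene ID) and truncates to ``n_top``. May return
    fewer than ``n_top`` genes.
    """
    if not res:
        raise ValueError("empty DE result list")
    kept = [r for r in res if r.p < p_max and r.ratio > min_ratio]
    kept.sort(key=lambda r: (-r.ratio, r.gene_id))
    if len(kept) < n_top:
        log.info("select_top_downregulated: only %d of %d requested genes pass filters",
                 len(kept), n_top)
    return [r.gene_id for r in kept[:n_top]]


def de_table(res: list[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame indexed by gene ID."""
    return pd.DataFrame(
        {
            "mean_a": [r.mean_a for r in res],
            "mean_b": [r.mean_b for r in res],
            "ratio": [r.ratio for r in res],
            "fc": [r.fc for r in res],
            "log2fc": [r.log2fc for r in res],
            "p": [r.p for r in res],
            "q": [r.q for r in res],
        },
        index=pd.Index([r.gene_id for r in res], name="gene_id"),
    )
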