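"""Per-gene stability classification across a replicate-free PMI time course.

With a single replicate per time point there is no within-gene variance
estimate, so significance comes from an intensity-dependent variance trend
estimated across genes, in the spirit of local-noise models used for
low-replicate expression data:

1. per gene and time point t > 0, the log-ratio to baseline
   ``d_t = log2((x_t + c) / (x_0 + c))``;
2. genes are ordered by mean log2 intensity and, per time point, a local
   robust scale ``sigma_hat`` is estimated over a sliding window of W
   genes (default 500) via the median absolute deviation, so
   low-expression genes — whose ratios are noisier — are judged against a
   wider null;
3. ``z_t = d_t / sigma_hat`` gives a per-time-point normal two-sided
   p-value; the per-gene p is the Sidak combination of the best time
   point, ``p = 1 - (1 - min_t p_t)**T``;
4. Benjamini-Hochberg FDR across genes.

A gene is called ``not_stable`` when q <= fdr_max and its maximum
|log2 FC| vs time 0 reaches the fold cutoff; ``stable`` when it passes
neither the significance nor the fold bar; anything else (significant but
small, or large but not significant) is ``indeterminate`` — a third class
exists by construction.

The module also computes the enrichment of activity-dependent genes among
not-stable genes: ``E = (A_ns / A_s) / (N_ns / N_s)``, activity counts
normalized by the all-gene background, the ratio-of-ratios summarized per
fold-change cutoff used to define the activity sets.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet, TimeCourseMatrix
from .differential import DEResult, bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "StabilityCall",
    "StabilityEnrichment",
    "classify_stability",
    "activity_genes_at_cutoff",
    "stability_enrichment",
    "enrichment_from_counts",
    "stability_counts",
]

STABLE = "stable"
NOT_STABLE = "not_stable"
INDETERMINATE = "indeterminate"

_MIN_SCALE = 1e-6  # floor on the local noise scale (log2 units)


@dataclass(frozen=True)
class StabilityCall:
    gene_id: str
    max_abs_log2fc: float
    p: float
    q: float
    call: str


@dataclass(frozen=True)
class StabilityEnrichment:
    """Activity-set enrichment among not-stable genes at one |FC| cutoff."""

    fc_cutoff: float
    total_activity: int
    activity_stable: int
    activity_not_stable: int
    background_stable: int
    background_not_stable: int
    E: float


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(values)
        .rolling(window=window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def classify_stability(
    tc: TimeCourseMatrix,
    fc_min: float = 1.3,
    fdr_max: float = 0.01,
    pseudocount: float = 1.0,
    window: int = 500,
) -> list[StabilityCall]:
    """Three-way stable / not-stable / indeterminate call per gene."""
    t = tc.timepoints_h
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    if t[0] != 0.0:
        raise ValueError("time-course must include a t=0 baseline column")
    if fc_min < 1.0:
        raise ValueError("fc_min must be >= 1")
    n = tc.n_genes
    if n < window:
        warnings.warn(
            f"only {n} genes; shrinking variance-trend window from {window} to {n}",
            stacklevel=2,
        )
        window = max(3, n)

    L = np.log2(tc.values + pseudocount)
    d = L[:, 1:] - L[:, [0]]
    n_t = d.shape[1]

    intensity = L.mean(axis=1)
    order = np.argsort(intensity, kind="mergesort")

    z = np.empty_like(d)
    for j in range(n_t):
        ds = d[order, j]
        med = _rolling_median(ds, window)
        scale = 1.4826 * _rolling_median(np.abs(ds - med), window)
        scale = np.maximum(scale, _MIN_SCALE)
        zs = ds / scale
        z[order, j] = zs

    p_t = 2.0 * stats.norm.sf(np.abs(z))
    p_min = p_t.min(axis=1)
    # Sidak combination of the best time point over n_t comparisons
    with np.errstate(divide="ignore"):
        p_gene = -np.expm1(n_t * np.log1p(-np.minimum(p_min, 1.0 - 1e-16)))
    p_gene = np.clip(p_gene, 0.0, 1.0)
    q = bh_adjust(p_gene)

    max_abs = np.abs(d).max(axis=1)
    log2_cut = np.log2(fc_min)

    calls = []
    for i, gene in enumerate(tc.gene_ids):
        significant = q[i] <= fdr_max
        large = max_abs[i] >= log2_cut
        if significant and large:
            call = NOT_STABLE
        elif not significant and not large:
            call = STABLE
        else:
            call = INDETERMINATE
        calls.append(StabilityCall(gene, float(max_abs[i]), float(p_gene[i]), float(q[i]), call))
    return calls


def stability_counts(calls: list[StabilityCall]) -> dict[str, int]:
    out = {STABLE: 0, NOT_STABLE: 0, INDETERMINATE: 0}
    for c in calls:
        out[c.call] += 1
    return out


def activity_genes_at_cutoff(
    de_high_low: list[DEResult], fc_cutoff: float, fdr_max: float = 0.01
) -> GeneSet:
    """Activity-dependent gene set from a high-vs-low DE comparison.

    Genes with sign-encoded |FC| >= cutoff (up or down) at q <= fdr_max.
    Sets are nested: a stricter cutoff always yields a subset.
    """
    members = frozenset(
        r.gene_id for r in de_high_low if abs(r.fc) >= fc_cutoff and r.q <= fdr_max
    )
    return GeneSet(name=f"activity_fc{fc_cutoff:g}", members=members)


def enrichment_from_counts(
    activity_not_stable: int,
    activity_stable: int,
    background_not_stable: int,
    background_stable: int,
    fc_cutoff: float = float("nan"),
    total_activity: int | None = None,
    strict: bool = True,
) -> StabilityEnrichment:
    """E = (A_ns / A_s) / (N_ns / N_s) from explicit counts.

    The background counts are over *all* classified genes (activity genes
    included); indeterminate genes appear in neither ratio. With
    ``strict=False`` an undefined ratio yields E = nan instead of raising.
    """
    undefined = (
        activity_stable == 0 or background_stable == 0 or background_not_stable == 0
    )
    if undefined:
        if strict and activity_stable == 0:
            raise ZeroDivisionError("no stable activity genes: enrichment undefined")
        if strict:
            raise ZeroDivisionError("degenerate background counts: enrichment undefined")
        e = float("nan")
    else:
        e = (activity_not_stable / activity_stable) / (
            background_not_stable / background_stable
        )
    if total_activity is None:
        total_activity = activity_not_stable + activity_stable
    return StabilityEnrichment(
        fc_cutoff=fc_cutoff,
        total_activity=total_activity,
        activity_stable=activity_stable,
        activity_not_stable=activity_not_stable,
        background_stable=background_stable,
        background_not_stable=background_not_stable,
        E=float(e),
    )


def stability_enrichment(
    calls: list[StabilityCall],
    activity: GeneSet,
    fc_cutoff: float = float("nan"),
    strict: bool = True,
) -> StabilityEnrichment:
    """Enrichment of an activity set among not-stable genes."""
    universe = {c.gene_id for c in calls}
    outside = set(activity.members) - universe
    if outside:
        raise ValueError(f"activity genes not covered by stability calls: {sorted(outside)[:5]}")
    counts = stability_counts(calls)
    a_s = sum(1 for c in calls if c.call == STABLE and c.gene_id in activity)
    a_ns = sum(1 for c in calls if c.call == NOT_STABLE and c.gene_id in activity)
    return enrichment_from_counts(
        activity_not_stable=a_ns,
        activity_stable=a_s,
        background_not_stable=counts[NOT_STABLE],
        background_stable=counts[STABLE],
        fc_cutoff=fc_cutoff,
        total_activity=len(activity),
        strict=strict,
    )


def stability_table(calls: list[StabilityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "max_abs_log2fc": [c.max_abs_log2fc for c in calls],
            "p": [c.p for c in calls],
            "q": [c.q for c in calls],
            "call": [c.call for c in calls],
        },
        index=pd.Index([c.gene_id for c in calls], name="gene_id"),
    )
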