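"""Hypergeometric fold-enrichment machinery.

Fold enrichment of an annotated gene set in a selection is the
observed/expected ratio ``E = (k/n) / (K/N)`` with the upper-tail
hypergeometric p-value ``P(X >= k)`` for the overlap under sampling
without replacement. Two composite analyses are provided: ordered-bin
enrichment along a ranked gene list (are the most postmortem-
downregulated genes disproportionately activity-dependent?) and the
housekeeping-gene stability ratio (are classical reference genes
over-represented among PMI-stable genes?).
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .containers import GeneSet
from .stability import NOT_STABLE, STABLE, StabilityCall, stability_counts

__all__ = [
    "EnrichmentResult",
    "HousekeepingStability",
    "hypergeom_enrichment",
    "binned_enrichment",
    "housekeeping_stability_enrichment",
    "housekeeping_ratio_from_counts",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """(k, n, K, N) overlap counts with fold enrichment and tail p-value."""

    k: int  #: annotated genes in the selection
    n: int  #: selection size
    K: int  #: annotated genes in the universe
    N: int  #: universe size
    E: float  #: (k/n) / (K/N)
    p: float  #: P(X >= k), X ~ Hypergeom(N, K, n)


def hypergeom_enrichment(
    selection: GeneSet, annotated: GeneSet, universe: GeneSet
) -> EnrichmentResult:
    """Enrichment of ``annotated`` within ``selection`` against ``universe``."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    if len(selection) == 0:
        raise ValueError("empty selection")
    for name, gs in (("selection", selection), ("annotated", annotated)):
        outside = set(gs.members) - set(universe.members)
        if outside:
            raise ValueError(f"{name} not contained in universe: {sorted(outside)[:5]}")
    n = len(selection)
    big_k = len(annotated)
    big_n = len(universe)
    k = len(selection.intersection(annotated))
    if big_k == 0:
        raise ValueError("annotated set empty within universe: enrichment undefined")
    e = (k / n) / (big_k / big_n)
    # survival function at k-1 gives P(X >= k); scipy evaluates the tail
    # stably in log space internally
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    return EnrichmentResult(k=k, n=n, K=big_k, N=big_n, E=float(e), p=min(max(p, 0.0), 1.0))


def binned_enrichment(
    ranked_genes: list[str],
    annotated: GeneSet,
    universe: GeneSet,
    bin_size: int = 500,
    n_bins: int = 4,
) -> list[EnrichmentResult]:
    """Enrichment in consecutive rank bins of an ordered gene list.

    ``ranked_genes`` is expected in decreasing order of effect (e.g.
    fresh/postmortem expression ratio); bin 0 holds ranks 1..bin_size.
    """
    if bin_size < 1 or n_bins < 1:
        raise ValueError("bin_size and n_bins must be >= 1")
    need = bin_size * n_bins
    if len(ranked_genes) < need:
        raise ValueError(
            f"need at least {need} ranked genes ({n_bins} bins of {bin_size}), "
            f"got {len(ranked_genes)}"
        )
    out = []
    for b in range(n_bins):
        chunk = ranked_genes[b * bin_size : (b + 1) * bin_size]
        sel = GeneSet(name=f"bin{b + 1}", members=frozenset(chunk))
        if len(sel) != bin_size:
            raise ValueError(f"bin {b + 1} contains duplicate gene IDs")
        out.append(hypergeom_enrichment(sel, annotated, universe))
    return out


@dataclass(frozen=True)
class HousekeepingStability:
    """Over-representation of housekeeping genes among stable genes."""

    ratio: float  #: (hk_stable/N_stable) / (hk_not_stable/N_not_stable)
    hk_stable: int
    hk_not_stable: int
    n_stable: int
    n_not_stable: int


def housekeeping_ratio_from_counts(
    hk_stable: int, n_stable: int, hk_not_stable: int, n_not_stable: int
) -> HousekeepingStability:
    """Housekeeping stability ratio from explicit class counts."""
    if n_stable == 0 or n_not_stable == 0:
        raise ZeroDivisionError("degenerate stability background")
    if hk_not_stable == 0:
        ratio = float("inf")
    else:
        ratio = (hk_stable / n_stable) / (hk_not_stable / n_not_stable)
    return HousekeepingStability(
        ratio=ratio,
        hk_stable=hk_stable,
        hk_not_stable=hk_not_stable,
        n_stable=n_stable,
        n_not_stable=n_not_stable,
    )


def housekeeping_stability_enrichment(
    calls: list[StabilityCall], hk: GeneSet
) -> HousekeepingStability:
    """Ratio form of housekeeping enrichment among PMI-stable genes.

    With no unstable housekeeping genes the ratio is reported as +inf
    alongside the raw counts.
    """
    universe = {c.gene_id for c in calls}
    outside = set(hk.members) - universe
    if outside:
        raise ValueError(f"housekeeping genes not classified: {sorted(outside)[:5]}")
    counts = stability_counts(calls)
    hk_s = sum(1 for c in calls if c.call == STABLE and c.gene_id in hk)
    hk_ns = sum(1 for c in calls if c.call == NOT_STABLE and c.gene_id in hk)
    if counts[STABLE] == 0 or counts[NOT_STABLE] == 0:
        raise ZeroDivisionError("degenerate stability background")
    if hk_ns == 0:
        ratio = float("inf")
    else:
        ratio = (hk_s / counts[STABLE]) / (hk_ns / counts[NOT_STABLE])
    return HousekeepingStability(
        ratio=ratio,
        hk_stable=hk_s,
        hk_not_stable=hk_ns,
        n_stable=counts[STABLE],
        n_not_stable=counts[NOT_STABLE],
    )
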