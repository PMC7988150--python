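"""Sample ordination by PCA with group barycenters and confidence ellipses.

Observations are samples (or time points), variables are the genes of a
selected panel on the log2(x + pseudocount) scale, centered and (by
default) standardized to unit variance. The decomposition uses singular
values; component signs follow a fixed convention — the loading of the
alphabetically first panel gene with a non-negligible loading is made
non-negative — so scores are reproducible across linear-algebra backends.

Group barycenters are mean score positions; the confidence ellipse of a
barycenter comes from the eigen-decomposition of S/m (S the 2-D sample
covariance of the group's scores, m the group size) with semi-axes
``sqrt(eigenvalue * chi2_2(level))`` — at the default level 0.80,
chi2_2 = 3.2189.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .containers import GeneSet, GroupedMatrix, TimeCourseMatrix

__all__ = [
    "Ellipse",
    "PCAResult",
    "pca_samples",
    "confidence_ellipse",
]

_SV_TOL = 1e-12


@dataclass(frozen=True)
class Ellipse:
    """Barycenter confidence ellipse in 2-D score space."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  #: major, minor
    rotation_rad: float  #: angle of the major axis vs component 1
    level: float
    degenerate: bool = False  #: singular covariance (line segment / point)


@dataclass(frozen=True)
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  #: samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  #: components x genes
    gene_panel: list[str]
    barycenters: dict[str, tuple[float, ...]]
    ellipses: dict[str, Ellipse]
    group_of: dict[str, str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_samples(
    m: GroupedMatrix | TimeCourseMatrix,
    gene_panel: GeneSet | None = None,
    scale: bool = True,
    pseudocount: float = 1.0,
    level: float = 0.80,
) -> PCAResult:
    """PCA of samples on a gene panel, with per-group barycenters/ellipses.

    Zero-variance genes are dropped (with a warning) when ``scale`` is
    on. Groups come from a :class:`GroupedMatrix`; a time course is
    treated as ungrouped (no barycenters).
    """
    if isinstance(m, TimeCourseMatrix):
        sample_ids = [f"{h:g}h" for h in m.timepoints_h]
        group_of: dict[str, str] = {}
    else:
        sample_ids = m.sample_ids
        group_of = dict(m.group_of)
    if len(sample_ids) < 2:
        raise ValueError("PCA needs >= 2 samples")

    if gene_panel is not None:
        missing = set(gene_panel.members) - set(m.gene_ids)
        if missing:
            raise ValueError(f"panel genes absent from matrix: {sorted(missing)[:5]}")
        genes = sorted(gene_panel.members)
    else:
        genes = list(m.gene_ids)
    x = np.log2(m.data.loc[genes].to_numpy(dtype=float).T + pseudocount)

    sd = x.std(axis=0, ddof=0)
    if scale:
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance gene(s) before scaling",
                stacklevel=2,
            )
            genes = [g for g, k in zip(genes, keep) if k]
            x = x[:, keep]
            sd = sd[keep]
        if x.shape[1] == 0:
            raise ValueError("no genes left after zero-variance filtering")
        x = (x - x.mean(axis=0)) / sd
    else:
        x = x - x.mean(axis=0)

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("matrix has no variance; PCA undefined")
    keep = s > _SV_TOL * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]

    # sign convention: first alphabetical gene with a non-negligible
    # loading gets a non-negative loading on every component
    alpha_order = sorted(range(len(genes)), key=lambda j: genes[j])
    for k in range(s.size):
        for j in alpha_order:
            if abs(vt[k, j]) > 1e-9:
                if vt[k, j] < 0:
                    vt[k] = -vt[k]
                    u[:, k] = -u[:, k]
                break

    scores = u * s
    evr = s**2 / total

    barycenters: dict[str, tuple[float, ...]] = {}
    ellipses: dict[str, Ellipse] = {}
    if group_of:
        levels = sorted(set(group_of.values()))
        for lev in levels:
            rows = [i for i, sid in enumerate(sample_ids) if group_of[sid] == lev]
            pts = scores[rows]
            barycenters[lev] = tuple(float(v) for v in pts.mean(axis=0))
            if len(rows) >= 3 and scores.shape[1] >= 2:
                ellipses[lev] = confidence_ellipse(pts[:, :2], level=level)

    return PCAResult(
        sample_ids=sample_ids,
        scores=scores,
        explained_variance_ratio=evr,
        loadings=vt,
        gene_panel=genes,
        barycenters=barycenters,
        ellipses=ellipses,
        group_of=group_of,
    )


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.80) -> Ellipse:
    """Confidence ellipse of the barycenter of a 2-D point cloud.

    Eigen-decomposition of S/m, S the sample covariance (ddof=1) of the
    m points; semi-axes are ``sqrt(eigenvalue * chi2.ppf(level, df=2))``.
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores_2d must be an (m, 2) array")
    m = pts.shape[0]
    if m < 3:
        raise ValueError("need >= 3 points for a confidence ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    s = np.cov(pts, rowvar=False, ddof=1) / m
    evals, evecs = np.linalg.eigh(s)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    quant = chi2.ppf(level, df=2)
    semi = np.sqrt(evals * quant)
    major = evecs[:, 0]
    rotation = float(np.arctan2(major[1], major[0]))
    degenerate = bool(evals[0] <= 0 or evals[1] <= _SV_TOL * max(evals[0], 1.0))
    return Ellipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        rotation_rad=rotation,
        level=level,
        degenerate=degenerate,
    )
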