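"""Synthetic expression data with the structure of a simulated postmortem interval.

The generator plants four gene classes on a lognormal baseline:

* ``neuronal_decay`` — activity-dependent neuronal genes that decay
  exponentially, ``x(t) = x(0) * exp(-lambda * t)``;
* ``glial_rise`` — glial (astrocyte/microglia) genes that rise with a
  saturating exponential, ``x(t) = x(0) * (1 + a * (1 - exp(-t / tau)))``,
  so profiles are still rising at 24 h;
* ``stable_background`` — flat in expectation;
* ``housekeeping`` — flat in expectation, tracked separately because the
  analysis asks how stable classical reference genes are.

Every value is then multiplied by ``2**eps`` with ``eps ~ Normal(0, sigma)``:
multiplicative log2-normal noise, which preserves positivity of FPKM-like
values and makes fold changes the natural effect scale.

A single :class:`numpy.random.Generator` stream seeded from ``cfg.seed``
drives a run, and the planted truth is drawn before any noise, so
:func:`generate_timecourse` and :func:`generate_grouped` of the same config
share identical gene labels and planted parameters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .containers import GroupedMatrix, TimeCourseMatrix

__all__ = [
    "ConfigError",
    "SynthConfig",
    "GeneTruth",
    "generate_timecourse",
    "generate_grouped",
    "truth_gene_set",
    "activity_truth_at_cutoff",
]

NEURONAL = "neuronal_decay"
GLIAL = "glial_rise"
BACKGROUND = "stable_background"
HOUSEKEEPING = "housekeeping"


class ConfigError(ValueError):
    """An invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults emulate a ~0-24 h room-temperature time course with a
    29 h postmortem comparison group and 4 replicates per group.
    """

    n_genes: int = 5000
    n_neuronal: int = 300
    n_glial: int = 450
    n_housekeeping: int = 64
    #: fraction of the activity-dependent set drawn from the neuronal module
    frac_neuronal_activity: float = 0.71
    timepoints_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    #: lognormal parameters of the per-hour decay rate lambda
    decay_rate_log_mean: float = float(np.log(0.15))
    decay_rate_log_sd: float = 0.2
    #: saturating-rise amplitude a (fold above baseline at t -> inf)
    rise_amplitude_range: tuple[float, float] = (2.5, 5.0)
    #: rise time constant tau in hours
    rise_tau_range: tuple[float, float] = (4.0, 6.0)
    #: sigma of the multiplicative log2-normal noise
    noise_sd_log2: float = 0.15
    #: |FC| range for planted activity genes (high vs low activity)
    activity_fc_range: tuple[float, float] = (1.3, 4.0)
    #: geometric thinning rate of |FC| magnitudes above the lower cutoff
    activity_fc_log_rate: float = 10.0
    pm_interval_h: float = 29.0
    n_replicates_per_group: int = 4
    #: lognormal baseline expression, on the log2 scale
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    #: inject extra noise at the 1 h and 4 h points (RNA-quality dip)
    quality_dip: bool = False
    quality_dip_extra_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_neuronal", "n_glial", "n_housekeeping",
                     "n_replicates_per_group"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_neuronal + self.n_glial + self.n_housekeeping > self.n_genes:
            raise ConfigError(
                "n_genes must be >= n_neuronal + n_glial + n_housekeeping "
                f"({self.n_neuronal}+{self.n_glial}+{self.n_housekeeping} > {self.n_genes})"
            )
        if self.n_replicates_per_group < 1:
            raise ConfigError("n_replicates_per_group must be >= 1")
        t = tuple(float(x) for x in self.timepoints_h)
        if len(t) < 2 or t[0] != 0.0:
            raise ConfigError("timepoints_h must start at 0 and have >= 2 points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ConfigError("timepoints_h must be strictly increasing")
        if not 0.0 <= self.frac_neuronal_activity <= 1.0:
            raise ConfigError("frac_neuronal_activity must be in [0, 1]")
        if self.decay_rate_log_sd < 0:
            raise ConfigError("decay_rate_log_sd must be >= 0")
        for name in ("rise_amplitude_range", "rise_tau_range", "activity_fc_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.activity_fc_range[0] < 1.0:
            raise ConfigError("activity_fc_range lower bound must be >= 1")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if self.activity_fc_log_rate <= 0:
            raise ConfigError("activity_fc_log_rate must be > 0")
        if self.pm_interval_h <= 0:
            raise ConfigError("pm_interval_h must be > 0")
        if self.quality_dip_extra_sd < 0:
            raise ConfigError("quality_dip_extra_sd must be >= 0")


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    planted_class: str
    is_activity_dependent: bool = False
    #: signed high/low activity fold change; positive = higher in high activity
    planted_activity_fc: float | None = None
    planted_lambda: float | None = None
    #: (amplitude, tau) of the saturating rise
    planted_rise: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.planted_class not in (NEURONAL, GLIAL, BACKGROUND, HOUSEKEEPING):
            raise ValueError(f"unknown planted_class {self.planted_class!r}")
        if self.is_activity_dependent != (self.planted_activity_fc is not None):
            raise ValueError("planted_activity_fc must be present iff is_activity_dependent")


@dataclass
class _Plant:
    """Internal arrays describing the planted truth, index-aligned to gene order."""

    gene_ids: list[str]
    classes: np.ndarray  # object array of class names
    x0: np.ndarray
    lam: np.ndarray  # nan where not neuronal
    amp: np.ndarray  # nan where not glial
    tau: np.ndarray
    activity_fc: np.ndarray  # nan where not activity-dependent


def _draw_plant(cfg: SynthConfig, rng: np.random.Generator) -> _Plant:
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(1, n + 1)]
    classes = np.full(n, BACKGROUND, dtype=object)
    perm = rng.permutation(n)
    neuronal_idx = perm[: cfg.n_neuronal]
    glial_idx = perm[cfg.n_neuronal : cfg.n_neuronal + cfg.n_glial]
    hk_idx = perm[cfg.n_neuronal + cfg.n_glial : cfg.n_neuronal + cfg.n_glial + cfg.n_housekeeping]
    classes[neuronal_idx] = NEURONAL
    classes[glial_idx] = GLIAL
    classes[hk_idx] = HOUSEKEEPING

    x0 = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)

    lam = np.full(n, np.nan)
    lam[neuronal_idx] = rng.lognormal(cfg.decay_rate_log_mean, cfg.decay_rate_log_sd,
                                      size=cfg.n_neuronal)
    amp = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    amp[glial_idx] = rng.uniform(*cfg.rise_amplitude_range, size=cfg.n_glial)
    tau[glial_idx] = rng.uniform(*cfg.rise_tau_range, size=cfg.n_glial)

    # Activity-dependent set: all neuronal genes plus a complement split
    # evenly between the glial module (glial activation genes also differ
    # between high- and low-activity cortex) and the stable background
    # (activity-dependent but PMI-insensitive genes exist: the enrichment
    # ratio needs both stable and unstable activity genes).
    frac = cfg.frac_neuronal_activity
    if cfg.n_neuronal > 0 and frac > 0:
        n_activity = int(round(cfg.n_neuronal / frac))
    else:
        n_activity = cfg.n_neuronal
    n_other = max(0, n_activity - cfg.n_neuronal)
    bg_pool = np.setdiff1d(np.arange(n), np.concatenate([neuronal_idx, glial_idx, hk_idx]))
    n_from_glial = min(n_other // 2, glial_idx.size)
    n_from_bg = min(n_other - n_from_glial, bg_pool.size)
    other_idx = np.concatenate([glial_idx[:n_from_glial], bg_pool[:n_from_bg]])
    act_idx = np.concatenate([neuronal_idx, other_idx]).astype(int)

    # |FC| magnitudes thin geometrically above the lower cutoff (truncated
    # exponential on the log scale), emulating activity sets that shrink
    # steeply as the cutoff tightens.
    lo, hi = cfg.activity_fc_range
    span = np.log(hi / lo)
    u = rng.uniform(size=act_idx.size)
    rate = cfg.activity_fc_log_rate
    log_mag = -np.log1p(-u * (1.0 - np.exp(-rate * span))) / rate
    mag = lo * np.exp(log_mag)
    sign = np.ones(act_idx.size)
    # non-neuronal activity genes change in either direction
    n_neu = cfg.n_neuronal
    sign[n_neu:] = rng.choice([-1.0, 1.0], size=act_idx.size - n_neu)
    activity_fc = np.full(n, np.nan)
    activity_fc[act_idx] = sign * mag

    return _Plant(gene_ids, classes, x0, lam, amp, tau, activity_fc)


def _truth_list(plant: _Plant) -> list[GeneTruth]:
    out = []
    for i, gene in enumerate(plant.gene_ids):
        cls = plant.classes[i]
        fc = plant.activity_fc[i]
        out.append(GeneTruth(
            gene_id=gene,
            planted_class=cls,
            is_activity_dependent=bool(np.isfinite(fc)),
            planted_activity_fc=float(fc) if np.isfinite(fc) else None,
            planted_lambda=float(plant.lam[i]) if cls == NEURONAL else None,
            planted_rise=(float(plant.amp[i]), float(plant.tau[i])) if cls == GLIAL else None,
        ))
    return out


def _noiseless_profiles(plant: _Plant, t: np.ndarray) -> np.ndarray:
    """Expected expression (genes x time points) before noise."""
    prof = np.ones((len(plant.gene_ids), t.size))
    neu = plant.classes == NEURONAL
    gli = plant.classes == GLIAL
    prof[neu] = np.exp(-plant.lam[neu, None] * t[None, :])
    prof[gli] = 1.0 + plant.amp[gli, None] * (1.0 - np.exp(-t[None, :] / plant.tau[gli, None]))
    return plant.x0[:, None] * prof


def _apply_noise(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return x.copy()
    return x * 2.0 ** rng.normal(0.0, sigma, size=x.shape)


def generate_timecourse(cfg: SynthConfig) -> tuple[TimeCourseMatrix, list[GeneTruth]]:
    """Simulate the 7-point (default) single-replicate PMI time course."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    plant = _draw_plant(cfg, rng)
    t = np.asarray(cfg.timepoints_h, dtype=float)
    x = _noiseless_profiles(plant, t)
    x = _apply_noise(x, cfg.noise_sd_log2, rng)
    if cfg.quality_dip and cfg.quality_dip_extra_sd > 0:
        dip_cols = np.isin(t, (1.0, 4.0))
        if dip_cols.any():
            x[:, dip_cols] *= 2.0 ** rng.normal(
                0.0, cfg.quality_dip_extra_sd, size=(x.shape[0], int(dip_cols.sum()))
            )
    df = pd.DataFrame(x, index=plant.gene_ids, columns=t)
    return TimeCourseMatrix(df), _truth_list(plant)


def generate_grouped(
    cfg: SynthConfig,
    mode: Literal["fresh_vs_postmortem", "high_vs_low"] = "fresh_vs_postmortem",
) -> tuple[GroupedMatrix, list[GeneTruth]]:
    """Simulate two replicated groups.

    ``fresh_vs_postmortem``
        Fresh replicates sit at the t=0 expectation; postmortem replicates
        at the decay/rise laws evaluated at ``cfg.pm_interval_h``.
    ``high_vs_low``
        Activity-dependent genes differ by their planted signed fold
        change, split symmetrically around baseline; all other genes are
        equal in expectation.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    plant = _draw_plant(cfg, rng)
    nrep = cfg.n_replicates_per_group

    if mode == "fresh_vs_postmortem":
        mean_a = plant.x0.copy()
        mean_b = _noiseless_profiles(plant, np.array([cfg.pm_interval_h]))[:, 0]
        labels = ("fresh", "postmortem")
    elif mode == "high_vs_low":
        ratio = np.ones(cfg.n_genes)
        has = np.isfinite(plant.activity_fc)
        fc = plant.activity_fc[has]
        ratio[has] = np.where(fc > 0, np.abs(fc), 1.0 / np.abs(fc))
        mean_a = plant.x0 * np.sqrt(ratio)
        mean_b = plant.x0 / np.sqrt(ratio)
        labels = ("high", "low")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    base = np.concatenate(
        [np.repeat(mean_a[:, None], nrep, axis=1), np.repeat(mean_b[:, None], nrep, axis=1)],
        axis=1,
    )
    x = _apply_noise(base, cfg.noise_sd_log2, rng)
    samples = [f"{labels[0]}_{i+1}" for i in range(nrep)] + [
        f"{labels[1]}_{i+1}" for i in range(nrep)
    ]
    group_of = {s: labels[0] if i < nrep else labels[1] for i, s in enumerate(samples)}
    df = pd.DataFrame(x, index=plant.gene_ids, columns=samples)
    return GroupedMatrix(df, group_of=group_of, levels=labels), _truth_list(plant)


def truth_gene_set(truth: list[GeneTruth], planted_class: str, name: str | None = None):
    """Gene set of one planted class."""
    from .containers import GeneSet

    members = frozenset(g.gene_id for g in truth if g.planted_class == planted_class)
    return GeneSet(name=name or planted_class, members=members)


def activity_truth_at_cutoff(truth: list[GeneTruth], fc_cutoff: float):
    """Planted activity-dependent genes with |FC| >= cutoff, as a gene set."""
    from .containers import GeneSet

    members = frozenset(
        g.gene_id
        for g in truth
        if g.is_activity_dependent and abs(g.planted_activity_fc) >= fc_cutoff
    )
    return GeneSet(name=f"activity_fc{fc_cutoff:g}", members=members)


def truth_table(truth: list[GeneTruth]) -> pd.DataFrame:
    """Truth as a DataFrame, indexed by gene ID (for TSV export)."""
    rows = []
    for g in truth:
        rows.append({
            "gene_id": g.gene_id,
            "planted_class": g.planted_class,
            "is_activity_dependent": int(g.is_activity_dependent),
            "planted_activity_fc": g.planted_activity_fc if g.planted_activity_fc is not None else "",
            "planted_lambda": g.planted_lambda if g.planted_lambda is not None else "",
            "rise_amplitude": g.planted_rise[0] if g.planted_rise is not None else "",
            "rise_tau": g.planted_rise[1] if g.planted_rise is not None else "",
        })
    return pd.DataFrame(rows).set_index("gene_id")
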