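"""End-to-end orchestration of the simulated-PMI analysis.

``run_full`` chains the stages in the order the analysis tells its story:

1. simulate (or load) the time course, the fresh-vs-postmortem group
   matrix and the high-vs-low-activity gene sets;
2. quantile-normalize and test fresh vs postmortem, rank genes by
   fresh/postmortem ratio, and compute ordered-bin enrichment of
   activity-dependent genes among the most downregulated genes;
3. classify time-course stability and compute the activity-set
   enrichment among not-stable genes at each |FC| cutoff, plus the
   housekeeping stability ratio;
4. build the co-expression graph, extract MCODE kernels and summarize
   their reciprocal rising/falling profiles;
5. ordinate samples and time points by PCA on the most-downregulated
   activity genes.

Every stage draws its randomness (there is none outside simulation) and
its inputs from the one :class:`RunConfig`; a rerun with the same config
and seed is bit-identical. All outputs are plain text: TSV tables,
GraphML for the network, and a single JSON report embedding the config.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .containers import GeneSet, GroupedMatrix, TimeCourseMatrix
from .differential import (
    de_table,
    quantile_normalize,
    select_top_downregulated,
    test_two_group,
)
from .enrichment import binned_enrichment, housekeeping_stability_enrichment
from .io import read_gene_set, read_group_map, read_matrix, write_gene_set, write_graphml, write_matrix
from .network import (
    MCODEParams,
    correlation_graph,
    mcode_find_clusters,
    mcode_vertex_weights,
    summarize_cluster,
)
from .ordination import pca_samples
from .simulate import (
    HOUSEKEEPING,
    SynthConfig,
    activity_truth_at_cutoff,
    generate_grouped,
    generate_timecourse,
    truth_gene_set,
    truth_table,
)
from .stability import classify_stability, stability_counts, stability_enrichment, stability_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class RunConfig:
    """Full-run parameters; every field has a usable default."""

    seed: int = 0
    outdir: str = "pmikit_run"
    simulate: bool = True
    #: used when simulate is False
    timecourse_path: str | None = None
    grouped_path: str | None = None
    group_map_path: str | None = None
    activity_set_paths: tuple[str, ...] = ()
    housekeeping_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    pseudocount: float = 1.0
    #: DE / ranking
    top_n: int = 2000
    select_p_max: float = 0.05
    select_min_ratio: float = 2.6
    bin_size: int = 500
    n_bins: int = 4
    #: stability
    stability_fc_min: float = 1.3
    stability_fdr_max: float = 0.01
    stability_window: int = 500
    activity_cutoffs: tuple[float, ...] = (1.3, 1.4, 1.5)
    #: network
    r_min: float = 0.95
    corr_p_max: float = 0.001
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    #: ordination
    pca_panel_size: int = 500
    pca_level: float = 0.80
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        """Build a config from a plain mapping, rejecting unknown keys."""
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in raw and isinstance(raw["synth"], dict):
            synth_known = {f.name for f in dataclasses.fields(SynthConfig)}
            bad = set(raw["synth"]) - synth_known
            if bad:
                raise ValueError(f"unknown synth config keys: {sorted(bad)}")
            sraw = dict(raw["synth"])
            for key in ("timepoints_h", "rise_amplitude_range", "rise_tau_range",
                        "activity_fc_range"):
                if key in sraw and isinstance(sraw[key], list):
                    sraw[key] = tuple(sraw[key])
            raw["synth"] = SynthConfig(**sraw)
        for key in ("activity_set_paths", "activity_cutoffs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _load_inputs(cfg: RunConfig):
    """Return (timecourse, grouped fresh/pm, activity sets by cutoff, hk set)."""
    if cfg.simulate:
        synth = replace(cfg.synth, seed=cfg.seed)
        tc, truth = generate_timecourse(synth)
        grouped, _ = generate_grouped(synth, mode="fresh_vs_postmortem")
        activity = {c: activity_truth_at_cutoff(truth, c) for c in cfg.activity_cutoffs}
        hk = truth_gene_set(truth, HOUSEKEEPING, name="housekeeping")
        return tc, grouped, activity, hk, truth
    for name in ("timecourse_path", "grouped_path", "group_map_path", "housekeeping_path"):
        if getattr(cfg, name) is None:
            raise ValueError(f"simulate=False requires {name}")
    if len(cfg.activity_set_paths) != len(cfg.activity_cutoffs):
        raise ValueError("need one activity_set_path per activity cutoff")
    tc = read_matrix(cfg.timecourse_path, kind="timecourse")
    grouped = read_matrix(
        cfg.grouped_path, kind="grouped", group_map=read_group_map(cfg.group_map_path)
    )
    activity = {
        c: read_gene_set(p, name=f"activity_fc{c:g}")
        for c, p in zip(cfg.activity_cutoffs, cfg.activity_set_paths)
    }
    hk = read_gene_set(cfg.housekeeping_path, name="housekeeping")
    return tc, grouped, activity, hk, None


@_stage("differential")
def _run_differential(cfg: RunConfig, grouped: GroupedMatrix, activity: dict[float, GeneSet]):
    norm = quantile_normalize(grouped)
    res = test_two_group(norm, pseudocount=cfg.pseudocount)
    selected = select_top_downregulated(
        res, n_top=cfg.top_n, p_max=cfg.select_p_max, min_ratio=cfg.select_min_ratio
    )
    # ranked list for ordered-bin enrichment: the top_n by A/B ratio,
    # unfiltered, so the binning is well defined even when few genes pass
    # the (p, ratio) selection filter
    ranked_all = sorted(res, key=lambda r: (-r.ratio, r.gene_id))
    ranked = [r.gene_id for r in ranked_all[: cfg.top_n]]
    universe = GeneSet("tested", frozenset(r.gene_id for r in res))
    lowest_cut = min(activity)
    annotated = GeneSet(
        activity[lowest_cut].name,
        activity[lowest_cut].members & universe.members,
    )
    bins = None
    if len(ranked) >= cfg.bin_size * cfg.n_bins:
        bins = binned_enrichment(
            ranked, annotated, universe, bin_size=cfg.bin_size, n_bins=cfg.n_bins
        )
    else:
        log.warning("too few ranked genes (%d) for %d bins of %d; skipping binned enrichment",
                    len(ranked), cfg.n_bins, cfg.bin_size)
    return norm, res, selected, ranked, universe, bins


@_stage("stability")
def _run_stability(cfg: RunConfig, tc: TimeCourseMatrix, activity, hk):
    calls = classify_stability(
        tc,
        fc_min=cfg.stability_fc_min,
        fdr_max=cfg.stability_fdr_max,
        pseudocount=cfg.pseudocount,
        window=cfg.stability_window,
    )
    classified = {c.gene_id for c in calls}
    enrich = {}
    for cut in sorted(activity):
        gs = GeneSet(activity[cut].name, activity[cut].members & classified)
        # strict=False: a sparse activity set can lack stable members, in
        # which case the ratio is undefined (reported as null with counts)
        enrich[cut] = stability_enrichment(calls, gs, fc_cutoff=cut, strict=False)
    hk_in = GeneSet(hk.name, hk.members & classified)
    hk_ratio = housekeeping_stability_enrichment(calls, hk_in)
    return calls, enrich, hk_ratio


@_stage("network")
def _run_network(cfg: RunConfig, tc: TimeCourseMatrix, candidates: GeneSet):
    cg = correlation_graph(
        tc,
        candidate_genes=candidates,
        r_min=cfg.r_min,
        p_max=cfg.corr_p_max,
        pseudocount=cfg.pseudocount,
    )
    weights = mcode_vertex_weights(cg)
    params = MCODEParams(vwp=cfg.vwp, haircut=cfg.haircut, fluff=cfg.fluff)
    clusters = mcode_find_clusters(cg, params, weights=weights)
    clusters = [summarize_cluster(tc, c, weights=weights, pseudocount=cfg.pseudocount)
                for c in clusters]
    return cg, weights, clusters


@_stage("ordination")
def _run_ordination(cfg: RunConfig, grouped, tc, ranked: list[str], activity: GeneSet):
    panel_genes = [g for g in ranked if g in activity.members][: cfg.pca_panel_size]
    if len(panel_genes) < 2:
        raise ValueError("PCA panel has fewer than 2 genes")
    panel = GeneSet("pca_panel", frozenset(panel_genes))
    pca_groups = pca_samples(grouped, panel, pseudocount=cfg.pseudocount, level=cfg.pca_level)
    tc_panel = GeneSet("pca_panel_tc", frozenset(g for g in panel_genes if g in tc.data.index))
    pca_time = pca_samples(tc, tc_panel, pseudocount=cfg.pseudocount, level=cfg.pca_level)
    return pca_groups, pca_time, panel


def run_full(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage and write a versioned JSON report to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        tc, grouped, activity, hk, truth = _load_inputs(cfg)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc

    write_matrix(tc, outdir / "timecourse.tsv")
    write_matrix(grouped, outdir / "grouped.tsv")
    for cut, gs in activity.items():
        write_gene_set(gs, outdir / f"activity_fc{cut:g}.txt")
    write_gene_set(hk, outdir / "housekeeping.txt")
    if truth is not None:
        truth_table(truth).to_csv(outdir / "truth.tsv", sep="\t")

    norm, res, selected, ranked, universe, bins = _run_differential(cfg, grouped, activity)
    de_table(res).to_csv(outdir / "de_fresh_vs_postmortem.tsv", sep="\t")

    calls, stab_enrich, hk_ratio = _run_stability(cfg, tc, activity, hk)
    stability_table(calls).to_csv(outdir / "stability_calls.tsv", sep="\t")

    candidates = GeneSet(
        "cluster_candidates",
        activity[min(activity)].members & set(tc.gene_ids),
    )
    cg, weights, clusters = _run_network(cfg, tc, candidates)
    write_graphml(cg.graph, clusters, outdir / "network.graphml", weights=weights)

    pca_groups, pca_time, panel = _run_ordination(
        cfg, grouped, tc, ranked, activity[min(activity)]
    )

    counts = stability_counts(calls)
    n_classified = len(calls)
    report: dict[str, Any] = {
        "pmikit_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_jsonable(),
        "inputs": {
            "n_genes_timecourse": tc.n_genes,
            "timepoints_h": [float(t) for t in tc.timepoints_h],
            "n_samples_grouped": len(grouped.sample_ids),
            "activity_set_sizes": {f"{c:g}": len(gs) for c, gs in activity.items()},
            "n_housekeeping": len(hk),
        },
        "differential": {
            "n_tested": len(res),
            "n_selected_downregulated": len(selected),
            "binned_enrichment": [
                {"bin": i + 1, "k": b.k, "n": b.n, "K": b.K, "N": b.N, "E": b.E, "p": b.p}
                for i, b in enumerate(bins or [])
            ],
        },
        "stability": {
            "counts": counts,
            "fractions": {k: v / n_classified for k, v in counts.items()},
            "activity_enrichment": {
                f"{cut:g}": {
                    "total_activity": e.total_activity,
                    "activity_stable": e.activity_stable,
                    "activity_not_stable": e.activity_not_stable,
                    "background_stable": e.background_stable,
                    "background_not_stable": e.background_not_stable,
                    "E": e.E if np.isfinite(e.E) else None,
                }
                for cut, e in stab_enrich.items()
            },
            "mean_E": (
                float(np.mean([e.E for e in stab_enrich.values() if np.isfinite(e.E)]))
                if any(np.isfinite(e.E) for e in stab_enrich.values())
                else None
            ),
            "housekeeping": {
                # +inf (no unstable housekeeping genes) is not valid JSON;
                # encode as None with the flag set
                "ratio": hk_ratio.ratio if np.isfinite(hk_ratio.ratio) else None,
                "ratio_is_infinite": not np.isfinite(hk_ratio.ratio),
                "hk_stable": hk_ratio.hk_stable,
                "hk_not_stable": hk_ratio.hk_not_stable,
                "n_stable": hk_ratio.n_stable,
                "n_not_stable": hk_ratio.n_not_stable,
            },
        },
        "network": {
            "n_nodes": cg.graph.number_of_nodes(),
            "n_edges": cg.n_edges,
            "clusters": [
                {
                    "size": len(c),
                    "seed_gene": c.seed_gene,
                    "score": c.score,
                    "direction": c.direction,
                    "mean_profile": list(c.mean_profile),
                    "profile_sem": list(c.profile_sem),
                }
                for c in clusters
            ],
        },
        "ordination": {
            "panel_size": len(panel),
            "grouped": {
                "explained_variance_ratio": [float(v) for v in
                                             pca_groups.explained_variance_ratio],
                "barycenters": {k: list(v) for k, v in pca_groups.barycenters.items()},
                "ellipses": {
                    k: {
                        "center": list(e.center),
                        "semi_axes": list(e.semi_axes),
                        "rotation_rad": e.rotation_rad,
                        "level": e.level,
                        "degenerate": e.degenerate,
                    }
                    for k, e in pca_groups.ellipses.items()
                },
            },
            "timecourse": {
                "explained_variance_ratio": [float(v) for v in
                                             pca_time.explained_variance_ratio],
                "component1_order": [
                    pca_time.sample_ids[i]
                    for i in np.argsort(pca_time.scores[:, 0], kind="mergesort")
                ],
            },
        },
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
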