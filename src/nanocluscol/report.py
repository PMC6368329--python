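"""Point-weighted histograms, group statistics, and pipeline orchestration.

Cluster-property distributions are summarized as *point-weighted*
histograms: each cluster contributes its localization count as weight,
so the histogram answers "what fraction of localizations sit in
clusters with this property" rather than "what fraction of clusters".
Group comparisons (Welch's t, one-way ANOVA with Bonferroni or Tukey
post-hoc, two-sample Kolmogorov-Smirnov) are off-the-shelf statistics
included as pipeline plumbing.

``run_pipeline`` ties the stages together from a configuration mapping
and writes a machine-readable run manifest alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import locdata_io, synthpoints
from .cluster_interaction import (DEFAULT_EPS, DEFAULT_HIC_MIN,
                                  DEFAULT_MIN_LOCS, DEFAULT_MIN_PTS,
                                  cluster_channel, roi_summary)
from .doc_score import (DEFAULT_DOC_THRESHOLD, DEFAULT_DR, DEFAULT_R_MAX,
                        compute_doc, percent_colocalized)
from .errors import ConfigError, ValidationError
from .locdata_io import Dialect, filter_by_roi
from .vbms import vbms_pipeline

__all__ = [
    "WeightedHistogram",
    "weighted_histogram",
    "GroupComparison",
    "compare_groups",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Point-weighted histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightedHistogram:
    edges: np.ndarray
    frequencies: np.ndarray     # sums to 1 over in-range weight
    total_weight: float
    overflow_weight: float      # weight of values outside the edges

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.edges[:-1],
            "bin_right": self.edges[1:],
            "frequency": self.frequencies,
        })


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(q, cdf, v))


def _auto_edges(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis on the weighted sample (effective n from weights)."""
    n_eff = weights.sum() ** 2 / (weights ** 2).sum()
    iqr = (_weighted_quantile(values, weights, 0.75)
           - _weighted_quantile(values, weights, 0.25))
    lo, hi = float(values.min()), float(values.max())
    if iqr <= 0 or hi <= lo:
        return np.linspace(lo, hi if hi > lo else lo + 1.0, 11)
    width = 2.0 * iqr / n_eff ** (1.0 / 3.0)
    nbins = max(int(np.ceil((hi - lo) / width)), 1)
    return np.linspace(lo, hi, nbins + 1)


def weighted_histogram(values: Sequence[float], weights: Sequence[float],
                       edges: Sequence[float] | None = None) -> WeightedHistogram:
    """Normalized weighted histogram of a per-cluster property.

    Bin b accumulates the weight of values in [edge_b, edge_{b+1}) with
    the last bin right-closed. Values outside the edges go to an
    overflow tally (logged); frequencies are normalized over the
    in-range weight so they sum to 1.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if len(values) == 0 or len(values) != len(weights):
        raise ValidationError("values and weights must be equal-length and non-empty")
    if np.any(weights <= 0):
        raise ValidationError("weights must be positive")
    if edges is None:
        edges = _auto_edges(values, weights)
    edges = np.asarray(edges, float)
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    total = float(weights.sum())
    in_range = float(hist.sum())
    overflow = total - in_range
    if overflow > 0:
        logger.warning("weighted_histogram: %.3g of %.3g total weight outside "
                       "the bin range", overflow, total)
    if in_range <= 0:
        raise ValidationError("no values fall inside the bin range")
    return WeightedHistogram(edges=edges, frequencies=hist / in_range,
                             total_weight=total, overflow_weight=overflow)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    method: str
    statistic: float                 # omnibus statistic (F, t, D)
    pvalue: float                    # omnibus p-value
    pairwise: pd.DataFrame | None    # columns: group_i, group_j, statistic, pvalue


def compare_groups(samples: Sequence[Sequence[float]],
                   method: str = "welch_t") -> GroupComparison:
    """Compare >= 2 value lists.

    methods: ``welch_t`` (2 groups, unequal variances), ``ks``
    (2 groups, two-sample Kolmogorov-Smirnov), ``anova_bonferroni`` and
    ``anova_tukey`` (one-way ANOVA with the named post-hoc over all
    pairs; Bonferroni multiplies each pairwise p by the number of
    comparisons, capped at 1).
    """
    arrs = [np.asarray(s, float) for s in samples]
    if len(arrs) < 2:
        raise ValidationError("need at least two groups")
    for gi, a in enumerate(arrs):
        if len(a) < 2:
            raise ValidationError(f"group {gi} has fewer than 2 values")

    if method == "welch_t":
        if len(arrs) != 2:
            raise ValidationError("welch_t compares exactly two groups")
        t, p = stats.ttest_ind(arrs[0], arrs[1], equal_var=False)
        if np.isnan(t) and np.allclose(arrs[0].mean(), arrs[1].mean()):
            t, p = 0.0, 1.0          # both groups constant and equal
        return GroupComparison(method, float(t), float(p), None)

    if method == "ks":
        if len(arrs) != 2:
            raise ValidationError("ks compares exactly two groups")
        res = stats.ks_2samp(arrs[0], arrs[1])
        return GroupComparison(method, float(res.statistic),
                               float(res.pvalue), None)

    if method in ("anova_bonferroni", "anova_tukey"):
        f, p = stats.f_oneway(*arrs)
        rows = []
        pairs = list(itertools.combinations(range(len(arrs)), 2))
        if method == "anova_bonferroni":
            for i, j in pairs:
                t_ij, p_ij = stats.ttest_ind(arrs[i], arrs[j], equal_var=True)
                rows.append({"group_i": i, "group_j": j,
                             "statistic": float(t_ij),
                             "pvalue": min(float(p_ij) * len(pairs), 1.0)})
        else:
            res = stats.tukey_hsd(*arrs)
            for i, j in pairs:
                rows.append({"group_i": i, "group_j": j,
                             "statistic": float(res.statistic[i, j]),
                             "pvalue": float(res.pvalue[i, j])})
        return GroupComparison(method, float(f), float(p), pd.DataFrame(rows))

    raise ValidationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    manifest: dict[str, Any]
    outputs: dict[str, Path] = field(default_factory=dict)
    doc: Any = None
    clusters: dict[str, list] = field(default_factory=dict)
    summary: Any = None
    vbms: Any = None


def _validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    cfg = dict(config)
    tracks = cfg.get("tracks", ["clusdoc"])
    if isinstance(tracks, str):
        tracks = [tracks]
    unknown = set(tracks) - {"clusdoc", "vbms"}
    if unknown:
        raise ConfigError(f"unknown track(s): {sorted(unknown)}")
    cfg["tracks"] = tracks
    if "simulate" not in cfg:
        inp = cfg.get("input")
        if not inp or "localizations" not in inp:
            raise ConfigError("config needs input.localizations or a simulate block")
        if not Path(inp["localizations"]).exists():
            raise ConfigError(f"input file not found: {inp['localizations']}")
        if "roi" in inp and not Path(inp["roi"]).exists():
            raise ConfigError(f"ROI file not found: {inp['roi']}")
    doc_cfg = cfg.setdefault("doc", {})
    doc_cfg.setdefault("dr", DEFAULT_DR)
    doc_cfg.setdefault("r_max", DEFAULT_R_MAX)
    doc_cfg.setdefault("threshold", DEFAULT_DOC_THRESHOLD)
    clu = cfg.setdefault("clusters", {})
    clu.setdefault("eps", DEFAULT_EPS)
    clu.setdefault("min_pts", DEFAULT_MIN_PTS)
    clu.setdefault("min_locs", dict(DEFAULT_MIN_LOCS))
    clu.setdefault("hic_min", DEFAULT_HIC_MIN)
    if clu["hic_min"] < 1:
        raise ConfigError("clusters.hic_min must be >= 1")
    if clu["eps"] <= 0 or clu["min_pts"] < 1:
        raise ConfigError("clusters.eps must be > 0 and min_pts >= 1")
    if not 0 < doc_cfg["threshold"] <= 1:
        raise ConfigError("doc.threshold must be in (0, 1]")
    cfg.setdefault("vbms", {})
    return cfg


def _load_or_simulate(cfg: Mapping[str, Any], seed: int):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        kind = sim.pop("kind", "two_channel")
        roi = synthpoints.ring_roi(
            center=sim.pop("center", (0.0, 0.0)),
            r_inner=sim.pop("r_inner", 4000.0),
            r_outer=sim.pop("r_outer", 5000.0),
            n_vertices=sim.pop("n_vertices", 256))
        if kind != "two_channel":
            raise ConfigError(f"unsupported simulate.kind {kind!r}")
        for key in ("n_parents", "mu_molecules", "sigma_cluster", "n_background",
                    "channels"):
            if key in sim:
                sim[key] = tuple(sim[key])
        scene = synthpoints.simulate_two_channel(roi, seed=seed, **sim)
        return scene.table, roi, scene
    inp = cfg["input"]
    dialect = Dialect(**inp.get("dialect", {}))
    table = locdata_io.read_localizations(inp["localizations"], dialect,
                                          channels=inp.get("channels"))
    roi = locdata_io.read_roi(inp["roi"]) if "roi" in inp else None
    return table, roi, None


def run_pipeline(config: Mapping[str, Any], seed: int = 0,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the configured analysis tracks end to end.

    The configuration is validated before any computation; outputs (a
    manifest, cluster tables, score tables and summaries) are written
    under ``out_dir`` when given, deterministically for a fixed
    (config, seed) pair.
    """
    cfg = _validate_config(config)
    table, roi, scene = _load_or_simulate(cfg, seed)
    if roi is not None:
        table_roi = filter_by_roi(table, roi)
    else:
        table_roi = table

    result = PipelineResult(manifest={
        "software": "nanocluscol",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "n_localizations": len(table),
        "n_in_roi": len(table_roi),
    })

    outputs: dict[str, pd.DataFrame | dict] = {}
    if "clusdoc" in cfg["tracks"]:
        doc_cfg = cfg["doc"]
        doc = compute_doc(table_roi, dr=doc_cfg["dr"], r_max=doc_cfg["r_max"],
                          threshold=doc_cfg["threshold"])
        result.doc = doc
        pct = percent_colocalized(doc)
        clu_cfg = cfg["clusters"]
        clusters = {}
        for ch in table_roi.channels:
            clusters[ch] = cluster_channel(
                table_roi, doc, ch, eps=clu_cfg["eps"],
                min_pts=clu_cfg["min_pts"], min_locs=clu_cfg["min_locs"],
                doc_threshold=doc_cfg["threshold"], hic_min=clu_cfg["hic_min"])
        result.clusters = clusters
        all_clusters = [c for cs in clusters.values() for c in cs]
        result.summary = roi_summary(all_clusters, doc)
        outputs["doc_scores.csv"] = pd.concat(
            [df.assign(direction=d) for d, df in doc.per_direction.items()],
            ignore_index=True)
        outputs["percent_colocalized.json"] = pct
        outputs["clusters.csv"] = all_clusters
        outputs["roi_summary.json"] = _jsonable(dataclasses.asdict(result.summary))

    if "vbms" in cfg["tracks"]:
        v_cfg = dict(cfg["vbms"])
        channel = v_cfg.pop("channel", table_roi.channels[-1])
        sub = table_roi.select_channel(channel)
        vres = vbms_pipeline(sub.coords(), point_ids=sub.ids(), **v_cfg)
        result.vbms = vres
        outputs["vbms_clusters.csv"] = pd.DataFrame([
            {"id": k, "n_locs": c.n_locs, "area_nm2": c.area,
             "density_per_nm2": c.density,
             "mode_x": c.mode[0], "mode_y": c.mode[1]}
            for k, c in enumerate(vres.clusters)])
        outputs["vbms_assignment.csv"] = pd.DataFrame({
            "id": sub.ids(), "cluster": vres.assignment})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, obj in outputs.items():
            path = out_dir / name
            if name == "clusters.csv":
                locdata_io.write_cluster_table(obj, path)
            elif isinstance(obj, pd.DataFrame):
                obj.to_csv(path, index=False, float_format="%.10g")
            else:
                path.write_text(json.dumps(_jsonable(obj), indent=2,
                                           sort_keys=True) + "\n")
            result.outputs[name] = path
        if scene is not None:
            locdata_io.write_localizations(scene.table,
                                           out_dir / "localizations.txt")
            scene.truth.to_csv(out_dir / "ground_truth.csv", index=False,
                               float_format="%.10g")
            result.outputs["localizations.txt"] = out_dir / "localizations.txt"
            result.outputs["ground_truth.csv"] = out_dir / "ground_truth.csv"
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(result.manifest, indent=2,
                                            sort_keys=True) + "\n")
        result.outputs["manifest.json"] = manifest_path
    return result


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
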