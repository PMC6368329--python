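"""DBSCAN cluster detection and NIC/LIC/HIC interaction classification.

Clusters are single-channel objects found by DBSCAN and retained only
above a channel-specific size threshold (defaults: >= 5 localizations
for 5-LO, >= 10 for FLAP — the higher FLAP bar reflects its homotrimeric
stoichiometry, three localizations per functional unit at minimum).
Each retained cluster is classified by how many of its own ("founding")
members carry a DoC score >= 0.4:

    NIC — no interacting members,
    LIC — 1 to 4 interacting members,
    HIC — 5 or more interacting members.

Cluster geometry is the convex hull of the members (shoelace area);
density is members per hull area, and relative density compares the
mean local density within 20 nm of each member against the cluster
average, a measure of internal concentration hotspots.

DBSCAN is implemented here with an explicit, order-independent border
rule: core points (>= min_pts neighbours within eps, counting
themselves) are grouped into connected components, and a border point
joins the cluster of its lowest-id core neighbour. Labels are therefore
deterministic and reproducible across point orderings.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .doc_score import DEFAULT_DOC_THRESHOLD, DoCResult
from .errors import ConfigError, ValidationError
from .locdata_io import LocalizationTable, RoiPolygon

__all__ = [
    "ClusterRecord",
    "RoiSummary",
    "dbscan",
    "make_clusters",
    "classify_interaction",
    "classify_clusters",
    "cluster_area",
    "relative_density",
    "roi_summary",
    "aggregate_summaries",
    "estimate_trimers",
    "cluster_channel",
    "NOISE",
    "CLASSES",
    "DEFAULT_EPS",
    "DEFAULT_MIN_PTS",
    "DEFAULT_MIN_LOCS",
    "DEFAULT_HIC_MIN",
    "DEFAULT_R_LOCAL",
]

NOISE = -1
CLASSES = ("NIC", "LIC", "HIC")

DEFAULT_EPS = 20.0        # nm, DBSCAN neighbourhood radius
DEFAULT_MIN_PTS = 3       # DBSCAN core threshold (neighbours incl. self)
DEFAULT_MIN_LOCS = {"5-LO": 5, "FLAP": 10}   # per-channel cluster size floor
DEFAULT_HIC_MIN = 5       # interacting members needed for HIC
DEFAULT_R_LOCAL = 20.0    # nm, local-density radius


@dataclass(frozen=True)
class ClusterRecord:
    """One detected cluster and its morphometrics."""

    cluster_id: int
    channel: str
    member_ids: np.ndarray          # localization ids
    contour: np.ndarray | None      # CCW hull vertices, None if degenerate
    area: float                     # nm^2 (0 for degenerate/collinear)
    n_locs: int
    density: float                  # locs / nm^2 (nan if degenerate)
    relative_density: float         # dimensionless (nan if degenerate)
    n_interacting: int = -1         # -1 until classified
    interaction_class: str = ""     # "" until classified

    @property
    def degenerate(self) -> bool:
        return self.area <= 0.0


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Label points with cluster ids (0, 1, ...) or -1 for noise.

    Core point: >= min_pts neighbours within eps, itself included.
    Clusters are the connected components of core points; each border
    point is assigned to the cluster of its lowest-id core neighbour.
    """
    if eps <= 0:
        raise ValidationError("eps must be > 0")
    if min_pts < 1:
        raise ValidationError("min_pts must be >= 1")
    points = np.asarray(points, float)
    n = len(points)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighbours = tree.query_ball_point(points, eps)
    core = np.array([len(nb) >= min_pts for nb in neighbours])

    nxt = 0
    for start in range(n):
        if not core[start] or labels[start] != NOISE:
            continue
        labels[start] = nxt
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in neighbours[i]:
                if core[j] and labels[j] == NOISE:
                    labels[j] = nxt
                    queue.append(j)
        nxt += 1

    for i in range(n):
        if core[i]:
            continue
        core_nb = [j for j in neighbours[i] if core[j]]
        if core_nb:
            labels[i] = labels[min(core_nb)]
    return labels


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def cluster_area(coords: np.ndarray) -> tuple[float, np.ndarray | None]:
    """Convex-hull (shoelace) area of >= 3 points; collinear -> (0, None)."""
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        raise ValidationError("cluster area needs >= 3 members")
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return 0.0, None
    verts = coords[hull.vertices]          # CCW in 2-D
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return float(area), verts


def relative_density(coords: np.ndarray, area: float,
                     r_local: float = DEFAULT_R_LOCAL) -> float:
    """Mean over members of (local density within r_local) / (cluster density).

    The local count includes the focal member itself; for a uniform
    cluster the ratio is ~1 (slightly below, from hull-edge members
    seeing half-empty neighbourhoods).
    """
    coords = np.asarray(coords, float)
    if area <= 0:
        raise ValidationError("relative density undefined for degenerate cluster")
    tree = cKDTree(coords)
    counts = tree.query_ball_point(coords, r_local, return_length=True)
    rho_local = counts / (np.pi * r_local**2)
    rho_bar = len(coords) / area
    return float(rho_local.mean() / rho_bar)


# ---------------------------------------------------------------------------
# Cluster assembly and classification
# ---------------------------------------------------------------------------

def make_clusters(labels: np.ndarray, table: LocalizationTable, channel: str,
                  min_locs: Mapping[str, int] = DEFAULT_MIN_LOCS,
                  r_local: float = DEFAULT_R_LOCAL) -> list[ClusterRecord]:
    """Build records for every non-noise DBSCAN label meeting the size floor.

    ``labels`` must align row-wise with the given channel's records in
    ``table``. Degenerate (collinear) clusters are kept for counting and
    classification but carry nan density metrics.
    """
    if channel not in min_locs:
        raise ConfigError(f"no min_locs entry for channel {channel!r}")
    df = table.df[table.df["channel"] == channel].reset_index(drop=True)
    if len(labels) != len(df):
        raise ValidationError("labels do not align with the channel's records")
    floor = int(min_locs[channel])
    out: list[ClusterRecord] = []
    for lab in np.unique(labels):
        if lab == NOISE:
            continue
        sel = df[labels == lab]
        if len(sel) < floor:
            continue
        coords = sel[["x", "y"]].to_numpy(float)
        area, contour = cluster_area(coords)
        if area > 0:
            dens = len(sel) / area
            rel = relative_density(coords, area, r_local)
        else:
            dens = float("nan")
            rel = float("nan")
        out.append(ClusterRecord(
            cluster_id=int(lab), channel=channel,
            member_ids=sel["id"].to_numpy(),
            contour=contour, area=area, n_locs=len(sel),
            density=dens, relative_density=rel))
    return out


def classify_interaction(cluster: ClusterRecord, doc: DoCResult,
                         doc_threshold: float = DEFAULT_DOC_THRESHOLD,
                         hic_min: int = DEFAULT_HIC_MIN) -> str:
    """NIC/LIC/HIC from the number of members with DoC score >= threshold."""
    direction = _direction_for(cluster.channel, doc)
    scores = doc.score_by_id(direction)
    missing = [i for i in cluster.member_ids if i not in scores.index]
    if missing:
        raise ValidationError(
            f"cluster {cluster.cluster_id}: members without DoC scores: "
            f"{missing[:5]}")
    n_int = int((scores.loc[cluster.member_ids] >= doc_threshold).sum())
    if n_int == 0:
        return "NIC"
    if n_int < hic_min:
        return "LIC"
    return "HIC"


def classify_clusters(clusters: Sequence[ClusterRecord], doc: DoCResult,
                      doc_threshold: float = DEFAULT_DOC_THRESHOLD,
                      hic_min: int = DEFAULT_HIC_MIN) -> list[ClusterRecord]:
    """Return copies of the records with n_interacting and class filled in."""
    out = []
    for c in clusters:
        direction = _direction_for(c.channel, doc)
        scores = doc.score_by_id(direction)
        n_int = int((scores.loc[c.member_ids] >= doc_threshold).sum())
        cls = classify_interaction(c, doc, doc_threshold, hic_min)
        out.append(replace(c, n_interacting=n_int, interaction_class=cls))
    return out


def _direction_for(channel: str, doc: DoCResult) -> str:
    for d in doc.directions:
        if d.split("->")[0] == channel:
            return d
    raise ValidationError(f"no DoC direction with source channel {channel!r}")


def cluster_channel(table: LocalizationTable, doc: DoCResult, channel: str,
                    eps: float = DEFAULT_EPS, min_pts: int = DEFAULT_MIN_PTS,
                    min_locs: Mapping[str, int] = DEFAULT_MIN_LOCS,
                    doc_threshold: float = DEFAULT_DOC_THRESHOLD,
                    hic_min: int = DEFAULT_HIC_MIN) -> list[ClusterRecord]:
    """DBSCAN -> size filter -> classification for one channel of a table."""
    labels = dbscan(table.coords(channel), eps, min_pts)
    clusters = make_clusters(labels, table, channel, min_locs)
    return classify_clusters(clusters, doc, doc_threshold, hic_min)


# ---------------------------------------------------------------------------
# Per-ROI summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSummary:
    """Cluster metrics for one ROI, broken out by interaction class."""

    clusters_per_class: dict[str, int]
    mean_area_per_class: dict[str, float]                 # nan when absent
    mean_n_locs: dict[str, dict[str, float]]              # channel -> class -> mean
    mean_relative_density: dict[str, dict[str, float]]
    percent_interacting_in_clusters: dict[str, float | None]  # None = undefined


def roi_summary(clusters: Sequence[ClusterRecord], doc: DoCResult,
                roi: RoiPolygon | None = None) -> RoiSummary:
    """Summarize one ROI's classified clusters.

    Percent-interacting-in-clusters per channel is the share of that
    channel's interacting localizations (DoC >= threshold) that belong
    to a retained cluster; with no interacting localizations the
    percentage is undefined and reported as None, not 0. Degenerate
    clusters contribute to counts but not to area/density means.
    """
    for c in clusters:
        if not c.interaction_class:
            raise ValidationError("clusters must be classified before summarizing")
    channels = sorted({d.split("->")[0] for d in doc.directions})
    counts = {cls: 0 for cls in CLASSES}
    areas: dict[str, list[float]] = {cls: [] for cls in CLASSES}
    nlocs: dict[str, dict[str, list[float]]] = \
        {ch: {cls: [] for cls in CLASSES} for ch in channels}
    rels: dict[str, dict[str, list[float]]] = \
        {ch: {cls: [] for cls in CLASSES} for ch in channels}
    for c in clusters:
        counts[c.interaction_class] += 1
        if not c.degenerate:
            areas[c.interaction_class].append(c.area)
            rels[c.channel][c.interaction_class].append(c.relative_density)
        nlocs[c.channel][c.interaction_class].append(c.n_locs)

    def _mean(v):
        return float(np.mean(v)) if v else float("nan")

    pct: dict[str, float | None] = {}
    for ch in channels:
        direction = _direction_for(ch, doc)
        df = doc.per_direction[direction]
        interacting = set(df.loc[df["score"] >= doc.threshold, "id"])
        if not interacting:
            pct[ch] = None
            continue
        in_clusters = set()
        for c in clusters:
            if c.channel == ch:
                in_clusters.update(int(i) for i in c.member_ids)
        pct[ch] = 100.0 * len(interacting & in_clusters) / len(interacting)

    return RoiSummary(
        clusters_per_class=counts,
        mean_area_per_class={cls: _mean(areas[cls]) for cls in CLASSES},
        mean_n_locs={ch: {cls: _mean(nlocs[ch][cls]) for cls in CLASSES}
                     for ch in channels},
        mean_relative_density={ch: {cls: _mean(rels[ch][cls]) for cls in CLASSES}
                               for ch in channels},
        percent_interacting_in_clusters=pct,
    )


def aggregate_summaries(summaries: Sequence[RoiSummary],
                        min_rois: int = 3) -> pd.DataFrame:
    """Across-ROI means of per-class cluster counts and areas.

    A class contributed by fewer than ``min_rois`` ROIs is flagged
    ``excluded`` (too few values to average meaningfully), mirroring the
    exclusion rule used for sparse cluster classes.
    """
    rows = []
    for cls in CLASSES:
        counts = [s.clusters_per_class[cls] for s in summaries]
        areas = [s.mean_area_per_class[cls] for s in summaries
                 if np.isfinite(s.mean_area_per_class[cls])]
        contributing = sum(1 for c in counts if c > 0)
        rows.append({
            "class": cls,
            "mean_clusters_per_roi": float(np.mean(counts)) if counts else float("nan"),
            "mean_area": float(np.mean(areas)) if areas else float("nan"),
            "n_rois_contributing": contributing,
            "excluded": contributing < min_rois,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trimer accounting
# ---------------------------------------------------------------------------

def estimate_trimers(n_locs: int) -> int:
    """Lower-bound trimer count for a homotrimeric protein: floor(n/3)."""
    if n_locs < 0:
        raise ValidationError("n_locs must be >= 0")
    return int(n_locs) // 3
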