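"""Per-localization degree-of-colocalization (DoC) scoring.

Coordinate-based colocalization asks, for each localization, whether the
density of the *other* channel grows around it the same way its own
channel's density does. For localization i of the source channel and
radii r_k = k*dr (k = 1..K, K*dr = R_max) the neighbour counts
N_same(i, r_k) (excluding i) and N_cross(i, r_k) are converted to
area-normalized gradients

    D(i, r_k) = (N(i, r_k) / N(i, R_max)) * (R_max^2 / r_k^2),

and the score is the Spearman rank correlation of the two gradient
vectors over k, damped by the cross-channel nearest-neighbour distance:

    score_i = rho_spearman(D_same, D_cross) * exp(-d_i / R_max).

Scores live in [-1, 1]; a localization with no same- or cross-channel
neighbours within R_max, or a zero-variance rank vector, scores 0
(neutral). A score >= 0.4 defines an "interacting" localization.

Defaults dr = 20 nm, R_max = 500 nm. Counts use closed balls
(distance <= r_k). No edge correction is applied at ROI boundaries;
points within R_max of the boundary see truncated neighbourhoods in
both channels, a known shared bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .errors import ValidationError
from .locdata_io import LocalizationTable

__all__ = [
    "DoCResult",
    "nearest_neighbor_distances",
    "compute_doc",
    "percent_colocalized",
    "DEFAULT_DR",
    "DEFAULT_R_MAX",
    "DEFAULT_DOC_THRESHOLD",
]

DEFAULT_DR = 20.0          # nm, radius step
DEFAULT_R_MAX = 500.0      # nm, largest correlation radius
DEFAULT_DOC_THRESHOLD = 0.4


@dataclass(frozen=True)
class DoCResult:
    """DoC scores for both directions of a two-channel table.

    ``per_direction`` maps a direction key (e.g. ``"5-LO->FLAP"``) to a
    DataFrame with columns id, x, y, score, nnd, colocalized.
    """

    per_direction: Mapping[str, pd.DataFrame]
    dr: float
    r_max: float
    threshold: float

    def scores(self, direction: str) -> np.ndarray:
        return self.per_direction[direction]["score"].to_numpy()

    def score_by_id(self, direction: str) -> pd.Series:
        df = self.per_direction[direction]
        return pd.Series(df["score"].to_numpy(), index=df["id"].to_numpy())

    @property
    def directions(self) -> list[str]:
        return list(self.per_direction)


def nearest_neighbor_distances(query: np.ndarray, reference: np.ndarray,
                               exclude_self: bool = False) -> np.ndarray:
    """Euclidean distance from each query point to its nearest reference point.

    With ``exclude_self`` the query and reference are taken to be the
    same indexed set and point i's trivial self-match is skipped (a
    distinct point at the same coordinates still counts at distance 0).
    """
    query = np.asarray(query, float)
    reference = np.asarray(reference, float)
    n_ref = len(reference)
    if n_ref == 0 or (exclude_self and n_ref < 2):
        raise ValidationError("reference set empty after self-exclusion")
    if len(query) == 0:
        return np.zeros(0)
    tree = cKDTree(reference)
    if not exclude_self:
        d, _ = tree.query(query, k=1)
        return np.asarray(d, float)
    d, idx = tree.query(query, k=2)
    self_first = idx[:, 0] == np.arange(len(query))
    return np.where(self_first, d[:, 1], d[:, 0])


def _count_matrix(tree: cKDTree, pts: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """(n, K) closed-ball neighbour counts, self included where applicable."""
    cols = [tree.query_ball_point(pts, r, return_length=True) for r in radii]
    return np.column_stack(cols).astype(float)


def _spearman_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho with average-rank ties; zero variance -> 0."""
    ra = rankdata(a, axis=1, method="average")
    rb = rankdata(b, axis=1, method="average")
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    va = np.einsum("ij,ij->i", ra, ra)
    vb = np.einsum("ij,ij->i", rb, rb)
    num = np.einsum("ij,ij->i", ra, rb)
    ok = (va > 0) & (vb > 0)
    rho = np.zeros(len(a))
    rho[ok] = num[ok] / np.sqrt(va[ok] * vb[ok])
    return np.clip(rho, -1.0, 1.0)


def _doc_one_direction(src_xy: np.ndarray, cross_xy: np.ndarray,
                       dr: float, r_max: float) -> tuple[np.ndarray, np.ndarray]:
    radii = np.arange(1, int(round(r_max / dr)) + 1) * dr
    tree_src = cKDTree(src_xy)
    tree_cross = cKDTree(cross_xy)

    n_same = _count_matrix(tree_src, src_xy, radii) - 1.0  # exclude the point itself
    n_cross = _count_matrix(tree_cross, src_xy, radii)
    d_i = tree_cross.query(src_xy, k=1)[0]

    same_tot = n_same[:, -1]
    cross_tot = n_cross[:, -1]
    scale = (r_max / radii) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        d_same = n_same / same_tot[:, None] * scale
        d_cross = n_cross / cross_tot[:, None] * scale

    valid = (same_tot > 0) & (cross_tot > 0)
    scores = np.zeros(len(src_xy))
    if valid.any():
        rho = _spearman_rows(d_same[valid], d_cross[valid])
        scores[valid] = rho * np.exp(-d_i[valid] / r_max)
    return scores, np.asarray(d_i, float)


def compute_doc(table: LocalizationTable,
                dr: float = DEFAULT_DR,
                r_max: float = DEFAULT_R_MAX,
                threshold: float = DEFAULT_DOC_THRESHOLD) -> DoCResult:
    """Score every localization of a two-channel table in both directions.

    ``r_max`` must be a positive integer multiple of ``dr``. Both
    channels must be non-empty.
    """
    if dr <= 0 or r_max <= 0:
        raise ValidationError("dr and r_max must be positive")
    k = r_max / dr
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValidationError("r_max must be a positive multiple of dr")
    if len(table.channels) != 2:
        raise ValidationError("DoC needs exactly two declared channels")
    cha, chb = table.channels
    dfs = {ch: table.df[table.df["channel"] == ch] for ch in (cha, chb)}
    for ch, df in dfs.items():
        if len(df) == 0:
            raise ValidationError(f"channel {ch!r} is empty")

    out: dict[str, pd.DataFrame] = {}
    for src, other in ((cha, chb), (chb, cha)):
        src_df = dfs[src]
        scores, nnd = _doc_one_direction(
            src_df[["x", "y"]].to_numpy(float),
            dfs[other][["x", "y"]].to_numpy(float),
            dr, r_max)
        out[f"{src}->{other}"] = pd.DataFrame({
            "id": src_df["id"].to_numpy(),
            "x": src_df["x"].to_numpy(),
            "y": src_df["y"].to_numpy(),
            "score": scores,
            "nnd": nnd,
            "colocalized": scores >= threshold,
        })
    return DoCResult(out, dr=dr, r_max=r_max, threshold=threshold)


def percent_colocalized(result: DoCResult,
                        threshold: float | None = None) -> dict[str, float]:
    """100 x fraction of scored localizations with score >= threshold, per direction."""
    thr = result.threshold if threshold is None else threshold
    out = {}
    for direction, df in result.per_direction.items():
        if len(df) == 0:
            raise ValidationError(f"no scores for direction {direction}")
        out[direction] = 100.0 * float((df["score"] >= thr).sum()) / len(df)
    return out
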