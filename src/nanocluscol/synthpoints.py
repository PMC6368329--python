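"""Synthetic two-channel SMLM scenes with ground truth.

Real input to this package is a localization list from a dSTORM
acquisition of two proteins (here dubbed "5-LO" and "FLAP") on the
nuclear envelope of an activated mast cell. This module emulates such
scenes so every downstream stage can be validated against known ground
truth:

* complete spatial randomness (CSR) — the null model for colocalization,
* Thomas processes — Poisson parents with Gaussian-scattered offspring,
  i.e. planted nanoclusters,
* a two-channel compound model in which a controllable fraction of
  channel-A parent centres is reused by channel B (true colocalization),
  each molecule blinks a Geometric number of times, and every
  localization carries isotropic Gaussian localization error,
* a ring-shaped ROI approximating the nuclear-envelope annulus.

Ground truth records, per localization: molecule id, parent cluster (or
"background"), channel, and whether the parent is shared between
channels. Identical seed and parameters give byte-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .locdata_io import LocalizationTable, RoiPolygon

__all__ = [
    "SyntheticScene",
    "simulate_csr",
    "simulate_thomas",
    "simulate_two_channel",
    "ring_roi",
    "BACKGROUND",
]

BACKGROUND = "background"

# Defaults chosen to emulate the imaged system: nuclear-envelope annulus
# roughly 8-10 µm across; nanoclusters of ~50 nm Gaussian spread (convex
# hull areas of order 1e4-1e5 nm^2); ~20 nm localization precision
# typical of dSTORM; a handful of blinks per molecule.
DEFAULT_SIGMA_CLUSTER = 50.0   # nm, offspring spread
DEFAULT_SIGMA_LOC = 15.0       # nm, localization error
DEFAULT_BLINK_MEAN = 4.0       # localizations per molecule


@dataclass(frozen=True)
class SyntheticScene:
    """A simulated scene: localization table plus full ground truth."""

    table: LocalizationTable
    truth: pd.DataFrame           # id, channel, molecule, parent, shared
    parents: dict[str, np.ndarray]   # channel -> (n_parents, 2) centres
    parent_ids: dict[str, np.ndarray]  # channel -> parent label per centre
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.truth) != len(self.table):
            raise ValidationError("ground truth does not cover the table")
        if set(self.truth["id"]) != set(self.table.df["id"]):
            raise ValidationError("ground-truth ids do not match table ids")


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _uniform_in_polygon(region: RoiPolygon, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points from the polygon's bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = region.bounds()
    out = []
    got = 0
    frac = max(region.area / ((maxx - minx) * (maxy - miny)), 1e-6)
    while got < n:
        m = max(int((n - got) / frac * 1.2), 16)
        cand = np.column_stack([
            rng.uniform(minx, maxx, m),
            rng.uniform(miny, maxy, m),
        ])
        keep = cand[region.contains_points(cand)]
        out.append(keep)
        got += len(keep)
    return np.concatenate(out)[:n]


def _scene_from_parts(xy: np.ndarray, channel: np.ndarray, molecule: np.ndarray,
                      parent: np.ndarray, shared: np.ndarray,
                      parents: dict[str, np.ndarray],
                      parent_ids: dict[str, np.ndarray],
                      channels: tuple[str, ...],
                      params: dict[str, Any]) -> SyntheticScene:
    n = len(xy)
    ids = np.arange(n)
    df = pd.DataFrame({
        "id": ids,
        "x": xy[:, 0] if n else np.empty(0),
        "y": xy[:, 1] if n else np.empty(0),
        "channel": channel,
        "frame": np.zeros(n, dtype=int),
    })
    truth = pd.DataFrame({
        "id": ids,
        "channel": channel,
        "molecule": molecule,
        "parent": parent,
        "shared": shared,
    })
    return SyntheticScene(LocalizationTable(df, channels), truth,
                          parents, parent_ids, params)


# ---------------------------------------------------------------------------
# Single-channel generators
# ---------------------------------------------------------------------------

def simulate_csr(region: RoiPolygon, n: int, seed: int,
                 channel: str = "ch0") -> SyntheticScene:
    """n points uniform over the polygon, all labelled background."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    xy = _uniform_in_polygon(region, n, rng)
    return _scene_from_parts(
        xy,
        channel=np.full(n, channel, dtype=object),
        molecule=np.arange(n),
        parent=np.full(n, BACKGROUND, dtype=object),
        shared=np.zeros(n, dtype=bool),
        parents={channel: np.empty((0, 2))},
        parent_ids={channel: np.empty(0, dtype=object)},
        channels=(channel,),
        params={"kind": "csr", "n": n, "seed": seed},
    )


def simulate_thomas(region: RoiPolygon, n_parents: int, mu_offspring: float,
                    sigma_cluster: float, seed: int,
                    channel: str = "ch0") -> SyntheticScene:
    """Thomas process: uniform parents, Poisson(mu) Gaussian-scattered offspring.

    Offspring falling outside the region are kept — clusters may straddle
    the ROI edge; restricting to the ROI is a separate explicit step.
    """
    if n_parents < 0:
        raise ValidationError("n_parents must be >= 0")
    if mu_offspring <= 0:
        raise ValidationError("mu_offspring must be > 0")
    if sigma_cluster < 0:
        raise ValidationError("sigma_cluster must be >= 0")
    rng_p, rng_o = _rng_streams(seed, 2)
    centres = _uniform_in_polygon(region, n_parents, rng_p)
    labels = np.array([f"{channel}:p{i}" for i in range(n_parents)], dtype=object)
    counts = rng_o.poisson(mu_offspring, n_parents)
    parent_idx = np.repeat(np.arange(n_parents), counts)
    xy = centres[parent_idx] + rng_o.normal(0.0, sigma_cluster,
                                            (len(parent_idx), 2))
    n = len(xy)
    return _scene_from_parts(
        xy,
        channel=np.full(n, channel, dtype=object),
        molecule=np.arange(n),
        parent=labels[parent_idx] if n else np.empty(0, dtype=object),
        shared=np.zeros(n, dtype=bool),
        parents={channel: centres},
        parent_ids={channel: labels},
        channels=(channel,),
        params={"kind": "thomas", "n_parents": n_parents,
                "mu_offspring": mu_offspring, "sigma_cluster": sigma_cluster,
                "seed": seed},
    )


# ---------------------------------------------------------------------------
# Two-channel compound model
# ---------------------------------------------------------------------------

def simulate_two_channel(
    region: RoiPolygon,
    seed: int,
    channels: tuple[str, str] = ("5-LO", "FLAP"),
    n_parents: tuple[int, int] = (20, 20),
    mu_molecules: tuple[float, float] = (10.0, 15.0),
    sigma_cluster: tuple[float, float] = (DEFAULT_SIGMA_CLUSTER,
                                          DEFAULT_SIGMA_CLUSTER),
    n_background: tuple[int, int] = (100, 100),
    coloc_fraction: float = 0.0,
    blink_mean: float = DEFAULT_BLINK_MEAN,
    sigma_loc: float = DEFAULT_SIGMA_LOC,
) -> SyntheticScene:
    """Two-channel clustered scene with blinking and localization error.

    A fraction ``coloc_fraction`` of channel-A parent centres is reused
    as channel-B parent centres; those shared parents are the true
    colocalized clusters, and the ground truth flags every localization
    descending from one. Each parent hosts Poisson(``mu_molecules``)
    molecules scattered with ``sigma_cluster``; per-channel CSR
    background molecules are added; every molecule emits
    Geometric(1/``blink_mean``) localizations (support >= 1), each
    displaced by isotropic Gaussian(``sigma_loc``).
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValidationError("coloc_fraction must be in [0, 1]")
    if blink_mean < 1.0:
        raise ValidationError("blink_mean must be >= 1")
    cha, chb = channels
    rng_pa, rng_pb, rng_a, rng_b = _rng_streams(seed, 4)

    centres_a = _uniform_in_polygon(region, n_parents[0], rng_pa)
    labels_a = np.array([f"{cha}:p{i}" for i in range(n_parents[0])], dtype=object)

    n_shared = int(round(coloc_fraction * min(n_parents)))
    shared_idx = rng_pb.choice(n_parents[0], n_shared, replace=False) \
        if n_shared else np.empty(0, dtype=int)
    n_fresh = n_parents[1] - n_shared
    fresh = _uniform_in_polygon(region, n_fresh, rng_pb)
    centres_b = np.concatenate([centres_a[shared_idx], fresh]) \
        if n_parents[1] else np.empty((0, 2))
    # shared parents keep the channel-A label so the identity is explicit
    labels_b = np.concatenate([
        labels_a[shared_idx],
        np.array([f"{chb}:p{i}" for i in range(n_fresh)], dtype=object),
    ]) if n_parents[1] else np.empty(0, dtype=object)
    shared_b = np.concatenate([np.ones(n_shared, bool), np.zeros(n_fresh, bool)])

    def _one_channel(ch, centres, labels, shared_flags, mu, sig, n_bg, rng,
                     mol_offset):
        mols_xy, mols_parent, mols_shared = [], [], []
        counts = rng.poisson(mu, len(centres))
        for c, lab, sh, k in zip(centres, labels, shared_flags, counts):
            if k == 0:
                continue
            mols_xy.append(c + rng.normal(0.0, sig, (k, 2)))
            mols_parent.extend([lab] * k)
            mols_shared.extend([sh] * k)
        bg = _uniform_in_polygon(region, n_bg, rng)
        if len(bg):
            mols_xy.append(bg)
            mols_parent.extend([BACKGROUND] * n_bg)
            mols_shared.extend([False] * n_bg)
        if not mols_xy:
            e = np.empty(0)
            return (np.empty((0, 2)), e.astype(object), e.astype(int),
                    e.astype(bool))
        mxy = np.concatenate(mols_xy)
        mparent = np.asarray(mols_parent, dtype=object)
        mshared = np.asarray(mols_shared, dtype=bool)
        blinks = rng.geometric(1.0 / blink_mean, len(mxy))
        idx = np.repeat(np.arange(len(mxy)), blinks)
        xy = mxy[idx] + rng.normal(0.0, sigma_loc, (len(idx), 2))
        return xy, mparent[idx], idx + mol_offset, mshared[idx]

    xy_a, par_a, mol_a, sh_a = _one_channel(
        cha, centres_a, labels_a, np.isin(np.arange(n_parents[0]), shared_idx),
        mu_molecules[0], sigma_cluster[0], n_background[0], rng_a, 0)
    xy_b, par_b, mol_b, sh_b = _one_channel(
        chb, centres_b, labels_b, shared_b,
        mu_molecules[1], sigma_cluster[1], n_background[1], rng_b, 10**7)

    xy = np.concatenate([xy_a, xy_b]) if len(xy_a) + len(xy_b) else np.empty((0, 2))
    channel = np.concatenate([np.full(len(xy_a), cha, dtype=object),
                              np.full(len(xy_b), chb, dtype=object)])
    return _scene_from_parts(
        xy, channel,
        molecule=np.concatenate([mol_a, mol_b]),
        parent=np.concatenate([par_a, par_b]),
        shared=np.concatenate([sh_a, sh_b]),
        parents={cha: centres_a, chb: centres_b},
        parent_ids={cha: labels_a, chb: labels_b},
        channels=(cha, chb),
        params={"kind": "two_channel", "seed": seed,
                "n_parents": tuple(n_parents), "mu_molecules": tuple(mu_molecules),
                "sigma_cluster": tuple(sigma_cluster),
                "n_background": tuple(n_background),
                "coloc_fraction": coloc_fraction, "blink_mean": blink_mean,
                "sigma_loc": sigma_loc, "shared_parents": list(labels_a[shared_idx])},
    )


# ---------------------------------------------------------------------------
# Ring ROI
# ---------------------------------------------------------------------------

def ring_roi(center: Sequence[float], r_inner: float, r_outer: float,
             n_vertices: int = 256) -> RoiPolygon:
    """Annulus approximating the nuclear-envelope ROI, as one simple polygon.

    The outer and inner rings are joined through a narrow radial seam
    (angular width 1e-6 rad) at angle 0; a zero-width seam would make the
    polygon self-touching. The enclosed area is within 2% of
    pi*(r_outer^2 - r_inner^2) for n_vertices >= 64.
    """
    if not 0 < r_inner < r_outer:
        raise ValidationError("need 0 < r_inner < r_outer")
    if n_vertices < 8:
        raise ValidationError("n_vertices must be >= 8")
    cx, cy = center
    gap = 1e-6
    m = n_vertices // 2
    theta = np.linspace(gap, 2 * np.pi - gap, m)
    outer = np.column_stack([cx + r_outer * np.cos(theta),
                             cy + r_outer * np.sin(theta)])
    inner = np.column_stack([cx + r_inner * np.cos(theta[::-1]),
                             cy + r_inner * np.sin(theta[::-1])])
    return RoiPolygon(np.concatenate([outer, inner]))
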