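# nanocluscol

Cluster and colocalization analysis for two-channel single-molecule
localization microscopy (SMLM / dSTORM) point data.

SMLM experiments produce lists of localizations — sub-diffraction (x, y)
positions of single fluorophore blinks — rather than images. A central
question for membrane signaling is whether two proteins (here the
leukotriene-synthesis pair: the enzyme 5-LO and its homotrimeric
membrane scaffold FLAP) organize into interacting nanoclusters on the
nuclear envelope. `nanocluscol` provides two complementary answers:

**Clus-DoC track.** Each localization *i* of one channel receives a
degree-of-colocalization score

```
D(i, r_k) = (N(i, r_k) / N(i, R_max)) · (R_max² / r_k²),   r_k = kΔr
DoC_i     = ρ_Spearman(D_same(i,·), D_cross(i,·)) · exp(−d_i / R_max)
```

where `N` are same-/cross-channel neighbour counts, `d_i` is the
cross-channel nearest-neighbour distance, `Δr = 20 nm`,
`R_max = 500 nm`. A score ≥ 0.4 marks an "interacting" localization.
DBSCAN clusters (eps 20 nm, min_pts 3; retained at ≥ 5 localizations
for 5-LO, ≥ 10 for FLAP) are then classified by their number of
interacting members: **NIC** (0), **LIC** (1–4), **HIC** (≥ 5), with
convex-hull area, density, and relative density (mean 20 nm local
density over cluster-average density) per cluster.

**Unbiased track (VBMS).** Variable-bandwidth mean shift climbs the
kernel density estimate of the point cloud with per-point diagonal
bandwidths (reference operating point: fixed 250 nm), truncating kernel
sums at 4× the bandwidth. The data is pre-partitioned with DBSCAN at an
eps equal to the 99.9th percentile of nearest-neighbour distances
(isolated points removed), and converged modes are merged to clusters
of > 3 localizations. This makes no assumption about cluster size or
shape — useful for clusters curved around a membrane.

A synthetic-scene simulator (CSR, Thomas processes, and a two-channel
compound model with shared parents, Geometric blinking, and Gaussian
localization error) supplies ground truth for every stage, plus a
ring-shaped ROI emulating the nuclear envelope.

## Worked example

```python
from collections import Counter

import nanocluscol as nc

# Nuclear-envelope-like annulus, 4-5 um radius
roi = nc.ring_roi(center=(0, 0), r_inner=4000, r_outer=5000)

# Two-channel scene: every FLAP parent cluster shares a 5-LO parent
scene = nc.simulate_two_channel(roi, seed=3, coloc_fraction=1.0)
print(f"{len(scene.table)} localizations, channels {scene.table.channels}")

doc = nc.compute_doc(scene.table)
for direction, pct in nc.percent_colocalized(doc).items():
    print(f"{direction}: {pct:.1f}% colocalized (DoC >= 0.4)")

for ch in scene.table.channels:
    clusters = nc.cluster_channel(scene.table, doc, ch)
    counts = Counter(c.interaction_class for c in clusters)
    print(f"{ch}: {len(clusters)} clusters "
          f"(NIC {counts['NIC']}, LIC {counts['LIC']}, HIC {counts['HIC']})")

flap_hic = [c for c in nc.cluster_channel(scene.table, doc, "FLAP")
            if c.interaction_class == "HIC"]
biggest = max(flap_hic, key=lambda c: c.n_locs)
print(f"largest FLAP HIC: {biggest.n_locs} localizations "
      f"(~{nc.estimate_trimers(biggest.n_locs)} trimers), "
      f"area {biggest.area:.0f} nm^2, "
      f"relative density {biggest.relative_density:.2f}")
```

prints

```
2879 localizations, channels ('5-LO', 'FLAP')
5-LO->FLAP: 69.4% colocalized (DoC >= 0.4)
FLAP->5-LO: 70.2% colocalized (DoC >= 0.4)
5-LO: 57 clusters (NIC 12, LIC 4, HIC 41)
FLAP: 29 clusters (NIC 5, LIC 2, HIC 22)
largest FLAP HIC: 97 localizations (~32 trimers), area 18231 nm^2, relative density 1.10
```

Because every FLAP parent shares a 5-LO parent, ~70% of localizations
score as colocalized and most retained clusters are HIC; rerunning with
`coloc_fraction=0.0` drops colocalization to ~6% and HIC essentially
vanish. The trimer estimate divides the localization count by three,
reflecting FLAP's homotrimeric stoichiometry (a blink-inflated upper
bound on molecules, hence "~").

## Command line

```sh
nanocluscol simulate --config cfg.yaml --seed 5 --out-dir sim/
nanocluscol clusdoc  --config run.yaml --out-dir analysis/
nanocluscol vbms     --config run.yaml --out-dir analysis/
nanocluscol report analysis/clusters.csv other/clusters.csv --value area_nm2
```

Inputs are tab-delimited localization tables (configurable column
dialect, coordinates converted to nm) and ROI polygon files (one
`x<TAB>y` vertex per line). Outputs are CSV/JSON: per-localization DoC
scores, cluster tables, per-ROI summaries, VBMS assignments,
point-weighted histograms, and a run manifest.

## Layout

- `src/nanocluscol/locdata_io.py` — localization tables, ROI polygons, I/O
- `src/nanocluscol/synthpoints.py` — synthetic scenes with ground truth
- `src/nanocluscol/doc_score.py` — DoC scoring and percent colocalized
- `src/nanocluscol/cluster_interaction.py` — DBSCAN, NIC/LIC/HIC, morphometrics
- `src/nanocluscol/vbms.py` — variable-bandwidth mean-shift track
- `src/nanocluscol/report.py`, `cli.py` — histograms, statistics, pipeline, CLI

See `docs/methods.md` for the models, parameter choices, and known
limitations.
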