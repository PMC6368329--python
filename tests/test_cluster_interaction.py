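"""DBSCAN, cluster thresholds, NIC/LIC/HIC classes, morphometrics."""

import numpy as np
import pandas as pd
import pytest
import shapely

import nanocluscol as nc
from nanocluscol.errors import ConfigError, ValidationError


def _table(xy, channel="5-LO", channels=("5-LO", "FLAP")):
    df = pd.DataFrame({"id": np.arange(len(xy)), "x": xy[:, 0], "y": xy[:, 1],
                       "channel": channel, "frame": 0})
    return nc.LocalizationTable(df, channels)


def _fake_doc(ids, scores, channel="5-LO", other="FLAP"):
    df = pd.DataFrame({"id": ids, "x": 0.0, "y": 0.0, "score": scores,
                       "nnd": 0.0, "colocalized": np.asarray(scores) >= 0.4})
    other_df = df.iloc[:0]
    return nc.DoCResult({f"{channel}->{other}": df,
                         f"{other}->{channel}": other_df},
                        dr=20.0, r_max=500.0, threshold=0.4)


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

def _brute_dbscan(points, eps, min_pts):
    """Independent O(n^2) DBSCAN: distance matrix + union-find cores,
    border points to the lowest-id claiming core point."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    within = d <= eps
    core = within.sum(1) >= min_pts           # diagonal counts the point itself
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if core[i] and core[j] and within[i, j]:
                parent[find(i)] = find(j)
    labels = np.full(n, -1)
    roots = {}
    for i in range(n):
        if core[i]:
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
    for i in range(n):
        if not core[i]:
            claimers = [j for j in range(n) if core[j] and within[i, j]]
            if claimers:
                labels[i] = labels[min(claimers)]
    return labels


def _canonical(labels):
    clusters = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            clusters.setdefault(lab, set()).add(i)
    return {frozenset(s) for s in clusters.values()}


class TestDbscan:
    def test_two_separated_triplets(self):
        tri = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        pts = np.concatenate([tri, tri + 100.0])
        labels = nc.dbscan(pts, eps=10.0, min_pts=3)
        assert len(set(labels)) == 2 and -1 not in labels

    def test_all_isolated_is_noise(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        labels = nc.dbscan(pts, eps=10.0, min_pts=2)
        assert set(labels) == {-1}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, (300, 2))
        labels = nc.dbscan(pts, eps=50.0, min_pts=3)
        oracle = _brute_dbscan(pts, eps=50.0, min_pts=3)
        assert _canonical(labels) == _canonical(oracle)
        np.testing.assert_array_equal(labels == -1, oracle == -1)

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 500, (200, 2))
        labels = nc.dbscan(pts, eps=40.0, min_pts=3)
        perm = rng.permutation(200)
        shuffled = nc.dbscan(pts[perm], eps=40.0, min_pts=3)
        back = np.empty(200, dtype=int)
        back[perm] = shuffled
        assert _canonical(labels) == _canonical(back)


# ---------------------------------------------------------------------------
# Size thresholds and classification
# ---------------------------------------------------------------------------

class TestMakeClusters:
    def _clustered_table(self, sizes, channel):
        blocks, labels = [], []
        rng = np.random.default_rng(0)
        for k, size in enumerate(sizes):
            blocks.append(rng.uniform(0, 30, (size, 2)) + 1000.0 * k)
            labels.extend([k] * size)
        return _table(np.concatenate(blocks), channel), np.asarray(labels)

    @pytest.mark.parametrize("channel,size,kept", [
        ("5-LO", 5, True),     # at the 5-LO floor: retained
        ("5-LO", 4, False),
        ("FLAP", 9, False),    # below the FLAP floor: discarded
        ("FLAP", 10, True),    # at the FLAP floor: retained
    ])
    def test_channel_size_floors(self, channel, size, kept):
        table, labels = self._clustered_table([size], channel)
        clusters = nc.make_clusters(labels, table, channel)
        assert (len(clusters) == 1) == kept

    def test_noise_ignored(self):
        table, labels = self._clustered_table([6], "5-LO")
        labels[-1] = -1
        clusters = nc.make_clusters(labels, table, "5-LO")
        assert clusters[0].n_locs == 5

    def test_unknown_channel_in_map(self):
        table, labels = self._clustered_table([6], "5-LO")
        with pytest.raises(ConfigError):
            nc.make_clusters(labels, table, "5-LO", min_locs={"FLAP": 10})

    def test_members_inside_contour(self):
        table, labels = self._clustered_table([30], "5-LO")
        (c,) = nc.make_clusters(labels, table, "5-LO")
        poly = shapely.Polygon(c.contour)
        pts = table.coords("5-LO")
        assert shapely.covers(shapely.buffer(poly, 1e-9),
                              shapely.points(pts)).all()


class TestClassification:
    @pytest.mark.parametrize("n_int,expected", [
        (0, "NIC"), (1, "LIC"), (4, "LIC"), (5, "HIC"), (12, "HIC"),
    ])
    def test_truth_table(self, n_int, expected):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 50, (15, 2))
        table = _table(xy)
        labels = np.zeros(15, dtype=int)
        (cluster,) = nc.make_clusters(labels, table, "5-LO")
        scores = np.full(15, 0.0)
        scores[:n_int] = 0.9
        doc = _fake_doc(np.arange(15), scores)
        assert nc.classify_interaction(cluster, doc) == expected
        (classified,) = nc.classify_clusters([cluster], doc)
        assert classified.n_interacting == n_int
        assert classified.interaction_class == expected

    def test_missing_score_rejected(self):
        rng = np.random.default_rng(2)
        table = _table(rng.uniform(0, 50, (8, 2)))
        (cluster,) = nc.make_clusters(np.zeros(8, int), table, "5-LO")
        doc = _fake_doc(np.arange(5), np.zeros(5))   # ids 5..7 unscored
        with pytest.raises(ValidationError):
            nc.classify_interaction(cluster, doc)

    def test_classification_exhaustive_exclusive(self, coloc_scene):
        doc = nc.compute_doc(coloc_scene.table)
        for ch in coloc_scene.table.channels:
            for c in nc.cluster_channel(coloc_scene.table, doc, ch):
                assert c.interaction_class in nc.cluster_interaction.CLASSES


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

class TestClusterArea:
    def test_right_triangle(self):
        area, contour = nc.cluster_area(np.array([[0.0, 0.0], [4.0, 0.0],
                                                  [0.0, 3.0]]))
        assert area == pytest.approx(6.0)
        assert len(contour) == 3

    def test_interior_point_ignored(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [1000.0, 1000.0],
                        [0.0, 1000.0], [500.0, 500.0]])
        area, contour = nc.cluster_area(pts)
        assert area == pytest.approx(1.0e6)
        assert len(contour) == 4

    def test_collinear_flagged_degenerate(self):
        area, contour = nc.cluster_area(np.array([[0.0, 0.0], [1.0, 1.0],
                                                  [2.0, 2.0], [3.0, 3.0]]))
        assert area == 0.0 and contour is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_shapely_hull(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, (100, 2))
        area, _ = nc.cluster_area(pts)
        oracle = shapely.MultiPoint(pts).convex_hull.area
        assert area == pytest.approx(oracle, rel=1e-12)

    def test_too_few_members_rejected(self):
        with pytest.raises(ValidationError):
            nc.cluster_area(np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestRelativeDensity:
    def test_six_point_longhand(self):
        """Two tight triangles 424 nm apart: every member sees exactly its
        3-point triangle within 20 nm, so mean local density is
        3/(400*pi) nm^-2; the hull area (shoelace, by hand) is 6050 nm^2
        and the cluster density 6/6050, giving 6050/(800*pi)."""
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0],
                        [300.0, 300.0], [310.0, 300.0], [300.0, 310.0]])
        area, _ = nc.cluster_area(pts)
        assert area == pytest.approx(6050.0)
        rel = nc.relative_density(pts, area)
        assert rel == pytest.approx(6050.0 / (800.0 * np.pi), rel=1e-12)

    def test_uniform_disc_near_one(self):
        """A dense uniform disc has relative density ~1: local neighbourhoods
        see the cluster-average density (hull-edge members see slightly less;
        the focal-point term is negligible once ~10+ members fall within
        20 nm, as in any DBSCAN-retained nanocluster)."""
        rng = np.random.default_rng(3)
        r = 250.0 * np.sqrt(rng.uniform(0, 1, 2000))
        th = rng.uniform(0, 2 * np.pi, 2000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        area, _ = nc.cluster_area(pts)
        assert nc.relative_density(pts, area) == pytest.approx(1.0, rel=0.10)

    def test_concentrated_blob_much_greater_than_one(self):
        rng = np.random.default_rng(4)
        blob = rng.uniform(0, 20, (50, 2))
        corners = np.array([[0.0, 0.0], [5000.0, 0.0], [5000.0, 5000.0],
                            [0.0, 5000.0]])
        pts = np.concatenate([blob, corners])
        area, _ = nc.cluster_area(pts)
        assert nc.relative_density(pts, area) > 10.0

    def test_degenerate_area_rejected(self):
        with pytest.raises(ValidationError):
            nc.relative_density(np.zeros((5, 2)), 0.0)


# ---------------------------------------------------------------------------
# Summaries and trimer accounting
# ---------------------------------------------------------------------------

class TestRoiSummary:
    def _mini(self):
        rng = np.random.default_rng(5)
        rows = []
        clusters = []
        scores_a = []
        ids = iter(range(10_000))
        specs = [("NIC", 0), ("HIC", 6), ("HIC", 7)]
        for k, (cls, n_int) in enumerate(specs):
            xy = rng.uniform(0, 40, (12, 2)) + 2000.0 * k
            member_ids = np.array([next(ids) for _ in range(12)])
            rows.append(pd.DataFrame({"id": member_ids, "x": xy[:, 0],
                                      "y": xy[:, 1], "channel": "5-LO",
                                      "frame": 0}))
            area, contour = nc.cluster_area(xy)
            clusters.append(nc.ClusterRecord(
                cluster_id=k, channel="5-LO", member_ids=member_ids,
                contour=contour, area=area, n_locs=12,
                density=12 / area, relative_density=1.0,
                n_interacting=n_int, interaction_class=cls))
            s = np.zeros(12)
            s[:n_int] = 0.9
            scores_a.append(pd.DataFrame({
                "id": member_ids, "x": xy[:, 0], "y": xy[:, 1], "score": s,
                "nnd": 0.0, "colocalized": s >= 0.4}))
        # three interacting localizations outside any cluster
        extra_ids = np.array([next(ids) for _ in range(3)])
        scores_a.append(pd.DataFrame({
            "id": extra_ids, "x": 0.0, "y": 0.0, "score": 0.8, "nnd": 0.0,
            "colocalized": True}))
        doc = nc.DoCResult(
            {"5-LO->FLAP": pd.concat(scores_a, ignore_index=True),
             "FLAP->5-LO": scores_a[0].iloc[:0]},
            dr=20.0, r_max=500.0, threshold=0.4)
        return clusters, doc

    def test_counts_per_class(self):
        clusters, doc = self._mini()
        s = nc.roi_summary(clusters, doc)
        assert s.clusters_per_class == {"NIC": 1, "LIC": 0, "HIC": 2}

    def test_percent_interacting_in_clusters(self):
        clusters, doc = self._mini()
        s = nc.roi_summary(clusters, doc)
        # 13 interacting 5-LO localizations of 16 total sit in clusters
        assert s.percent_interacting_in_clusters["5-LO"] == \
            pytest.approx(100.0 * 13 / 16)

    def test_no_interacting_is_missing_not_zero(self):
        clusters, doc = self._mini()
        zeroed = {}
        for d, df in doc.per_direction.items():
            df = df.copy()
            df["score"] = 0.0
            df["colocalized"] = False
            zeroed[d] = df
        doc0 = nc.DoCResult(zeroed, dr=20.0, r_max=500.0, threshold=0.4)
        clusters0 = [
            nc.ClusterRecord(**{**c.__dict__, "n_interacting": 0,
                                "interaction_class": "NIC"})
            for c in clusters]
        s = nc.roi_summary(clusters0, doc0)
        assert s.percent_interacting_in_clusters["5-LO"] is None

    def test_aggregate_flags_sparse_classes(self):
        clusters, doc = self._mini()
        s = nc.roi_summary(clusters, doc)
        agg = nc.aggregate_summaries([s, s], min_rois=3)
        assert agg.loc[agg["class"] == "HIC", "excluded"].item()
        assert agg.loc[agg["class"] == "HIC",
                       "mean_clusters_per_roi"].item() == pytest.approx(2.0)


class TestEstimateTrimers:
    @pytest.mark.parametrize("n,expected", [(450, 150), (250, 83), (2, 0)])
    def test_worked_examples(self, n, expected):
        assert nc.estimate_trimers(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            nc.estimate_trimers(-1)


# ---------------------------------------------------------------------------
# Recovery properties
# ---------------------------------------------------------------------------

class TestRecovery:
    def test_planted_cluster_recovery(self, big_square_roi):
        """Thomas clusters with 10% CSR background: >= 90% of parents are
        matched by a retained cluster centroid within 100 nm."""
        matched = total = 0
        for seed in range(3):
            scene = nc.simulate_thomas(big_square_roi, 20, 60, 50.0, seed=seed)
            bg = nc.simulate_csr(big_square_roi, len(scene.table) // 10,
                                 seed=1000 + seed)
            xy = np.concatenate([scene.table.coords(), bg.table.coords()])
            df = pd.DataFrame({"id": np.arange(len(xy)), "x": xy[:, 0],
                               "y": xy[:, 1], "channel": "5-LO", "frame": 0})
            table = nc.LocalizationTable(df, ("5-LO", "FLAP"))
            labels = nc.dbscan(table.coords("5-LO"), eps=40.0, min_pts=3)
            clusters = nc.make_clusters(labels, table, "5-LO")
            cents = [table.coords("5-LO")[np.isin(table.ids("5-LO"),
                                                  c.member_ids)].mean(0)
                     for c in clusters]
            for p in scene.parents["ch0"]:
                total += 1
                if cents and min(np.hypot(*(c - p)) for c in cents) <= 100.0:
                    matched += 1
        assert matched / total >= 0.90

    def test_hic_requires_colocalization(self, ring):
        """Matched seeds: full parent sharing yields strictly more HIC than
        independent channels, where HIC are rare."""
        for seed in (3, 4):
            hic = {}
            for frac in (1.0, 0.0):
                scene = nc.simulate_two_channel(ring, seed=seed,
                                                coloc_fraction=frac)
                doc = nc.compute_doc(scene.table)
                n = 0
                for ch in scene.table.channels:
                    n += sum(c.interaction_class == "HIC"
                             for c in nc.cluster_channel(scene.table, doc, ch))
                hic[frac] = n
            assert hic[1.0] > hic[0.0]
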