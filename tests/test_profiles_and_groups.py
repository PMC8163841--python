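"""Composites, heat maps, Reb1 scoring/grouping, +1 distances, densities."""

import numpy as np
import pytest

from nucposlab import profiles_and_groups as pg
from nucposlab.dyad_tracks import DyadTrack, OccupancyTrack
from nucposlab.io_formats import Anchor
from nucposlab.nucleosome_calling import PlusOneAnnotation

L = 5000


def track(values=None):
    return OccupancyTrack({"t1": np.ones(L) if values is None else values})


class TestCompositeProfile:
    def test_constant_track_normalized_flat(self):
        prof = pg.composite_profile(track(), [Anchor("t1", 2500, "+", "a")], 100)
        np.testing.assert_allclose(prof.mean, 1.0)
        assert prof.offsets[0] == -100 and prof.offsets[-1] == 100

    def test_impulse_offset(self):
        values = np.zeros(L)
        values[2510] = 5.0
        prof = pg.composite_profile(
            track(values), [Anchor("t1", 2500, "+", "a")], 100, per_anchor_norm=False
        )
        assert prof.offsets[np.argmax(prof.mean)] == 10

    def test_minus_strand_flips_offset(self):
        values = np.zeros(L)
        values[2510] = 5.0
        prof = pg.composite_profile(
            track(values), [Anchor("t1", 2500, "-", "a")], 100, per_anchor_norm=False
        )
        assert prof.offsets[np.argmax(prof.mean)] == -10

    def test_unnormalized_equals_naive_window_mean(self, rng):
        values = rng.random(L)
        anchors = [
            Anchor("t1", int(p), s, str(i))
            for i, (p, s) in enumerate(
                zip(rng.integers(200, L - 200, 20), rng.choice(["+", "-"], 20))
            )
        ]
        prof = pg.composite_profile(track(values), anchors, 150, per_anchor_norm=False)
        naive = np.zeros(301)
        for a in anchors:
            w = values[a.pos - 150 : a.pos + 151]
            naive += w[::-1] if a.strand == "-" else w
        np.testing.assert_allclose(prof.mean, naive / len(anchors), atol=1e-12)

    def test_zero_mean_window_dropped(self):
        values = np.zeros(L)
        values[3000] = 1.0
        prof = pg.composite_profile(
            track(values),
            [Anchor("t1", 500, "+", "zero"), Anchor("t1", 3000, "+", "ok")],
            50,
        )
        assert prof.n_contributing.max() == 1

    def test_no_survivors_is_error(self):
        with pytest.raises(ValueError):
            pg.composite_profile(track(np.zeros(L)), [Anchor("t1", 2500, "+", "a")], 10)


class TestHeatmap:
    def anchors(self, keys):
        return [
            Anchor("t1", 1000 + 10 * i, "+", gid, {"ndr": k})
            for i, (gid, k) in enumerate(keys.items())
        ]

    def test_descending_key_order(self):
        hm = pg.heatmap_matrix(track(), self.anchors({"g1": 5, "g2": 9}), 50, "ndr")
        assert hm.row_ids == ["g2", "g1"]

    def test_ties_by_id(self):
        hm = pg.heatmap_matrix(track(), self.anchors({"b": 1, "a": 1}), 50, "ndr")
        assert hm.row_ids == ["a", "b"]

    def test_missing_key_drops_anchor(self):
        anchors = self.anchors({"g1": 5}) + [Anchor("t1", 1500, "+", "nokey")]
        hm = pg.heatmap_matrix(track(), anchors, 50, "ndr")
        assert hm.row_ids == ["g1"]


class TestReb1Score:
    def test_uniform_signal(self):
        scores = pg.reb1_score(track(), [Anchor("t1", 1000, "+", "g")], 120, 160)
        assert scores["g"] == 1.0

    def test_plus_strand_window_placement(self):
        values = np.zeros(L)
        values[720:840] = 1.0  # exactly [1000-160-120, 1000-160)
        scores = pg.reb1_score(track(values), [Anchor("t1", 1000, "+", "g")])
        assert scores["g"] == 1.0
        values2 = np.zeros(L)
        values2[719] = values2[840] = 100.0  # just outside
        assert pg.reb1_score(track(values2), [Anchor("t1", 1000, "+", "g")])["g"] == 0.0

    def test_minus_strand_mirror(self):
        values = np.zeros(L)
        values[1161:1281] = 1.0  # mirror window for a minus-strand +1 at 1000
        scores = pg.reb1_score(track(values), [Anchor("t1", 1000, "-", "g")])
        assert scores["g"] == 1.0

    def test_window_outside_contig_dropped(self):
        scores = pg.reb1_score(track(), [Anchor("t1", 100, "+", "g")])
        assert scores == {}

    def test_top_fraction(self):
        scores = {f"g{i}": float(i) for i in range(8)}
        assert pg.top_fraction(scores, 0.125) == {"g7"}


class TestGroupPromoters:
    def setup(self, gene_strand="+", pwm_strand="+", divergent=False):
        genes = [Anchor("t1", 2000, gene_strand, "g1")]
        plus1 = [PlusOneAnnotation("g1", gene_strand, 2060 if gene_strand == "+" else 1940, None)]
        if divergent:
            genes.append(Anchor("t1", 1800, "-", "g2"))
            plus1.append(PlusOneAnnotation("g2", "-", 1740, None))
        hit_pos = 1960 if gene_strand == "+" else 2040
        if divergent:
            hit_pos = 1900
        reb1 = [Anchor("t1", hit_pos, ".", "hit1")]
        pwm = [Anchor("t1", hit_pos + 5, pwm_strand, "pwm1")]
        return reb1, pwm, plus1, genes

    def test_sense_strand_group1(self):
        groups = pg.group_promoters(*self.setup("+", "+"))
        assert groups == {"g1": 1}

    def test_antisense_group2(self):
        groups = pg.group_promoters(*self.setup("+", "-"))
        assert groups == {"g1": 2}

    def test_bidirectional_group3(self):
        groups = pg.group_promoters(*self.setup("+", "+", divergent=True))
        assert groups.get("g1") == 3 and groups.get("g2") == 3

    def test_distant_pwm_not_grouped(self):
        reb1, pwm, plus1, genes = self.setup()
        pwm = [Anchor("t1", pwm[0].pos + 200, "+", "pwm1")]
        assert pg.group_promoters(reb1, pwm, plus1, genes) == {}

    def test_hit_beyond_upstream_limit_not_grouped(self):
        reb1, pwm, plus1, genes = self.setup()
        reb1 = [Anchor("t1", 1500, ".", "hit1")]
        pwm = [Anchor("t1", 1505, "+", "pwm1")]
        assert pg.group_promoters(reb1, pwm, plus1, genes) == {}


class TestPlus1DistanceStats:
    def ann(self, gid, strand, dyad):
        return PlusOneAnnotation(gid, strand, dyad, None)

    def test_identical_annotations(self):
        a = [self.ann("g", "+", 1000)]
        stats = pg.plus1_distance_stats(a, a)
        assert stats.median == 0 and stats.iqr == (0, 0) and stats.n == 1

    def test_sign_convention_plus(self):
        stats = pg.plus1_distance_stats(
            [self.ann("g", "+", 1010)], [self.ann("g", "+", 1000)]
        )
        assert stats.distances["g"] == 10

    def test_sign_convention_minus(self):
        stats = pg.plus1_distance_stats(
            [self.ann("g", "-", 1010)], [self.ann("g", "-", 1000)]
        )
        assert stats.distances["g"] == -10

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError):
            pg.plus1_distance_stats(
                [self.ann("g", "+", None)], [self.ann("g", "+", 1000)]
            )


class TestDyadDensity:
    def dyad_track(self, positions):
        counts = np.zeros(L, dtype=np.int64)
        for p in positions:
            counts[p] += 1
        return DyadTrack({"t1": counts})

    def test_all_dyads_at_anchor(self):
        t = self.dyad_track([2500] * 10)
        centers, density = pg.dyad_density(t, [Anchor("t1", 2500, "+", "a")], 100, 5)
        assert density.sum() * 5 == pytest.approx(1.0)
        assert abs(centers[np.argmax(density)]) <= 5

    def test_depth_invariance(self):
        a = [Anchor("t1", 2500, "+", "a")]
        t1 = self.dyad_track([2400, 2500, 2600])
        t2 = self.dyad_track([2400, 2500, 2600] * 5)
        c1, d1 = pg.dyad_density(t1, a, 200, 5)
        c2, d2 = pg.dyad_density(t2, a, 200, 5)
        np.testing.assert_allclose(d1, d2)

    def test_integrates_to_one(self, rng):
        t = self.dyad_track(rng.integers(2000, 3000, 200).tolist())
        _, density = pg.dyad_density(t, [Anchor("t1", 2500, "+", "a")], 600, 7)
        assert density.sum() * 7 == pytest.approx(1.0, abs=1e-9)

    def test_no_dyads_is_error(self):
        with pytest.raises(ValueError):
            pg.dyad_density(self.dyad_track([]), [Anchor("t1", 2500, "+", "a")], 100)
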