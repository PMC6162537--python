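import math

import numpy as np
import pytest

from laminatlas.imgio import VoxelGrid
from laminatlas.telospots import (
    Spot,
    ac_ratio,
    coloc_fraction,
    detect_spots,
    flag_aggregates,
    telomere_metrics,
)

VS = (0.2, 0.1, 0.1)


def _spot_image(centres_um, shape=(24, 48, 48), sigma=(0.18, 0.11, 0.11),
                amplitude=500.0):
    """Sum of Gaussian spots at physical positions, voxel-centre convention."""
    z, y, x = [np.arange(n) * v for n, v in zip(shape, VS)]
    img = np.zeros(shape)
    for c in centres_um:
        g = (np.exp(-0.5 * ((z - c[0]) / sigma[0]) ** 2)[:, None, None]
             * np.exp(-0.5 * ((y - c[1]) / sigma[1]) ** 2)[None, :, None]
             * np.exp(-0.5 * ((x - c[2]) / sigma[2]) ** 2)[None, None, :])
        img += amplitude * g
    return VoxelGrid(img, VS, "TELO")


def _full_nucleus(shape=(24, 48, 48)):
    return VoxelGrid(np.ones(shape, np.uint8), VS, "MASK")


def _mk(centroid, volume=0.01, label=1, intensity=1.0, agg=False):
    return Spot(centroid=tuple(centroid), total_intensity=intensity,
                volume=volume, label=label, is_aggregate=agg)


class TestDetectSpots:
    def test_single_blob_centroid_within_one_voxel(self):
        centre = (2.4, 2.35, 2.15)
        telo = _spot_image([centre])
        spots, regions = detect_spots(telo, _full_nucleus())
        assert len(spots) == 1
        err = np.abs(np.asarray(spots[0].centroid) - centre)
        assert (err <= np.asarray(VS)).all()

    def test_twenty_well_separated_blobs(self):
        rng = np.random.default_rng(0)
        centres = []
        while len(centres) < 20:
            c = rng.uniform([0.8, 0.8, 0.8], [4.0, 4.0, 4.0])
            if all(np.linalg.norm(c - np.asarray(p)) > 1.0 for p in centres):
                centres.append(c)
        spots, _ = detect_spots(_spot_image(centres), _full_nucleus())
        assert len(spots) == 20

    def test_zero_channel(self):
        telo = VoxelGrid(np.zeros((8, 8, 8)), VS, "TELO")
        nuc = VoxelGrid(np.ones((8, 8, 8), np.uint8), VS, "MASK")
        spots, regions = detect_spots(telo, nuc)
        assert spots == [] and regions.data.max() == 0

    def test_count_invariant_to_global_scaling(self):
        telo = _spot_image([(2.0, 2.0, 2.0), (2.0, 3.5, 3.5)])
        n1 = len(detect_spots(telo, _full_nucleus())[0])
        n2 = len(detect_spots(telo.like(telo.data * 37.0), _full_nucleus())[0])
        assert n1 == n2 == 2

    def test_out_of_nucleus_maxima_discarded(self):
        telo = _spot_image([(2.0, 1.0, 1.0), (2.0, 3.5, 3.5)])
        nuc = np.zeros(telo.shape, np.uint8)
        nuc[:, :24, :24] = 1          # only the first spot is inside
        spots, _ = detect_spots(telo, telo.like(nuc, "MASK"))
        assert len(spots) == 1

    def test_empty_nucleus_rejected(self):
        telo = _spot_image([(2.0, 2.0, 2.0)])
        with pytest.raises(ValueError):
            detect_spots(telo, telo.like(np.zeros(telo.shape, np.uint8), "MASK"))


class TestFlagAggregates:
    def test_near_pair_both_flagged(self):
        spots = [_mk((1.0, 1.0, 1.0)), _mk((1.0, 1.0, 1.1), label=2),
                 _mk((3.0, 3.0, 3.0), label=3)]
        out = flag_aggregates(spots, merge_distance_um=0.2)
        assert [s.is_aggregate for s in out] == [True, True, False]

    def test_isolated_median_spots_unflagged(self):
        spots = [_mk((float(i), 1.0, 1.0), label=i + 1) for i in range(5)]
        assert not any(s.is_aggregate for s in flag_aggregates(spots))

    def test_oversized_region_flagged(self):
        spots = [_mk((float(i), 1.0, 1.0), label=i + 1) for i in range(4)]
        spots.append(_mk((9.0, 1.0, 1.0), volume=0.02, label=5))
        out = flag_aggregates(spots)
        assert [s.is_aggregate for s in out] == [False] * 4 + [True]

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            flag_aggregates([_mk((0, 0, 0))], merge_distance_um=0.0)


class TestAcRatio:
    def test_cube_corners_exactly_one(self):
        pts = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        assert ac_ratio([_mk(p) for p in pts]) == pytest.approx(1.0)

    def test_fewer_than_four_undefined(self):
        assert math.isnan(ac_ratio([_mk((0, 0, 0))] * 3))

    def test_coplanar_undefined(self):
        pts = [(0.0, float(i), float(j)) for i in range(3) for j in range(3)]
        assert math.isnan(ac_ratio([_mk(p) for p in pts]))

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 3))
        base = ac_ratio([_mk(p) for p in pts])
        # random rotation via QR, then uniform scaling
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = 3.7 * pts @ q.T
        assert ac_ratio([_mk(p) for p in moved]) == pytest.approx(base, rel=1e-9)


class TestColocFraction:
    def _setup(self):
        labels = np.zeros((6, 10, 10), np.int32)
        labels[2, 2, 2] = 1
        labels[2, 7, 7] = 2
        regions = VoxelGrid(labels, VS, "MASK")
        internal = np.zeros((6, 10, 10), np.uint8)
        spots = [_mk((0.4, 0.2, 0.2), label=1), _mk((0.4, 0.7, 0.7), label=2)]
        return spots, regions, internal

    def test_all_inside(self):
        spots, regions, internal = self._setup()
        internal[:] = 1
        assert coloc_fraction(spots, regions, regions.like(internal)) == 1.0

    def test_none_inside(self):
        spots, regions, internal = self._setup()
        assert coloc_fraction(spots, regions, regions.like(internal)) == 0.0

    def test_one_voxel_dilation_tolerance(self):
        spots, regions, internal = self._setup()
        internal[2, 3, 3] = 1    # diagonal neighbour of spot 1's region
        assert coloc_fraction(spots, regions, regions.like(internal)) == 0.5

    def test_order_independent(self):
        spots, regions, internal = self._setup()
        internal[2, 2, 2] = 1
        f1 = coloc_fraction(spots, regions, regions.like(internal))
        f2 = coloc_fraction(spots[::-1], regions, regions.like(internal))
        assert f1 == f2

    def test_no_spots_undefined(self):
        _, regions, internal = self._setup()
        assert math.isnan(coloc_fraction([], regions, regions.like(internal)))


class TestTelomereMetrics:
    def test_assembly(self):
        spots = [_mk((0, 0, 0), intensity=10.0),
                 _mk((1, 1, 1), intensity=30.0, agg=True)]
        m = telomere_metrics(spots, nuclear_volume=50.0, coloc=0.5)
        assert m.n_signals == 2 and m.n_aggregates == 1
        assert m.total_intensity == 40.0 and m.mean_intensity == 20.0
        assert m.nuclear_volume == 50.0 and m.coloc_fraction == 0.5
        assert math.isnan(m.ac_ratio)   # only 2 spots

    def test_empty(self):
        m = telomere_metrics([], nuclear_volume=1.0)
        assert m.n_signals == 0 and math.isnan(m.mean_intensity)
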