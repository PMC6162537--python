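import numpy as np
import pytest
from scipy import ndimage

from conftest import ALL_PATTERNS, rendered
from laminatlas.synthgen import (
    CellSpec,
    H_COMPARTMENTS,
    RS_LOBES,
    calibrate_internal_brightness,
    render_cell,
    sample_population,
    spec_for_pattern,
)


class TestSpecValidation:
    def test_coloc_fraction_bounds(self):
        with pytest.raises(ValueError):
            CellSpec(coloc_fraction=1.5)
        with pytest.raises(ValueError):
            CellSpec(aggregate_fraction=-0.1)

    def test_pattern_consistency(self):
        with pytest.raises(ValueError):
            CellSpec(pattern="HB", n_lobes=1, n_compartments=3)
        with pytest.raises(ValueError):
            CellSpec(pattern="RS3", n_lobes=2, n_compartments=2)
        with pytest.raises(ValueError):
            CellSpec(pattern="H0", n_lobes=2, n_compartments=2)

    def test_spec_for_pattern_unknown(self):
        with pytest.raises(ValueError):
            spec_for_pattern("XX")

    def test_spec_for_pattern_counts(self):
        for pat, k in H_COMPARTMENTS.items():
            s = spec_for_pattern(pat)
            assert s.n_lobes == 1 and s.n_compartments == k
        for pat, n in RS_LOBES.items():
            s = spec_for_pattern(pat)
            assert s.n_lobes == n


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = spec_for_pattern("HB", CellSpec(), n_telomeres=10, coloc_fraction=0.4)
        s1, t1 = render_cell(spec, seed=7)
        s2, t2 = render_cell(spec, seed=7)
        for role in s1.channels:
            np.testing.assert_array_equal(s1[role].data, s2[role].data)
        np.testing.assert_array_equal(t1.telomere_centres, t2.telomere_centres)

    def test_different_seeds_differ(self):
        spec = spec_for_pattern("HB")
        s1, _ = render_cell(spec, seed=1)
        s2, _ = render_cell(spec, seed=2)
        assert not np.array_equal(s1["LAMIN"].data, s2["LAMIN"].data)


class TestTruthGeometry:
    @pytest.mark.parametrize("pattern", ALL_PATTERNS)
    def test_truth_counts_and_masks(self, pattern):
        _, truth = rendered(pattern, seed=0)
        spec = truth.spec
        assert truth.n_compartments == spec.n_compartments
        lobes = truth.lobe_labels.data
        assert int(lobes.max()) == spec.n_lobes
        nucleus = truth.nucleus_mask.data.astype(bool)
        shell = truth.shell_mask.data.astype(bool)
        internal = truth.internal_mask.data.astype(bool)
        assert not (shell & internal).any()
        assert (shell | internal).sum() <= nucleus.sum()
        assert ((shell | internal) & ~nucleus).sum() == 0
        # DNA and free space partition the interior exactly
        dna = truth.dna_mask.data.astype(bool)
        free = truth.free_space_mask.data.astype(bool)
        assert not (dna & free).any()

    def test_k_septa_make_k_plus_1_compartments(self):
        # flood fill of the true open interior must agree with the label map
        for pattern in ("HB", "HC", "HD"):
            _, truth = rendered(pattern, seed=1)
            nucleus = truth.nucleus_mask.data.astype(bool)
            lam = truth.shell_mask.data.astype(bool) | truth.internal_mask.data.astype(bool)
            _, n = ndimage.label(nucleus & ~lam, structure=np.ones((3, 3, 3), bool))
            assert n == truth.spec.n_compartments


class TestTelomereTruth:
    def test_centres_in_detection_frame(self):
        stack, truth = rendered("HB", seed=3, n_telomeres=20)
        vs = np.asarray(stack.voxel_size)
        extent = np.asarray(stack.shape) * vs
        assert (truth.telomere_centres >= 0).all()
        assert (truth.telomere_centres <= extent).all()
        # each centre lies inside the true nucleus
        nucleus = truth.nucleus_mask.data.astype(bool)
        idx = np.round(truth.telomere_centres / vs).astype(int)
        assert nucleus[tuple(idx.T)].all()

    def test_coloc_flags_match_geometry(self):
        stack, truth = rendered("HB", seed=4, n_telomeres=30, coloc_fraction=0.5)
        vs = np.asarray(stack.voxel_size)
        internal = truth.internal_mask.data.astype(bool)
        d = ndimage.distance_transform_edt(~internal, sampling=stack.voxel_size)
        vals = d[tuple(np.round(truth.telomere_centres / vs).astype(int).T)]
        on = vals[truth.telomere_coloc]
        off = vals[~truth.telomere_coloc]
        assert on.max() <= 0.2          # on spots sit on internal lamin
        assert off.min() > 1.0          # off spots clear the apparent footprint

    def test_realized_fraction_consistent(self):
        _, truth = rendered("HB", seed=5, n_telomeres=40, coloc_fraction=0.3)
        assert truth.realized_coloc_fraction == pytest.approx(
            truth.telomere_coloc.mean())
        _, truth0 = rendered("H0", seed=5)
        assert np.isnan(truth0.realized_coloc_fraction)

    def test_aggregate_pairs(self):
        _, truth = rendered("H0", seed=6, n_telomeres=40, aggregate_fraction=0.2)
        assert truth.telomere_aggregate.sum() == 8  # 4 snapped pairs
        centres = truth.telomere_centres[truth.telomere_aggregate]
        for a, b in zip(centres[::2], centres[1::2]):
            assert np.linalg.norm(a - b) == pytest.approx(0.15)


class TestPopulationAndCalibration:
    def test_sample_population_reproducible(self):
        freqs = {"H0": 0.5, "HB": 0.5}
        p1 = sample_population(freqs, 4, seed=9)
        p2 = sample_population(freqs, 4, seed=9)
        for (s1, t1), (s2, t2) in zip(p1, p2):
            assert t1.spec.pattern == t2.spec.pattern
            np.testing.assert_array_equal(s1["LAMIN"].data, s2["LAMIN"].data)
        assert {t.spec.pattern for _, t in p1} <= set(freqs)

    def test_sample_population_validates_freqs(self):
        with pytest.raises(ValueError):
            sample_population({}, 3)
        with pytest.raises(ValueError):
            sample_population({"H0": 0.7}, 3)

    def test_calibration_hits_target(self):
        for pattern, target in (("HB", 3.0), ("RS2", 2.5)):
            spec = calibrate_internal_brightness(spec_for_pattern(pattern),
                                                 target, seed=11)
            _, truth = render_cell(
                spec.__class__(**{**spec.__dict__,
                                  "noise_poisson_scale": 0.0,
                                  "noise_gaussian_sd": 0.0}), seed=11)
            assert truth.true_Ie / truth.true_Ii == pytest.approx(target, rel=1e-6)

    def test_calibration_rejects_bad_target(self):
        with pytest.raises(ValueError):
            calibrate_internal_brightness(spec_for_pattern("HB"), 0.0)
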