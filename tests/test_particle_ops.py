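"""Coordinate rescaling, even-box-pair search, extraction and guarded merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryomerge.exceptions import CryomergeError, MergeError
from cryomerge.formats_io import StarTable
from cryomerge.particle_ops import (
    BoxPair,
    ParticleRescaleSpec,
    background_diameter,
    extract_particles,
    find_box_pairs,
    ideal_extract_box,
    merge_datasets,
    rescale_particle_table,
)
from cryomerge.synthetic_fixtures import render_micrograph


class TestRescaleParticleTable:
    def test_coordinates_scale_by_relative_over_target(self, particle_table):
        spec = ParticleRescaleSpec(1.36, 1.28, 1.40)
        out = rescale_particle_table(particle_table, spec)
        assert out["_rlnCoordinateX"].iloc[0] == pytest.approx(1000.0 * 1.28 / 1.40)
        assert out["_rlnCoordinateX"].iloc[0] == pytest.approx(914.286, abs=1e-3)
        assert out["_rlnOriginX"].iloc[0] == pytest.approx(1.5 * 1.28 / 1.40)

    def test_identity_when_relative_equals_target(self, particle_table):
        spec = ParticleRescaleSpec(1.36, 1.40, 1.40)
        out = rescale_particle_table(particle_table, spec)
        np.testing.assert_allclose(
            out["_rlnCoordinateX"], particle_table["_rlnCoordinateX"]
        )

    def test_implied_apix_becomes_target(self, particle_table):
        out = rescale_particle_table(particle_table, ParticleRescaleSpec(1.36, 1.28, 1.40))
        assert out.implied_apix() == pytest.approx(1.40)

    def test_micrograph_path_rewritten(self, particle_table):
        spec = ParticleRescaleSpec(1.36, 1.28, 1.40, new_micrograph_path="MRCS_ds2/")
        out = rescale_particle_table(particle_table, spec)
        assert out["_rlnMicrographName"].iloc[0] == "MRCS_ds2/mic1.mrc"

    def test_missing_coordinates_rejected(self, ctf_table):
        with pytest.raises(MergeError, match="_rlnCoordinate"):
            rescale_particle_table(ctf_table, ParticleRescaleSpec(1.36, 1.28, 1.40))


class TestFindBoxPairs:
    def test_published_search_finds_560_440(self):
        (pair,) = find_box_pairs(420, 600, 0.880, 1.120, 1)
        assert (pair.extract_box, pair.scaled_box) == (560, 440)
        assert pair.achieved_ratio == pytest.approx(0.78571, abs=5e-6)
        assert pair.error_percent == pytest.approx(0.0, abs=1e-9)

    def test_equal_pixel_sizes_give_smallest_identity_pair(self):
        (pair,) = find_box_pairs(100, 200, 1.0, 1.0, 1)
        assert (pair.extract_box, pair.scaled_box) == (100, 100)
        assert pair.error_percent == 0.0

    def test_matches_exhaustive_enumeration_oracle(self):
        # brute force over every even pair in range, ranked the same way
        min_box, max_box, start, target = 64, 120, 1.0, 1.37
        desired = start / target
        best = min(
            (
                (abs(s / e - desired) / desired, e, s)
                for e in range(min_box, max_box + 1, 2)
                for s in range(min_box, max_box + 1, 2)
            ),
        )
        (pair,) = find_box_pairs(min_box, max_box, start, target, 1)
        assert (pair.extract_box, pair.scaled_box) == (best[1], best[2])

    def test_two_to_one_downscale_within_range(self):
        (pair,) = find_box_pairs(100, 200, 1.0, 2.0, 1)
        assert (pair.extract_box, pair.scaled_box) == (200, 100)
        assert pair.error_percent == 0.0

    def test_n_answers_sorted_by_error(self):
        pairs = find_box_pairs(420, 600, 0.880, 1.120, 5)
        errors = [p.error_percent for p in pairs]
        assert errors == sorted(errors)
        assert len(pairs) == 5

    @settings(max_examples=30, derandomize=True)
    @given(
        start=st.floats(0.7, 1.5),
        target=st.floats(0.7, 1.5),
    )
    def test_never_worse_than_naive_nearest_even_pair(self, start, target):
        min_box, max_box = 100, 200
        (pair,) = find_box_pairs(min_box, max_box, start, target, 1)
        desired = start / target
        naive_scaled = min(max(round(min_box * desired / 2) * 2, min_box), max_box)
        naive_err = abs(naive_scaled / min_box - desired) / desired
        assert pair.error_percent <= 100 * naive_err + 1e-12

    def test_empty_range_rejected(self):
        with pytest.raises(CryomergeError):
            find_box_pairs(101, 101, 1.0, 2.0, 1)


class TestBoxArithmetic:
    def test_ideal_extract_box_is_fractional(self):
        assert ideal_extract_box(420, 1.120, 0.880) == pytest.approx(534.5, abs=0.05)

    def test_background_diameter_published_case(self):
        assert background_diameter(420, 1.120, 0.880) == 400

    def test_background_diameter_same_apix(self):
        assert background_diameter(400, 1.0, 1.0) == 300  # 0.75 * 400

    def test_background_diameter_full_fraction_floors(self):
        assert background_diameter(420, 1.120, 0.880, fraction=1.0) == 534


class TestExtractParticles:
    def _micrograph(self, noise_sd=0.05, seed=0):
        coords = [(64.0, 64.0), (160.0, 96.0), (96.0, 160.0)]
        mic, table = render_micrograph(
            [(3.0, 10.0)], (224, 224), 0.880, coords, noise_sd=noise_sd, seed=seed
        )
        return mic, coords

    def test_peak_lands_at_box_center(self):
        mic, coords = self._micrograph()
        stack, table = extract_particles(mic, coords, 48, 48, bg_diameter=36)
        for i in range(stack.n_images):
            peak = np.unravel_index(np.argmax(stack.data[i]), stack.data[i].shape)
            assert abs(peak[0] - 24) <= 1 and abs(peak[1] - 24) <= 1

    def test_background_normalized_to_zero_mean_unit_sd(self):
        mic, coords = self._micrograph()
        stack, _ = extract_particles(mic, coords, 48, 48, bg_diameter=36)
        ys = np.arange(48)[:, None] - 24
        xs = np.arange(48)[None, :] - 24
        outside = np.hypot(ys, xs) > 18
        for i in range(stack.n_images):
            bg = stack.data[i][outside].astype(np.float64)
            assert abs(bg.mean()) < 1e-6
            assert abs(bg.std() - 1.0) < 1e-6

    def test_rescaled_output_has_scaled_apix(self):
        mic, coords = self._micrograph()
        stack, _ = extract_particles(mic, coords, 56, 44, bg_diameter=40)
        assert stack.apix == pytest.approx(0.880 * 56 / 44)
        assert stack.data.shape[1:] == (44, 44)

    def test_edge_particles_skipped(self):
        mic, _ = self._micrograph()
        stack, table = extract_particles(
            mic, [(5.0, 5.0), (112.0, 112.0)], 48, 48, bg_diameter=36
        )
        assert stack.n_images == 1
        assert len(table) == 1

    def test_subpixel_residual_stored(self):
        mic, _ = self._micrograph()
        _, table = extract_particles(mic, [(100.4, 99.7)], 48, 48, bg_diameter=36)
        assert table["_rlnOriginX"].iloc[0] == pytest.approx(0.4, abs=1e-6)
        assert table["_rlnOriginY"].iloc[0] == pytest.approx(-0.3, abs=1e-6)

    def test_contrast_inversion(self):
        mic, coords = self._micrograph()
        pos, _ = extract_particles(mic, coords, 48, 48, 36, invert_contrast=False)
        neg, _ = extract_particles(mic, coords, 48, 48, 36, invert_contrast=True)
        np.testing.assert_allclose(neg.data, -pos.data, atol=1e-6)


def _harmonized_table(apix: float, n: int = 3) -> StarTable:
    return StarTable.from_columns(
        {
            "_rlnMicrographName": ["m.mrc"] * n,
            "_rlnCoordinateX": [100.0 * i for i in range(n)],
            "_rlnCoordinateY": [50.0 * i for i in range(n)],
            "_rlnMagnification": [10000.0] * n,
            "_rlnDetectorPixelSize": [apix] * n,
        }
    )


class TestMergeDatasets:
    def test_harmonized_tables_merge(self):
        merged = merge_datasets(_harmonized_table(1.120), _harmonized_table(1.120))
        assert len(merged) == 6

    def test_same_table_twice_doubles_rows(self):
        t = _harmonized_table(1.120, n=4)
        assert len(merge_datasets(t, t)) == 8

    def test_mismatched_scales_refused_citing_both(self):
        with pytest.raises(MergeError) as err:
            merge_datasets(
                _harmonized_table(1.120), _harmonized_table(1.125), tolerance=0.001
            )
        assert "1.12" in str(err.value) and "1.125" in str(err.value)

    def test_within_tolerance_allowed(self):
        merged = merge_datasets(
            _harmonized_table(1.120), _harmonized_table(1.119), tolerance=0.002
        )
        assert len(merged) == 6
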