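import numpy as np
import pandas as pd
import pytest

from ctcdetect import (
    CellSpec,
    DetectionParams,
    SyntheticSceneSpec,
    generate_benchmark,
    generate_scene,
    process_image,
    random_scene_spec,
)
from ctcdetect.synthetic_data import DEFAULT_MIX, sample_cells, sample_kinds

from conftest import two_cell_scene
from oracles import disc_pixel_count


class TestGenerateScene:
    def test_empty_scene_is_background_plus_hole_lattice(self):
        spec = SyntheticSceneSpec(height=200, width=200, cells=[], noise_sd=0.0, seed=1)
        image, truth = generate_scene(spec)
        assert truth.empty
        values = set(np.unique(image.blue))
        assert values == {spec.hole_level, spec.background_level}
        # hole at the lattice origin (spacing/2, spacing/2)
        assert image.blue[90, 90] == spec.hole_level
        np.testing.assert_array_equal(image.blue, image.green)
        np.testing.assert_array_equal(image.blue, image.red)

    def test_planted_kr_is_the_disc_pixel_count_ratio(self):
        cell = CellSpec(
            center=(60, 60),
            nucleus_radius=20,
            cell_radius=22,
            kind="CTC",
            blue_intensity=200,
            green_intensity=160,
            red_intensity=0,
        )
        spec = SyntheticSceneSpec(height=120, width=120, cells=[cell], noise_sd=0.0, seed=1)
        _, truth = generate_scene(spec)
        expected = disc_pixel_count(20) / disc_pixel_count(22)
        assert truth.loc[0, "planted_kr"] == pytest.approx(expected)
        assert expected == pytest.approx(0.83, abs=0.01)

    def test_same_spec_same_seed_is_bit_identical(self):
        spec = two_cell_scene(noise_sd=4.0)
        a, _ = generate_scene(spec)
        b, _ = generate_scene(spec)
        np.testing.assert_array_equal(a.blue, b.blue)
        np.testing.assert_array_equal(a.green, b.green)
        np.testing.assert_array_equal(a.red, b.red)

    def test_overlapping_cells_are_flagged(self):
        mk = lambda r, c: CellSpec(
            center=(r, c),
            nucleus_radius=10,
            cell_radius=12,
            kind="CTC",
            blue_intensity=200,
            green_intensity=160,
            red_intensity=0,
        )
        spec = SyntheticSceneSpec(
            height=100, width=100, cells=[mk(50, 40), mk(50, 55)], noise_sd=0.0, seed=1
        )
        _, truth = generate_scene(spec)
        assert truth["overlaps"].all()

    def test_out_of_bounds_cell_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SyntheticSceneSpec(
                height=50,
                width=50,
                cells=[
                    CellSpec(
                        center=(5, 5),
                        nucleus_radius=10,
                        cell_radius=12,
                        kind="CTC",
                        blue_intensity=200,
                        green_intensity=160,
                        red_intensity=0,
                    )
                ],
            )


class TestPopulationSampling:
    def test_kind_frequencies_follow_the_mix(self, rng):
        kinds = sample_kinds(rng, 2000, DEFAULT_MIX)
        ctc_like = sum(k in ("CTC", "small_CTC") for k in kinds)
        # prevalence 0.24; binomial sd over 2000 draws ~ 19
        assert ctc_like == pytest.approx(0.24 * 2000, abs=5 * 19)

    def test_invalid_mix_rejected(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            sample_kinds(rng, 10, {"CTC": 0.5, "leukocyte": 0.2})

    def test_sampled_cells_respect_kind_regimes(self, rng):
        cells = sample_cells(rng, 1200, 1600, 30)
        assert cells
        for cell in cells:
            planted = disc_pixel_count(cell.nucleus_radius) / disc_pixel_count(
                cell.cell_radius
            )
            if cell.kind in ("CTC", "small_CTC"):
                assert cell.green_intensity > 0 and cell.red_intensity == 0
                assert planted > 0.7
            elif cell.kind == "leukocyte":
                assert cell.red_intensity > 0 and cell.green_intensity == 0
                assert 0.35 <= planted <= 0.55
            if cell.kind == "small_CTC":
                assert 2 * cell.cell_radius + 1 <= 51  # below normal cell size
            if cell.kind != "debris":
                # nucleus passes the lower size gate
                assert 2 * cell.nucleus_radius + 1 > 46

    def test_debris_never_becomes_a_candidate(self):
        spec = random_scene_spec(
            5, n_cells=4, mix={"debris": 0.5, "leukocyte": 0.5}, noise_sd=0.0
        )
        assert any(c.kind == "debris" for c in spec.cells)
        image, truth = generate_scene(spec)
        measurements = process_image(image, DetectionParams())
        debris = truth[truth["kind"] == "debris"]
        for m in measurements:
            for _, row in debris.iterrows():
                assert not (
                    row.row0 <= m.bbox.center[0] < row.row1
                    and row.col0 <= m.bbox.center[1] < row.col1
                )


class TestNoiseDegradation:
    @staticmethod
    def _recovery(noise_sd):
        """Fraction of planted CTCs recovered over three fixed scenes."""
        from ctcdetect import generate_scene, match_boxes
        from ctcdetect.geometry import BoundingBox
        import dataclasses

        found = total = 0
        for i in range(3):
            spec = dataclasses.replace(
                random_scene_spec(400 + i, n_cells=8, source_id=f"n{i}"),
                noise_sd=noise_sd,
            )
            image, truth = generate_scene(spec)
            ms = process_image(image, DetectionParams())
            tb = [
                BoundingBox(int(r.row0), int(r.col0), int(r.row1), int(r.col1))
                for r in truth.itertuples()
            ]
            pairs = {ti: pi for pi, ti in match_boxes([m.bbox for m in ms], tb)}
            for ti, row in truth.iterrows():
                if row.label == "CTC":
                    total += 1
                    found += ti in pairs and ms[pairs[ti]].label == "CTC"
        return found / total if total else 1.0

    def test_sensitivity_does_not_improve_with_noise(self):
        quiet = self._recovery(noise_sd=3.0)
        loud = self._recovery(noise_sd=45.0)
        assert quiet == 1.0
        assert loud <= quiet


class TestBenchmark:
    def test_benchmark_layout_and_determinism(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        truth_a = generate_benchmark(a, 2, seed=5, cells_per_scene=4, height=500, width=640)
        truth_b = generate_benchmark(b, 2, seed=5, cells_per_scene=4, height=500, width=640)
        for d in (a, b):
            assert (d / "scene_000.png").exists()
            assert (d / "scene_001.png").exists()
            assert (d / "truth.csv").exists()
            assert (d / "benchmark_spec.json").exists()
        pd.testing.assert_frame_equal(truth_a, truth_b)
        assert (a / "scene_000.png").read_bytes() == (b / "scene_000.png").read_bytes()
        assert truth_a["source_id"].nunique() == 2

    def test_zero_scenes_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="n_scenes"):
            generate_benchmark(tmp_path, 0, seed=1)
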