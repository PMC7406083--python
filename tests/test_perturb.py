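"""Feature-reliance probes: region noise contracts, occlusion-importance
formula identities, region averaging, correct-trial filtering, heatmaps."""

import numpy as np
import pytest

from depthseg import (GRAY_FILL, ImportanceMap, add_region_noise, evaluate,
                      filter_correct, layer_heatmap, make_object,
                      compose_scene, occlusion_sweep, region_importance)
from depthseg.perturb import grid_positions
from depthseg.scenegen import Scene


def _gray_scene(H=16, category=0):
    mask = np.zeros((H, H), dtype=bool)
    mask[4:8, 4:8] = True
    return Scene(pixels=np.full((H, H, 3), 0.5), mask=mask, category=category,
                 condition="congruent", location=0, exemplar_id=0, background_id=0)


# ---------------------------------------------------------------------------
# region noise
# ---------------------------------------------------------------------------

class TestRegionNoise:
    def test_zero_sigma_is_identity(self, tiny_set):
        sc = tiny_set.scenes[0]
        out = add_region_noise(sc, "object", 0.0, 1)
        assert np.array_equal(out.pixels, sc.pixels)

    @pytest.mark.parametrize("region,untouched", [("object", False), ("background", True)])
    def test_complement_region_untouched(self, tiny_set, region, untouched):
        sc = tiny_set.scenes[1]
        out = add_region_noise(sc, region, 0.4, 3)
        comp = sc.mask if untouched else ~sc.mask
        assert np.array_equal(out.pixels[comp], sc.pixels[comp])
        assert not np.array_equal(out.pixels[~comp], sc.pixels[~comp])
        assert np.array_equal(out.mask, sc.mask)
        assert out.condition == sc.condition

    def test_both_equals_composition_with_shared_seed(self, tiny_set):
        sc = tiny_set.scenes[2]
        both = add_region_noise(sc, "both", 0.3, 9)
        obj = add_region_noise(sc, "object", 0.3, 9)
        bg = add_region_noise(sc, "background", 0.3, 9)
        composed = np.where(sc.mask[..., None], obj.pixels, bg.pixels)
        assert np.array_equal(both.pixels, composed)

    def test_output_clipped(self, tiny_set):
        out = add_region_noise(tiny_set.scenes[0], "both", 5.0, 0)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_unknown_region_rejected(self, tiny_set):
        with pytest.raises(ValueError, match="region"):
            add_region_noise(tiny_set.scenes[0], "edges", 0.1, 0)

    def test_negative_sigma_rejected(self, tiny_set):
        with pytest.raises(ValueError, match="sigma"):
            add_region_noise(tiny_set.scenes[0], "object", -1.0, 0)


# ---------------------------------------------------------------------------
# occlusion sweep
# ---------------------------------------------------------------------------

class TestOcclusionSweep:
    def test_grid_shape_formula(self):
        _, shape = grid_positions(512, 512, 128, 32)
        assert shape == (13, 13)
        positions, shape2 = grid_positions(16, 16, 4, 2)
        assert shape2 == (7, 7)
        assert len(positions) == 49
        # every placement fully inside
        assert all(r + 4 <= 16 and c + 4 <= 16 for r, c in positions)

    def test_pixel_ignoring_model_gives_zero_grid(self, stub_model_factory):
        model = stub_model_factory(3, lambda img: np.array([2.0, 1.0, 0.5]))
        imap = occlusion_sweep(model, _gray_scene(), patch=4, stride=2)
        assert imap.defined
        assert np.all(imap.grid == 0.0)
        assert np.all(imap.pixel_map == 0.0)

    def test_whole_image_occluder_closed_form(self, stub_model_factory):
        """With patch = H there is a single placement; a model whose score
        halves under full occlusion must yield importance exactly 0.5."""
        def score(img):
            # gray fill (0.5) gives mean 0.5 -> score 1; original scene below
            # is built so its mean is 1.0 -> score 2
            return np.array([4.0 * img.mean(), 0.0])
        sc = _gray_scene()
        sc.pixels[:] = 1.0
        model = stub_model_factory(2, score)
        imap = occlusion_sweep(model, sc, patch=16, stride=16)
        assert imap.grid.shape == (1, 1)
        assert imap.grid[0, 0] == pytest.approx(0.5)

    def test_occluder_matching_content_is_exactly_zero(self, trained_tiny_model):
        """A uniformly fill-colored scene is unchanged by occlusion, so every
        grid value is exactly 0 (not merely close)."""
        sc = _gray_scene()
        orig = trained_tiny_model.class_scores(sc.pixels)[sc.category]
        assume = orig != 0  # generic for a trained net
        assert assume
        imap = occlusion_sweep(trained_tiny_model, sc, patch=4, stride=4, fill=GRAY_FILL)
        assert np.all(imap.grid == 0.0)

    def test_zero_original_score_flagged_not_divided(self, stub_model_factory):
        model = stub_model_factory(2, lambda img: np.zeros(2))
        imap = occlusion_sweep(model, _gray_scene(), patch=4, stride=4)
        assert not imap.defined
        assert np.all(np.isnan(imap.grid))

    def test_sweep_deterministic(self, trained_tiny_model, tiny_set):
        sc = tiny_set.scenes[0]
        a = occlusion_sweep(trained_tiny_model, sc, 4, 2)
        b = occlusion_sweep(trained_tiny_model, sc, 4, 2)
        assert np.array_equal(a.grid, b.grid)
        assert np.array_equal(a.pixel_map, b.pixel_map)

    def test_oversized_patch_rejected(self, trained_tiny_model):
        with pytest.raises(ValueError, match="patch"):
            occlusion_sweep(trained_tiny_model, _gray_scene(), patch=32, stride=2)


# ---------------------------------------------------------------------------
# region importance
# ---------------------------------------------------------------------------

def _map_from(pixel_map, original_score=2.0):
    return ImportanceMap(grid=np.zeros((1, 1)), patch=2, stride=2, fill=GRAY_FILL,
                         original_score=original_score,
                         pixel_map=np.asarray(pixel_map, dtype=float), defined=True)


class TestRegionImportance:
    def test_uniform_map_gives_equal_regions(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :2] = True
        ri = region_importance(_map_from(np.full((4, 4), 0.3)), mask)
        assert ri.object_importance == pytest.approx(ri.background_importance)
        assert ri.object_importance == pytest.approx(0.3)

    def test_object_only_signal_gives_zero_background(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        pm = np.where(mask, 0.8, 0.0)
        ri = region_importance(_map_from(pm), mask)
        assert ri.background_importance == 0.0
        assert ri.object_importance == pytest.approx(0.8)

    def test_hand_arithmetic_on_4x4_map(self):
        pm = np.arange(16, dtype=float).reshape(4, 4) / 10.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0:2, 0:2] = True  # values 0.0, 0.1, 0.4, 0.5 -> mean 0.25
        ri = region_importance(_map_from(pm), mask)
        assert ri.object_importance == pytest.approx(0.25)
        # background: remaining 12 values sum to 12.0 - 1.0 -> mean 11/12... by hand:
        bg_mean = (pm.sum() - 1.0) / 12.0
        assert ri.background_importance == pytest.approx(bg_mean)
        assert ri.n_object_pixels == 4
        assert ri.n_background_pixels == 12

    def test_empty_region_flagged(self):
        mask = np.ones((4, 4), dtype=bool)
        ri = region_importance(_map_from(np.full((4, 4), 0.1)), mask)
        assert not ri.background_defined
        assert np.isnan(ri.background_importance)

    def test_undefined_map_rejected(self):
        imap = _map_from(np.zeros((4, 4)))
        imap.defined = False
        with pytest.raises(ValueError, match="undefined"):
            region_importance(imap, np.zeros((4, 4), dtype=bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            region_importance(_map_from(np.zeros((4, 4))), np.zeros((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# correct-trial filtering and heatmaps
# ---------------------------------------------------------------------------

class TestFilterCorrect:
    def test_always_correct_model_keeps_everything(self, tiny_set, tiny_gen, stub_model_factory):
        model = stub_model_factory(tiny_gen.K, lambda img: np.arange(tiny_gen.K, dtype=float))
        subset, counts = filter_correct(tiny_set.scenes, model, top_k=tiny_gen.K)
        assert len(subset) == len(tiny_set.scenes)
        assert sum(counts.values()) == len(tiny_set.scenes)

    def test_always_wrong_model_warns_and_empties(self, tiny_set, tiny_gen, stub_model_factory):
        # stable argsort ranks class 0 first on ties; scenes of category 0
        # would count as correct, so exclude them
        scenes = [sc for sc in tiny_set.scenes if sc.category != 0]
        model = stub_model_factory(tiny_gen.K,
                                   lambda img: np.array([1.0] + [0.0] * (tiny_gen.K - 1)))
        with pytest.warns(UserWarning, match="no correctly classified"):
            subset, counts = filter_correct(scenes, model, top_k=1)
        assert subset == []

    def test_agrees_with_evaluate_records(self, trained_tiny_model, tiny_set):
        subset, _ = filter_correct(tiny_set.scenes, trained_tiny_model, top_k=1)
        res = evaluate(trained_tiny_model, tiny_set, top_k=1)
        assert len(subset) == int(res.records.correct.sum())


class TestLayerHeatmap:
    def test_nonnegative_everywhere(self, trained_tiny_model, tiny_set):
        hm = layer_heatmap(trained_tiny_model, tiny_set.scenes[0], "stem")
        assert hm.ndim == 2
        assert np.all(hm >= 0.0)

    def test_single_filter_layer_equals_absolute_activation(self, tiny_gen):
        from depthseg import ModelSpec, build_model
        m = build_model(ModelSpec(1, False, 0, 1, 2, tiny_gen.image_size), 0)
        sp = make_object(0, 0, tiny_gen)
        sc = compose_scene(sp, None, 0, tiny_gen.image_size)
        acts = m.layer_activations(sc.pixels, "stem")
        assert acts.shape[0] == 1
        hm = layer_heatmap(m, sc, "stem")
        assert np.array_equal(hm, np.abs(acts[0]))

    def test_unknown_layer_lists_valid_names(self, trained_tiny_model, tiny_set):
        with pytest.raises(ValueError, match="valid layers"):
            layer_heatmap(trained_tiny_model, tiny_set.scenes[0], "block99")


def test_save_importance_map_writes_grid_and_overlay(trained_tiny_model, tiny_set, tmp_path):
    from depthseg.perturb import save_importance_map
    sc = tiny_set.scenes[0]
    imap = occlusion_sweep(trained_tiny_model, sc, 4, 2)
    save_importance_map(imap, sc, tmp_path / "m")
    grid = np.loadtxt(tmp_path / "m_grid.csv", delimiter=",")
    assert grid.shape == imap.grid.shape
    assert np.allclose(grid, imap.grid, atol=1e-5)
    assert (tmp_path / "m_overlay.png").exists()
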