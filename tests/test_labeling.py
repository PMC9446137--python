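import json

import numpy as np
import pytest

import woundlabel as wl
from woundlabel.errors import (
    CompletenessError,
    ConfigurationError,
    DomainError,
    ScriptError,
)

from conftest import random_raster
from oracles import bfs_flood_fill


@pytest.fixture
def session(rng):
    return wl.new_session(random_raster(rng, 12, 12))


class TestPalette:
    def test_default_palette_legend(self):
        p = wl.TissuePalette.default()
        assert [c.name for c in p.classes] == [
            "background", "intact_skin", "granulation", "slough", "necrotic",
        ]
        assert p.color_of(p.resolve("intact_skin")) == (0, 255, 0)
        assert p.color_of(p.resolve("slough")) == (255, 255, 0)
        assert p.color_of(p.resolve("granulation")) == (255, 0, 0)
        assert p.color_of(p.resolve("background")) == (0, 0, 255)
        assert p.color_of(p.resolve("necrotic")) == (0, 0, 0)

    def test_editor_preset_marks_intact_skin_blue(self):
        p = wl.TissuePalette.editor_preset()
        assert p.color_of(p.resolve("intact_skin")) == (0, 0, 255)

    def test_json_round_trip(self):
        p = wl.TissuePalette.default()
        assert wl.TissuePalette.from_json(p.to_json()) == p

    def test_invalid_palettes_rejected(self):
        with pytest.raises(ConfigurationError):
            wl.TissuePalette([])
        with pytest.raises(ConfigurationError):
            wl.TissuePalette(
                [wl.TissueClass(2, "a", (0, 0, 0))]  # ids must start at 1
            )
        with pytest.raises(ConfigurationError):
            wl.TissuePalette(
                [wl.TissueClass(1, "a", (0, 0, 0)), wl.TissueClass(2, "a", (1, 1, 1))]
            )

    def test_resolve_rejects_unknown(self):
        p = wl.TissuePalette.default()
        with pytest.raises(DomainError):
            p.resolve("bone")
        with pytest.raises(DomainError):
            p.resolve(9)


class TestSession:
    def test_new_session_starts_unlabeled(self, session):
        assert session.mask.unlabeled_count() == 12 * 12
        assert session.active_region == wl.Rect.full(12, 12)

    def test_propose_caches_identical_calls(self, session):
        p = wl.SlicParams(n_segments=4)
        a = wl.propose(session, "slic", p)
        b = wl.propose(session, "slic", p)
        assert a is b
        assert len(session.proposals) == 2  # both calls indexable by scripts

    def test_distinct_params_give_distinct_proposals(self, session):
        a = wl.propose(session, "slic", wl.SlicParams(n_segments=4))
        b = wl.propose(session, "slic", wl.SlicParams(n_segments=9))
        assert a is not b and a.n_segments != b.n_segments

    def test_region_proposal_has_region_dimensions(self, session):
        session.set_region(wl.Rect(0, 0, 12, 6))
        sp = wl.propose(session, "felzenszwalb", wl.FelzParams(min_size=1))
        assert (sp.height, sp.width) == (12, 6)

    def test_gamma_mutates_working_image_and_invalidates_cache(self, rng):
        s = wl.new_session(wl.RasterImage(rng.uniform(0.2, 0.8, (8, 8, 3))))
        before = s.image.data.copy()
        a = wl.propose(s, "slic", wl.SlicParams(n_segments=4))
        s.set_gamma(0.5)
        assert (s.image.data > before).all()
        b = wl.propose(s, "slic", wl.SlicParams(n_segments=4))
        assert a is not b

    def test_unknown_algorithm_and_wrong_params(self, session):
        with pytest.raises(DomainError):
            wl.propose(session, "watershed")
        with pytest.raises(DomainError):
            wl.propose(session, "slic", wl.FelzParams())


class TestSelectSegment:
    def test_select_writes_whole_segment(self, rng):
        img = wl.RasterImage(np.full((10, 10, 3), 0.5))
        s = wl.new_session(img)
        sp = wl.propose(s, "felzenszwalb", wl.FelzParams(min_size=1))
        n = wl.select_segment(s, sp, 0, "granulation")
        assert n == 100
        assert (s.mask.labels == 3).all()

    def test_last_selection_wins(self, rng):
        img = wl.RasterImage(np.full((6, 6, 3), 0.5))
        s = wl.new_session(img)
        sp = wl.propose(s, "felzenszwalb", wl.FelzParams(min_size=1))
        wl.select_segment(s, sp, 0, 1)
        wl.select_segment(s, sp, 0, 2)
        assert (s.mask.labels == 2).all()

    def test_region_offset_bookkeeping(self, rng):
        img = wl.RasterImage(np.full((12, 12, 3), 0.5))
        s = wl.new_session(img)
        s.set_region(wl.Rect(5, 2, 10, 9))
        sp = wl.propose(s, "felzenszwalb", wl.FelzParams(min_size=1))
        n = wl.select_segment(s, sp, 0, "slough")
        assert n == 5 * 7
        expect = np.zeros((12, 12), dtype=int)
        expect[5:10, 2:9] = 4
        assert np.array_equal(s.mask.labels, expect)

    def test_unknown_segment_or_class(self, session):
        sp = wl.propose(session, "slic", wl.SlicParams(n_segments=4))
        with pytest.raises(DomainError):
            wl.select_segment(session, sp, sp.n_segments, 1)
        with pytest.raises(DomainError):
            wl.select_segment(session, sp, 0, 77)


class TestBrush:
    def test_radius_zero_paints_one_pixel(self, session):
        assert wl.brush(session, (5, 5), 0, 1) == 1
        assert session.mask.labels[5, 5] == 1
        assert session.mask.unlabeled_count() == 143

    def test_radius_covering_diagonals(self, session):
        # d <= 1.5 on the integer grid: center, 4-neighbors, 4 diagonals
        assert wl.brush(session, (6, 6), 1.5, 2) == 9

    def test_corner_clipping(self, session):
        assert wl.brush(session, (0, 0), 1, 3) == 3

    def test_bad_inputs(self, session):
        with pytest.raises(DomainError):
            wl.brush(session, (99, 0), 1, 1)
        with pytest.raises(DomainError):
            wl.brush(session, (0, 0), 1, 42)


class TestMagicWand:
    def test_tolerance_zero_with_distinct_neighbors(self):
        data = np.zeros((3, 3, 3))
        data[1, 1] = 0.5
        s = wl.new_session(wl.RasterImage(data))
        assert wl.magic_wand(s, (1, 1), 0.0, 1) == 1

    def test_constant_image_floods_everything(self, rng):
        s = wl.new_session(wl.RasterImage(np.full((7, 9, 3), 0.3)))
        assert wl.magic_wand(s, (3, 4), 0.01, 5) == 63
        assert (s.mask.labels == 5).all()

    def test_connected_component_of_similar_grays(self):
        g = np.array(
            [[10, 10, 200, 200], [10, 10, 200, 200], [10, 200, 200, 200], [10, 10, 10, 200]]
        ) / 255.0
        s = wl.new_session(wl.RasterImage(np.dstack([g, g, g])))
        n = wl.magic_wand(s, (0, 0), 0.1, 1)
        assert n == 8
        expect = (g < 0.5).astype(int)
        expect[2, 1:] = 0  # (2,1..3) are bright; only the seed's component
        assert np.array_equal(s.mask.labels, (np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0]]
        )))

    def test_matches_bfs_reference(self, rng):
        for _ in range(10):
            img = wl.RasterImage(rng.integers(0, 4, size=(9, 9, 3)) / 3.0)
            s = wl.new_session(img)
            seed = (int(rng.integers(9)), int(rng.integers(9)))
            tol = float(rng.uniform(0, 0.8))
            wl.magic_wand(s, seed, tol, 1)
            ref = bfs_flood_fill(img.data, seed, tol)
            got = set(zip(*np.nonzero(s.mask.labels == 1)))
            assert got == ref

    def test_out_of_bounds_seed(self, session):
        with pytest.raises(DomainError):
            wl.magic_wand(session, (50, 0), 0.1, 1)


class TestScripts:
    def test_empty_script_leaves_mask_unlabeled(self, rng):
        mask, saved = wl.run_script(random_raster(rng, 5, 5), wl.SessionScript([]))
        assert mask.unlabeled_count() == 25 and saved == []

    def test_propose_and_select_via_script(self):
        img = wl.RasterImage(np.full((6, 6, 3), 0.5))
        script = wl.SessionScript([
            {"op": "propose", "algorithm": "felzenszwalb", "min_size": 1},
            {"op": "select", "proposal": 0, "segment": 0, "class": "background"},
        ])
        mask, _ = wl.run_script(img, script)
        assert (mask.labels == 1).all()

    def test_replay_is_bit_identical_including_files(self, rng, tmp_path):
        img = random_raster(rng, 16, 16)
        script = wl.SessionScript([
            {"op": "set_gamma", "gamma": 0.8},
            {"op": "propose", "algorithm": "slic", "n_segments": 6},
            {"op": "select", "proposal": 0, "segment": 0, "class": "granulation"},
            {"op": "brush", "row": 8, "col": 8, "radius": 3, "class": "necrotic"},
            {"op": "wand", "row": 0, "col": 0, "tolerance": 0.4, "class": "slough"},
            {"op": "save", "stem": str(tmp_path / "a"), "allow_unlabeled": True},
        ])
        mask1, _ = wl.run_script(img, script)
        bytes1 = (tmp_path / "a_label.png").read_bytes()
        script.actions[-1]["stem"] = str(tmp_path / "b")
        mask2, _ = wl.run_script(img, script)
        bytes2 = (tmp_path / "b_label.png").read_bytes()
        assert mask1 == mask2
        assert bytes1 == bytes2

    def test_script_round_trips_through_json(self):
        script = wl.SessionScript([
            {"op": "propose", "algorithm": "kmeans", "n_clusters": 3, "seed": 1},
        ])
        again = wl.SessionScript.from_json(script.to_json())
        assert again.actions == script.actions

    def test_first_invalid_action_reports_its_index(self, rng):
        script = wl.SessionScript([
            {"op": "propose", "algorithm": "slic", "n_segments": 4},
            {"op": "select", "proposal": 5, "segment": 0, "class": 1},
        ])
        with pytest.raises(ScriptError) as err:
            wl.run_script(random_raster(rng, 8, 8), script)
        assert err.value.index == 1

    def test_disjoint_actions_commute(self, rng):
        img = random_raster(rng, 10, 10)
        a = {"op": "brush", "row": 1, "col": 1, "radius": 1, "class": 1}
        b = {"op": "brush", "row": 8, "col": 8, "radius": 1, "class": 2}
        m1, _ = wl.run_script(img, wl.SessionScript([a, b]))
        m2, _ = wl.run_script(img, wl.SessionScript([b, a]))
        assert m1 == m2


class TestSavePair:
    def test_label_png_round_trip_bit_exact(self, rng, tmp_path):
        img = random_raster(rng, 9, 9)
        s = wl.new_session(img)
        wl.brush(s, (4, 4), 20, "intact_skin")  # covers all
        img_path, label_path = wl.save_pair(s, tmp_path / "out")
        assert img_path.exists() and label_path.exists()
        back = wl.load_label_map(label_path)
        assert back == s.mask
        sidecar = json.loads((tmp_path / "out_palette.json").read_text())
        assert sidecar["classes"][1]["name"] == "intact_skin"

    def test_unlabeled_pixels_block_save_with_count(self, rng, tmp_path):
        s = wl.new_session(random_raster(rng, 4, 4))
        wl.brush(s, (0, 0), 0, 1)
        with pytest.raises(CompletenessError) as err:
            wl.save_pair(s, tmp_path / "x")
        assert err.value.unlabeled_count == 15

    def test_label_png_palette_colors_follow_legend(self, rng, tmp_path):
        from PIL import Image

        s = wl.new_session(random_raster(rng, 4, 4))
        wl.brush(s, (1, 1), 10, "intact_skin")
        wl.save_pair(s, tmp_path / "leg")
        with Image.open(tmp_path / "leg_label.png") as im:
            pal = im.getpalette()
        # palette index = class id; intact skin (2) is green, background (1) blue
        assert pal[3 * 1 : 3 * 1 + 3] == [0, 0, 255]
        assert pal[3 * 2 : 3 * 2 + 3] == [0, 255, 0]
        assert pal[3 * 4 : 3 * 4 + 3] == [255, 255, 0]
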