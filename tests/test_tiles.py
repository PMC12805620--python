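import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpstils.simulate import literal_tile_label
from gpstils.tiles import (NEITHER, STILS, TILS, ScoringThresholds, TileCounts,
                           TileLabel, classify_tile, count_tile, patch_vector,
                           score_patches, score_patches_from_tile_counts,
                           tile_counts_from_nuclei, tile_grid)


class TestTileGrid:
    def test_default_patch_gives_16_tiles_of_side_448(self):
        tiles = tile_grid(0, 0)
        assert len(tiles) == 16
        assert all(x1 - x0 == 448 and y1 - y0 == 448 for x0, y0, x1, y1 in tiles)

    def test_tiles_partition_the_patch(self):
        tiles = tile_grid(1792, 3584)
        area = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in tiles)
        assert area == 1792 * 1792
        # pairwise disjoint: no two tiles share an interior point
        for i, a in enumerate(tiles):
            for b in tiles[i + 1:]:
                assert a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]

    def test_coarser_grid(self):
        t = ScoringThresholds(tile_side_px20=896, tiles_per_patch_side=2)
        tiles = tile_grid(0, 0, patch_side=1792, thresholds=t)
        assert len(tiles) == 4
        assert tiles[0][2] - tiles[0][0] == 896

    def test_indivisible_patch_side_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            tile_grid(0, 0, patch_side=1793)


class TestCountTile:
    def test_nucleus_on_shared_edge_counted_exactly_once(self):
        nuclei = pd.DataFrame({"slide_id": ["A"], "x": [448.0], "y": [100.0],
                               "cell_class": ["neoplastic"]})
        totals = [count_tile(nuclei, b).n_total for b in tile_grid(0, 0)]
        assert sum(totals) == 1

    def test_empty_tile_counts_zero(self):
        nuclei = pd.DataFrame({"slide_id": [], "x": [], "y": [], "cell_class": []})
        assert count_tile(nuclei, (0, 0, 448, 448)).n_total == 0

    def test_conservation_random_scatter(self):
        rng = np.random.default_rng(0)
        nuclei = pd.DataFrame({
            "slide_id": "A",
            "x": rng.uniform(0, 3000, 500),
            "y": rng.uniform(0, 3000, 500),
            "cell_class": rng.choice(["neoplastic", "lymphocyte", "stromal"], 500),
        })
        inside = ((nuclei.x < 1792) & (nuclei.y < 1792)).sum()
        totals = sum(count_tile(nuclei, b).n_total for b in tile_grid(0, 0))
        assert totals == inside


class TestClassifyTile:
    @pytest.mark.parametrize("counts,expected", [
        # boundary of the TILs definition: >=20 neoplastic, >=5 lymphocytes
        (TileCounts(20, 5, 2, 0, 0), (True, TILS, False)),
        # stroma-dominant with >=5 lymphocytes
        (TileCounts(3, 5, 6, 0, 0), (True, STILS, False)),
        # fewer than 10 nuclei in total: not considered
        (TileCounts(9, 0, 0, 0, 0), (False, NEITHER, False)),
        # necrosis flag independent of category
        (TileCounts(5, 0, 20, 15, 0), (True, NEITHER, True)),
        # both definitions hold: stroma dominance wins
        (TileCounts(20, 5, 25, 0, 0), (True, STILS, False)),
    ])
    def test_worked_examples(self, counts, expected):
        lab = classify_tile(counts)
        assert (lab.valid, lab.category, lab.necrotic_flag) == expected

    def test_tils_precedence_switch(self):
        t = ScoringThresholds(stils_precedence=False)
        assert classify_tile(TileCounts(20, 5, 25, 0, 0), t).category == TILS

    @settings(max_examples=300, deadline=None)
    @given(st.tuples(*[st.integers(0, 25)] * 5))
    def test_matches_literal_rule(self, counts):
        lab = classify_tile(TileCounts(*counts))
        assert (lab.valid, lab.category, lab.necrotic_flag) == literal_tile_label(*counts)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 30)] * 5))
    def test_adding_lymphocyte_never_removes_tils(self, counts):
        before = classify_tile(TileCounts(*counts))
        n, l, s, nec, o = counts
        after = classify_tile(TileCounts(n, l + 1, s, nec, o))
        if before.category == TILS:
            assert after.category in (TILS, STILS)  # can only flip by stroma rule
            if s <= n:
                assert after.category == TILS

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 30)] * 5))
    def test_adding_necrotic_nucleus_never_clears_flag(self, counts):
        before = classify_tile(TileCounts(*counts))
        n, l, s, nec, o = counts
        after = classify_tile(TileCounts(n, l, s, nec + 1, o))
        if before.necrotic_flag:
            assert after.necrotic_flag


class TestPatchVector:
    def test_all_neither(self):
        labels = [TileLabel(True, NEITHER, False)] * 16
        assert patch_vector(labels) == (0, 0, 0)

    def test_mixed_counts(self):
        labels = ([TileLabel(True, TILS, True)]            # TILs tile, also necrotic
                  + [TileLabel(True, TILS, False)] * 2
                  + [TileLabel(True, STILS, False)] * 2
                  + [TileLabel(True, NEITHER, False)] * 11)
        assert patch_vector(labels) == (3, 2, 1)

    def test_wrong_label_count_rejected(self):
        with pytest.raises(ValueError, match="16"):
            patch_vector([TileLabel(True, NEITHER, False)] * 15)


class TestCohortScoring:
    def test_counts_path_equals_nuclei_path(self, small_cohort):
        by_nuclei = score_patches(small_cohort.nuclei, small_cohort.patches)
        by_counts = score_patches_from_tile_counts(small_cohort.tile_counts,
                                                   small_cohort.patches)
        key = ["slide_id", "x0", "y0"]
        pd.testing.assert_frame_equal(
            by_nuclei.sort_values(key).reset_index(drop=True),
            by_counts.sort_values(key).reset_index(drop=True))

    def test_cohort_level_nucleus_conservation(self, small_cohort):
        counts = tile_counts_from_nuclei(small_cohort.nuclei, small_cohort.patches)
        total_binned = counts[[c for c in counts if c.startswith("n_")]].to_numpy().sum()
        assert total_binned == len(small_cohort.nuclei)  # every patch is labelled

    def test_patch_without_nuclei_scores_zero(self):
        nuclei = pd.DataFrame({"slide_id": ["A"], "x": [10.0], "y": [10.0],
                               "cell_class": ["neoplastic"]})
        patches = pd.DataFrame({"slide_id": ["A", "A"], "x0": [0, 1792],
                                "y0": [0, 0], "pattern": ["acinar", "solid"]})
        scored = score_patches(nuclei, patches).set_index("x0")
        assert scored.loc[1792, ["n_til_tiles", "n_stil_tiles", "n_necrotic_tiles"]].sum() == 0
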