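"""Cell/microglia/myelin detectors: thresholds, pass rules, watershed, Wolf map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcmap import detect
from ihcmap.detect import (CellParams, MicrogliaParams, MyelinParams, clip_channel,
                           detect_cells, detect_microglia, detect_myelin, mad_mask,
                           wolf_threshold_map)
from ihcmap.phantoms import gen_detection_tile


class TestClipChannel:
    @pytest.mark.parametrize("value,expected", [(-0.5, 0.0), (7.0, 3.0), (1.2, 1.2)])
    def test_truncation_bounds(self, value, expected):
        assert clip_channel(np.array([value]))[0] == expected


class TestMadMask:
    def test_constant_channel_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="MAD"):
            mask = mad_mask(np.full((8, 8), 2.0), k=3)
        assert not mask.any()

    def test_matches_direct_formula(self):
        chan = np.arange(100, dtype=float).reshape(10, 10)
        med = np.median(chan)
        mad = np.median(np.abs(chan - med))
        for k in (0.0, 1.0, 2.0):
            assert np.array_equal(mad_mask(chan, k), chan > med + k * mad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0, 5))
    def test_oracle_equivalence_random_channels(self, seed, k):
        chan = np.random.default_rng(seed).uniform(0, 3, (12, 12))
        med = np.median(chan)
        mad = np.median(np.abs(chan - med))
        expected = chan > med + k * mad if mad > 0 else chan > med
        assert np.array_equal(mad_mask(chan, k), expected)


class TestDetectCells:
    @pytest.mark.parametrize("n", [0, 10, 20])
    def test_exact_count_on_disjoint_nuclei(self, n):
        conc, truth = gen_detection_tile(seed=11, n_nuclei=n, tile_px=360)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs = detect_cells(conc, CellParams())
        assert cs.count == n

    def test_touching_pairs_split_by_watershed(self):
        import warnings

        split = total = 0
        for seed in range(10):
            conc, truth = gen_detection_tile(seed=seed, n_nuclei=8, overlap_pairs=2, tile_px=360)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs = detect_cells(conc, CellParams())
            # a pair counts as split when its two truth centers land in
            # different watershed labels
            for i1, i2 in truth["merged_pairs"]:
                c1 = truth["nuclei_centers"][i1]
                c2 = truth["nuclei_centers"][i2]
                l1 = cs.labels[int(round(c1[0])), int(round(c1[1]))]
                l2 = cs.labels[int(round(c2[0])), int(round(c2[1]))]
                total += 1
                split += int(l1 > 0 and l2 > 0 and l1 != l2)
        assert split / total >= 0.9

    def test_counts_nonincreasing_through_passes(self):
        import warnings

        from scipy import ndimage

        conc, _ = gen_detection_tile(seed=5, n_nuclei=15, tile_px=360)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = detect_cells(conc, CellParams(), keep_intermediates=True)
        struct = np.ones((3, 3), bool)
        n = [ndimage.label(cs.intermediates[p], structure=struct)[1]
             for p in ("pass1", "pass2", "pass3")]
        assert n[1] <= n[0] and n[2] <= n[1]

    def test_huge_mad_k_detects_nothing(self):
        import warnings

        conc, _ = gen_detection_tile(seed=5, n_nuclei=15, tile_px=360)
        rng = np.random.default_rng(0)
        conc[..., 0] += rng.uniform(0.05, 0.15, conc.shape[:2])  # non-degenerate MAD
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = detect_cells(conc, CellParams(mad_k=1e9))
        assert cs.count == 0

    def test_missing_channel_is_error(self):
        with pytest.raises(ValueError, match="channel"):
            detect_cells(np.zeros((8, 8)), CellParams())
        with pytest.raises(ValueError, match="channel"):
            detect_myelin(np.zeros((8, 8, 2)), MyelinParams())

    def test_component_metadata_consistent(self):
        import warnings

        conc, _ = gen_detection_tile(seed=9, n_nuclei=12, tile_px=360)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = detect_cells(conc, CellParams())
        assert cs.count == len(cs.areas) == len(cs.centroids)
        assert cs.labels.max() == cs.count
        assert np.array_equal(np.unique(cs.labels)[1:], np.arange(1, cs.count + 1))


class TestDetectMicroglia:
    def _tile_with_component(self, area_px, intensity, n_hot=0, hot_value=2.0):
        """One rectangular DAB component of the given area/intensity layout."""
        conc = np.zeros((120, 120, 3))
        side = int(np.sqrt(area_px))
        h, w = side, int(np.ceil(area_px / side))
        block = np.full((h, w), intensity)
        if n_hot:
            block.ravel()[:n_hot] = hot_value
        conc[10 : 10 + h, 10 : 10 + w, 1] = block
        return conc

    def test_large_low_intensity_component_kept_by_size_rule(self):
        conc = self._tile_with_component(400, intensity=0.3)
        p = MicrogliaParams(mad_k=1.0, min_size_1=10, low_intensity_pct_1=0,
                            size_req_min=300, intensity_req_min=1.0, intensity_req_count=20,
                            max_size_2=10000, centroid_trim_pct_3=0, min_size_3=10)
        assert detect_microglia(conc, p).count == 1

    def test_small_intense_component_kept_by_intensity_rule(self):
        conc = self._tile_with_component(60, intensity=0.4, n_hot=30, hot_value=2.0)
        p = MicrogliaParams(mad_k=1.0, min_size_1=10, low_intensity_pct_1=0,
                            size_req_min=300, intensity_req_min=1.5, intensity_req_count=20,
                            max_size_2=10000, centroid_trim_pct_3=0, min_size_3=10)
        assert detect_microglia(conc, p).count == 1

    def test_small_dim_component_dropped(self):
        conc = self._tile_with_component(60, intensity=0.4, n_hot=10, hot_value=2.0)
        p = MicrogliaParams(mad_k=1.0, min_size_1=10, low_intensity_pct_1=0,
                            size_req_min=300, intensity_req_min=1.5, intensity_req_count=20,
                            max_size_2=10000, centroid_trim_pct_3=0, min_size_3=10)
        assert detect_microglia(conc, p).count == 0

    def test_oversized_component_dropped_even_if_intense(self):
        conc = self._tile_with_component(900, intensity=2.5)
        p = MicrogliaParams(mad_k=1.0, min_size_1=10, low_intensity_pct_1=0,
                            size_req_min=300, intensity_req_min=1.0, intensity_req_count=20,
                            max_size_2=500, centroid_trim_pct_3=0, min_size_3=10)
        assert detect_microglia(conc, p).count == 0

    def test_phantom_count_recovery(self):
        import warnings

        conc, truth = gen_detection_tile(seed=3, n_nuclei=0, n_microglia=8, tile_px=360)
        p = MicrogliaParams(size_req_min=60, intensity_req_min=0.5, intensity_req_count=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = detect_microglia(conc, p)
        assert ms.count == truth["counts"]["microglia"]


class TestWolfThreshold:
    def test_constant_channel_yields_zero_positives(self):
        conc = np.zeros((64, 64, 3))
        conc[..., 2] = 1.7
        mask, n = detect_myelin(conc, MyelinParams())
        assert n == 0

    def test_map_equals_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        chan = rng.uniform(0, 3, (32, 32))
        params = MyelinParams(alpha=0.6, k=0.4, window_px=7)
        got = wolf_threshold_map(chan, params)
        w = params.window_px
        pad = np.pad(chan, w // 2, mode="symmetric")
        H, W = chan.shape
        s = np.array([[pad[i:i + w, j:j + w].std() for j in range(W)] for i in range(H)])
        R, mmin = s.max(), chan.min()
        expected = np.array(
            [[pad[i:i + w, j:j + w].mean()
              - params.k * (1 - params.alpha * s[i, j] / R) * (pad[i:i + w, j:j + w].mean() - mmin)
              for j in range(W)] for i in range(H)]
        )
        assert np.abs(got - expected).max() < 1e-10

    def test_default_window_is_15(self):
        assert MyelinParams().window_px == 15

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            MyelinParams(window_px=8)


class TestDetectMyelin:
    def test_zero_channel_zero_positives(self):
        conc = np.zeros((64, 64, 3))
        _, n = detect_myelin(conc, MyelinParams())
        assert n == 0

    def test_high_contrast_region_dice(self):
        conc, truth = gen_detection_tile(seed=4, n_nuclei=0, tile_px=360, myelin_blob=True)
        mask, n = detect_myelin(conc, MyelinParams())
        tm = truth["myelin_mask"]
        dice = 2 * (mask & tm).sum() / (mask.sum() + tm.sum())
        assert dice >= 0.95
        assert n == mask.sum()

    def test_negative_pixels_never_positive(self):
        rng = np.random.default_rng(1)
        conc = np.zeros((64, 64, 3))
        conc[..., 2] = rng.uniform(-1, 2, (64, 64))
        mask, _ = detect_myelin(conc, MyelinParams())
        assert not mask[conc[..., 2] < 0].any()

    def test_sentinel_exclusion(self):
        conc, _ = gen_detection_tile(seed=4, n_nuclei=0, tile_px=128, myelin_blob=True)
        exclude = np.zeros((128, 128), bool)
        exclude[:, :64] = True
        mask, _ = detect_myelin(conc, MyelinParams(), exclude=exclude)
        assert not mask[:, :64].any()


class TestParamsIO:
    @pytest.mark.parametrize("cls", [CellParams, MicrogliaParams, MyelinParams])
    def test_json_round_trip_with_standard_filenames(self, cls, tmp_path):
        params = cls()
        path = detect.save_params(params, tmp_path)
        assert path.name.endswith("_detection_parameters.json")
        assert detect.load_params(cls, tmp_path) == params
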