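import numpy as np
import pytest

from scopesr import (CrappifierSpec, DatasetSpec, ImageStack, TiledDataset,
                     TileRecord, downsample, enumerate_tiles, split_by_tile,
                     stitch)


def make_stack(shape, rng, axes=None):
    if axes is None:
        axes = ("T", "Y", "X") if len(shape) == 3 else ("Y", "X")
    return ImageStack(rng.uniform(0, 1, shape), axes, (0.0, 1.0))


def grid_records(n_tiles=10, n_frames=5):
    return [TileRecord("img", f, r, 0)
            for r in range(n_tiles) for f in range(n_frames)]


class TestEnumerateTiles:
    def test_2x2_grid(self, rng):
        recs = enumerate_tiles(make_stack((1024, 1024), rng), 512, 512)
        assert len(recs) == 4
        assert {(r.row, r.col) for r in recs} == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_frames_multiply_records(self, rng):
        recs = enumerate_tiles(make_stack((3, 1024, 1024), rng), 512, 512,
                               frame_axes={"T"})
        assert len(recs) == 12
        assert len({(r.row, r.col) for r in recs}) == 4

    def test_remainder_dropped(self, rng):
        recs = enumerate_tiles(make_stack((513, 512), rng), 512, 512)
        assert len(recs) == 1

    def test_overlapping_stride(self, rng):
        recs = enumerate_tiles(make_stack((768, 768), rng), 512, 256)
        assert {(r.row, r.col) for r in recs} == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_tile_too_large_names_dimension(self, rng):
        with pytest.raises(ValueError, match="Y"):
            enumerate_tiles(make_stack((100, 600), rng), 512, 512)


class TestSplitByTile:
    def test_no_tile_straddles_split(self):
        train, val = split_by_tile(grid_records(), 0.2, split_seed=3)
        train_keys = {r.tile_key for r in train}
        val_keys = {r.tile_key for r in val}
        assert not train_keys & val_keys
        assert len(val_keys) == 2 and len(val) == 10 and len(train) == 40

    def test_zero_fraction_all_train(self):
        train, val = split_by_tile(grid_records(), 0.0, split_seed=0)
        assert len(val) == 0 and len(train) == 50

    def test_deterministic(self):
        a = split_by_tile(grid_records(), 0.3, split_seed=9)
        b = split_by_tile(grid_records(), 0.3, split_seed=9)
        assert a == b

    def test_partition_is_exact(self):
        recs = grid_records()
        train, val = split_by_tile(recs, 0.4, split_seed=1)
        assert sorted(train + val) == sorted(recs)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="val_fraction"):
            split_by_tile(grid_records(), 1.0, 0)


class TestTrainSamples:
    @pytest.fixture
    def dataset(self, rng):
        spec = DatasetSpec(mode="train", hr_size=64, scale=4,
                           crappifier=CrappifierSpec(intensity_low=2,
                                                     intensity_high=8))
        return TiledDataset(spec, hr_stacks={"a": make_stack((128, 128), rng)})

    def test_runtime_crappification_lr_varies_hr_fixed(self, dataset):
        rec = dataset.records[0]
        gen = np.random.default_rng(0)
        s1 = dataset.get_train_sample(rec, gen)
        s2 = dataset.get_train_sample(rec, gen)
        np.testing.assert_array_equal(s1.hr, s2.hr)
        assert not np.array_equal(s1.lr, s2.lr)

    def test_zero_intensity_lr_is_downsample(self, rng):
        spec = DatasetSpec(mode="train", hr_size=64, scale=4,
                           crappifier=CrappifierSpec(intensity_low=0,
                                                     intensity_high=0))
        ds = TiledDataset(spec, hr_stacks={"a": make_stack((128, 128), rng)})
        sample = ds.get_train_sample(ds.records[0], np.random.default_rng(0))
        np.testing.assert_array_equal(sample.lr, downsample(sample.hr, 4))

    def test_stream_reproducible_from_seed(self, dataset):
        def stream(seed):
            gen = np.random.default_rng(seed)
            return [dataset.get_train_sample(r, gen).lr
                    for r in dataset.records]

        for a, b in zip(stream(99), stream(99)):
            np.testing.assert_array_equal(a, b)

    def test_sample_geometry(self, dataset):
        sample = dataset.get_train_sample(dataset.records[0],
                                          np.random.default_rng(0))
        assert sample.hr.shape == (64, 64) and sample.lr.shape == (16, 16)

    def test_validation_intensity_is_midpoint(self, dataset):
        sample = dataset.get_train_sample(dataset.records[0],
                                          np.random.default_rng(0),
                                          validation=True)
        assert sample.intensity_used == 5.0


class TestPredictAndBenchmark:
    def test_predict_sample_has_no_hr(self, rng):
        spec = DatasetSpec(mode="predict", hr_size=512, scale=4)
        ds = TiledDataset(spec, lr_stacks={"a": make_stack((128, 128), rng)})
        sample = ds.get_predict_sample(ds.records[0])
        assert sample.lr.shape == (128, 128)
        assert sample.hr is None

    def test_predict_multiframe_one_sample_per_frame(self, rng):
        spec = DatasetSpec(mode="predict", hr_size=512, scale=4)
        ds = TiledDataset(spec, lr_stacks={"a": make_stack((3, 128, 128), rng)},
                          frame_axes=("T",))
        assert len(ds.records) == 3

    def test_benchmark_pair_geometry_accepted(self, rng):
        spec = DatasetSpec(mode="benchmark", hr_size=512, scale=4)
        ds = TiledDataset(spec, hr_stacks={"a": make_stack((512, 512), rng)},
                          lr_stacks={"a": make_stack((128, 128), rng)})
        pair = ds.get_benchmark_pair(ds.records[0])
        assert pair.hr.shape == (512, 512) and pair.lr.shape == (128, 128)

    def test_benchmark_bad_geometry_rejected(self, rng):
        spec = DatasetSpec(mode="benchmark", hr_size=512, scale=4)
        with pytest.raises(ValueError, match="not .*4x|not 4"):
            TiledDataset(spec, hr_stacks={"a": make_stack((512, 512), rng)},
                         lr_stacks={"a": make_stack((100, 100), rng)})

    def test_benchmark_missing_partner_names_basename(self, rng):
        spec = DatasetSpec(mode="benchmark", hr_size=512, scale=4)
        with pytest.raises(ValueError, match="'solo'"):
            TiledDataset(spec, hr_stacks={"solo": make_stack((512, 512), rng)},
                         lr_stacks={"other": make_stack((128, 128), rng)})

    def test_benchmark_mode_rejects_crappifier(self):
        with pytest.raises(ValueError, match="no crappifier"):
            DatasetSpec(mode="benchmark", hr_size=512, scale=4,
                        crappifier=CrappifierSpec())


class TestStitch:
    def test_round_trip_identity(self, rng):
        stack = make_stack((1024, 1024), rng)
        recs = enumerate_tiles(stack, 512, 512)
        tiles = [(r, stack.data[r.row * 512:(r.row + 1) * 512,
                                r.col * 512:(r.col + 1) * 512]) for r in recs]
        out = stitch(tiles, (1024, 1024), 512)
        np.testing.assert_array_equal(out, stack.data)

    def test_overlapping_constant_tiles_stay_constant(self):
        tiles = [(TileRecord("a", 0, r, c), np.full((64, 64), 0.7))
                 for r in range(2) for c in range(2)]
        out = stitch(tiles, (96, 96), 32)
        np.testing.assert_allclose(out, 0.7)

    def test_missing_tile_is_coverage_error(self, rng):
        tiles = [(TileRecord("a", 0, r, c), rng.uniform(0, 1, (512, 512)))
                 for r, c in [(0, 0), (0, 1), (1, 0)]]
        with pytest.raises(ValueError, match="uncovered"):
            stitch(tiles, (1024, 1024), 512)
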