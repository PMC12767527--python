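"""Window geometry, signal scaling, fold assignment, encoding, augmentation."""

import numpy as np
import pandas as pd
import pytest

from enhancerkit.dataprep import (
    BoundaryError,
    CapacityError,
    DegenerateNormalizationError,
    EncodedDataset,
    GenomicInterval,
    InfeasiblePartitionError,
    assign_folds,
    augment_and_balance,
    augment_reverse_complement,
    encode_dataset,
    resize_interval,
    sample_inaccessible_controls,
    scale_and_filter_signal,
    tile_windows,
)
from enhancerkit.sequences import one_hot
from enhancerkit.synthetic import generate_genome
from enhancerkit.tracks import SignalTrack


class TestResizeInterval:
    def test_fixed_centering(self):
        out = resize_interval(GenomicInterval("chr1", 1000, 1001), 1001, "fixed")
        assert (out.start, out.end) == (500, 1501)

    def test_minimum_leaves_long_intervals_unchanged(self):
        iv = GenomicInterval("chr1", 10_000, 12_000)
        assert resize_interval(iv, 1501, "minimum") is iv

    def test_minimum_extends_symmetrically(self):
        iv = GenomicInterval("chr1", 10_000, 11_001)
        out = resize_interval(iv, 1501, "minimum")
        assert out.end - out.start == 1501
        assert abs(out.center - iv.center) <= 1

    def test_fixed_requires_odd_length(self):
        with pytest.raises(ValueError, match="odd"):
            resize_interval(GenomicInterval("chr1", 100, 200), 1000, "fixed")

    def test_boundary_error(self):
        with pytest.raises(BoundaryError):
            resize_interval(GenomicInterval("chr1", 10, 20), 1001, "fixed")


class TestTileWindows:
    def test_standard_yields_five_windows(self):
        region = GenomicInterval("chr1", 10_000, 11_001)
        windows = tile_windows(region, "standard")
        assert len(windows) == 5
        centers = sorted(w.center for w in windows)
        assert centers == [region.center + off for off in (-400, -200, 0, 200, 400)]

    def test_dense_yields_seventeen_windows(self):
        windows = tile_windows(GenomicInterval("chr1", 10_000, 11_001), "dense")
        assert len(windows) == 17
        assert all(w.length == 1001 for w in windows)

    def test_vista_1501bp_region(self):
        windows = tile_windows(GenomicInterval("chr1", 10_000, 11_501), "vista")
        assert len(windows) == 13
        starts = sorted(w.start for w in windows)
        assert starts[0] == 10_000 - 50 and starts[-1] == 10_000 + 550

    @pytest.mark.parametrize("length", [1001, 1051, 1499, 2000, 3503, 5000])
    def test_vista_matches_brute_force_overlap_enumerator(self, length):
        # candidate grid: 50 bp steps anchored at the region start, one step
        # of overhang past the last in-region window on each side; keep
        # candidates with >= 950 bp overlap with the region
        start = 50_000
        region = GenomicInterval("chr1", start, start + length)
        last_in = max(length - 1001, 0)
        candidates = range(-50, (last_in // 50) * 50 + 51, 50)
        expected = []
        for off in candidates:
            w_start = start + off
            overlap = min(start + length, w_start + 1001) - max(start, w_start)
            if overlap >= 950:
                expected.append(w_start)
        got = sorted(w.start for w in tile_windows(region, "vista"))
        assert got == expected

    def test_boundary_windows_dropped_with_warning(self):
        region = GenomicInterval("chr1", 300, 1301)
        with pytest.warns(UserWarning, match="dropped"):
            windows = tile_windows(region, "standard", chrom_length=10_000)
        assert all(w.start >= 0 for w in windows)
        assert len(windows) < 5


def test_vista_filter_drops_long_and_mutant_entries():
    from enhancerkit.dataprep import filter_vista_table

    table = pd.DataFrame(
        {
            "id": ["el1", "el2_mut1", "el3", "el4"],
            "chrom": ["chr1"] * 4,
            "start": [0, 0, 0, 0],
            "end": [1200, 1400, 5001, 5000],
        }
    )
    out = filter_vista_table(table)
    assert list(out["id"]) == ["el1", "el4"]


class TestScaleAndFilter:
    def test_single_region_closed_form(self):
        signal = pd.DataFrame({"heart": [1.0]}, index=["r1"])
        scaled, removed = scale_and_filter_signal(signal)
        assert scaled.loc["r1", "heart"] == pytest.approx(np.log2(1e6), abs=1e-9)
        assert removed == []

    def test_equal_signals_remove_nothing(self):
        signal = pd.DataFrame({"heart": np.ones(10_000)})
        _, removed = scale_and_filter_signal(signal)
        assert removed == []

    def test_single_outlier_removed(self):
        values = np.ones(10_000)
        values[1234] = 50.0
        signal = pd.DataFrame({"heart": values}, index=[f"r{i}" for i in range(10_000)])
        _, removed = scale_and_filter_signal(signal)
        assert removed == ["r1234"]

    def test_all_zero_tissue_raises(self):
        with pytest.raises(DegenerateNormalizationError):
            scale_and_filter_signal(pd.DataFrame({"heart": [0.0, 0.0]}))


class TestInaccessibleControls:
    def test_bin_count_on_empty_exclusions(self):
        from enhancerkit.genome import Genome

        genome = Genome(chroms={"chr1": np.zeros(1_000_000, dtype=np.uint8)})
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        n_bins = 1_000_000 // 1001
        controls = sample_inaccessible_controls(genome, empty, n_bins, seed=0)
        assert len(controls) == n_bins == 999

    def test_capacity_error_when_everything_excluded(self):
        genome = generate_genome(2, 50_000, seed=0)
        excl = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [50_000, 50_000]})
        with pytest.raises(CapacityError, match="eligible"):
            sample_inaccessible_controls(genome, excl, 1, seed=0)

    def test_min_distance_exhaustive(self):
        genome = generate_genome(2, 60_000, seed=3)
        excl = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "start": [5_000, 30_000, 12_000], "end": [6_001, 31_001, 13_001]}
        )
        controls = sample_inaccessible_controls(genome, excl, 20, seed=1)
        for row in controls.itertuples(index=False):
            for ex in excl.itertuples(index=False):
                if ex.chrom != row.chrom:
                    continue
                gap = max(ex.start - row.end, row.start - ex.end)
                assert gap >= 1500

    def test_deterministic_per_seed(self):
        genome = generate_genome(2, 60_000, seed=3)
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        a = sample_inaccessible_controls(genome, empty, 10, seed=5)
        b = sample_inaccessible_controls(genome, empty, 10, seed=5)
        pd.testing.assert_frame_equal(a, b)


def _regions(rows):
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


class TestAssignFolds:
    def test_close_regions_share_a_fold(self):
        rows = [("a", "chr1", 10_000, 11_001), ("b", "chr1", 12_401, 13_402)]  # 1,400 bp apart
        for extra in range(30):  # enough other blocks to fill the folds
            rows.append((f"x{extra}", "chr2", 10_000 + extra * 5_000, 11_001 + extra * 5_000))
        folds = assign_folds(_regions(rows), n_folds=5)
        assert folds.fold_of("a") == folds.fold_of("b")

    def test_gap_invariant_holds(self):
        rng = np.random.default_rng(8)
        starts = np.cumsum(rng.integers(1_600, 9_000, size=200))
        rows = [(f"r{i}", "chr1", int(s), int(s) + 1001) for i, s in enumerate(starts)]
        folds = assign_folds(_regions(rows), n_folds=20)
        df = _regions(rows)
        df["fold"] = df["region_id"].map(folds.mapping)
        df = df.sort_values("start")
        gaps = df["start"].to_numpy()[1:] - df["end"].to_numpy()[:-1]
        different = df["fold"].to_numpy()[1:] != df["fold"].to_numpy()[:-1]
        assert (gaps[different] >= 1500).all()

    def test_fold_sizes_balanced(self):
        rows = [(f"r{i}", "chr1", 10_000 + i * 5_000, 11_001 + i * 5_000) for i in range(200)]
        folds = assign_folds(_regions(rows), n_folds=20)
        sizes = pd.Series(folds.mapping).value_counts()
        assert sizes.between(8, 12).all()  # within +-20% of 10

    def test_holdout_chromosome_maps_to_holdout(self):
        rows = [(f"r{i}", "chr1", 10_000 + i * 5_000, 11_001 + i * 5_000) for i in range(30)]
        rows += [(f"h{i}", "chr9", 10_000 + i * 5_000, 11_001 + i * 5_000) for i in range(5)]
        folds = assign_folds(_regions(rows), n_folds=10, holdout_chrom="chr9")
        for i in range(5):
            assert folds.fold_of(f"h{i}") == "holdout"

    def test_infeasible_partition(self):
        rows = [(f"r{i}", "chr1", 10_000 + i * 5_000, 11_001 + i * 5_000) for i in range(3)]
        with pytest.raises(InfeasiblePartitionError):
            assign_folds(_regions(rows), n_folds=10)


@pytest.fixture(scope="module")
def genome():
    return generate_genome(2, 60_000, seed=4)


class TestEncodeDataset:
    def test_one_hot_rows_match_sequence(self, genome):
        windows = pd.DataFrame(
            {"region_id": ["w0"], "chrom": ["chr1"], "start": [100], "end": [1101], "strand": ["+"], "fold": [1]}
        )
        track = SignalTrack.from_records(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60_000], "value": [3.0]}))
        ds = encode_dataset(windows, genome, task="accessibility", signal_track=track)
        assert np.array_equal(ds.X[0], one_hot(genome.fetch("chr1", 100, 1101)))
        assert ds.y[0] == pytest.approx(2.0)  # log2(3 + 1)

    def test_zero_signal_gives_zero_target(self, genome):
        windows = pd.DataFrame(
            {"region_id": ["w0"], "chrom": ["chr1"], "start": [0], "end": [1001], "strand": ["+"], "fold": [1]}
        )
        track = SignalTrack.from_records(pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10], "value": [1.0]}))
        ds = encode_dataset(windows, genome, task="accessibility", signal_track=track)
        assert ds.y[0] == 0.0

    def test_activity_labels_attached(self, genome):
        windows = pd.DataFrame(
            {"region_id": ["a", "b"], "chrom": ["chr1", "chr1"], "start": [0, 5_000],
             "end": [1001, 6_001], "strand": ["+", "+"], "fold": [1, 2]}
        )
        ds = encode_dataset(windows, genome, task="activity", activity={"a": 1, "b": 0})
        assert list(ds.y) == [1.0, 0.0]

    def test_wrong_window_length_rejected(self, genome):
        windows = pd.DataFrame(
            {"region_id": ["w"], "chrom": ["chr1"], "start": [0], "end": [500], "strand": ["+"], "fold": [1]}
        )
        with pytest.raises(ValueError, match="1001"):
            encode_dataset(windows, genome, task="activity", activity={"w": 0})

    def test_save_load_roundtrip(self, genome, tmp_path):
        windows = pd.DataFrame(
            {"region_id": ["a"], "chrom": ["chr1"], "start": [0], "end": [1001], "strand": ["+"], "fold": [1]}
        )
        ds = encode_dataset(windows, genome, task="activity", activity={"a": 1})
        ds.save(tmp_path / "ds.npz")
        back = EncodedDataset.load(tmp_path / "ds.npz")
        assert np.array_equal(back.X, ds.X)
        assert np.array_equal(back.y, ds.y)
        assert list(back.folds) == list(ds.folds)


class TestAugmentBalance:
    @staticmethod
    def _dataset(n, fold_cycle=(1, 2), label=1.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.zeros((n, 1001, 4), dtype=np.float32)
        codes = rng.integers(0, 4, size=(n, 1001))
        for i in range(n):
            X[i, np.arange(1001), codes[i]] = 1.0
        folds = np.array([fold_cycle[i % len(fold_cycle)] for i in range(n)], dtype=object)
        prov = pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(n)], "chrom": "chr1",
             "start": np.arange(n) * 3000, "end": np.arange(n) * 3000 + 1001, "strand": "+"}
        )
        return EncodedDataset(X, np.full(n, label), folds, prov)

    def test_rc_doubles_and_is_involution(self):
        ds = self._dataset(10)
        aug = augment_reverse_complement(ds)
        assert len(aug) == 20
        assert np.array_equal(aug.X[10][::-1, ::-1], ds.X[0])

    def test_downsampling_ratio(self):
        pos = self._dataset(100, seed=1)
        neg = self._dataset(400, label=0.0, seed=2)
        out = augment_and_balance(pos, neg, neg_ratio=1.5, seed=3)
        # 200 augmented positives + 300 negatives
        assert len(out) == 500
        assert (out.y == 0).sum() == 300

    def test_balance_is_fold_stratified(self):
        pos = self._dataset(100, seed=1)
        neg = self._dataset(600, fold_cycle=(1, 2, 3), label=0.0, seed=2)
        out = augment_and_balance(pos, neg, neg_ratio=1.5, seed=3)
        neg_folds = pd.Series(out.folds[out.y == 0]).value_counts()
        assert neg_folds.max() - neg_folds.min() <= 2

    def test_scarce_negatives_warn_and_use_all(self):
        pos = self._dataset(100, seed=1)
        neg = self._dataset(20, label=0.0, seed=2)
        with pytest.warns(UserWarning, match="negatives"):
            out = augment_and_balance(pos, neg, neg_ratio=1.5, seed=3)
        assert (out.y == 0).sum() == 40
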