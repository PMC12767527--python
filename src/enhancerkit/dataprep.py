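"""From genome + signal + region tables to fold-partitioned encoded datasets.

The contract mirrors how genomic deep-learning training sets are usually
built: windows are exactly 1,001 bp; regions closer than 1.5 kb are never
split across cross-validation folds; one chromosome is held out entirely;
augmentation (tiling, reverse complement) happens only after fold
assignment so that no augmented copy of a region leaks across folds.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Genome
from .sequences import one_hot, reverse_complement_one_hot
from .tracks import SignalTrack

WINDOW = 1001
MIN_GAP = 1500
HOLDOUT = "holdout"


class BoundaryError(ValueError):
    """A resized or tiled window would exit the chromosome."""


class CapacityError(RuntimeError):
    """Not enough eligible genomic space for the request."""


class InfeasiblePartitionError(RuntimeError):
    """Fewer gap-linked blocks than requested folds."""


class DegenerateNormalizationError(ValueError):
    """A tissue has all-zero signal, so per-tissue scaling is undefined."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class RegionTable:
    """Region universe (peaks + VISTA-style enhancers + controls).

    ``df`` columns: region_id, chrom, start, end, strand, source plus
    ``signal_<tissue>`` (mean accessibility, >= 0) and ``activity_<tissue>``
    (0/1, NaN for peaks without activity annotation) per tissue.
    """

    df: pd.DataFrame
    tissues: list[str]

    def __post_init__(self):
        for col in ("region_id", "chrom", "start", "end", "source"):
            if col not in self.df.columns:
                raise ValueError(f"RegionTable missing column {col!r}")

    def subset(self, mask) -> "RegionTable":
        return RegionTable(self.df[mask].reset_index(drop=True), self.tissues)


@dataclass
class FoldAssignment:
    """region_id -> fold id (1..n_folds) or 'holdout'."""

    mapping: dict[str, int | str]
    holdout_chrom: str
    n_folds: int

    def fold_of(self, region_id: str) -> int | str:
        return self.mapping[region_id]

    def as_series(self) -> pd.Series:
        return pd.Series(self.mapping, name="fold")


@dataclass
class EncodedDataset:
    """One-hot sequences plus targets, folds and window provenance."""

    X: np.ndarray  # (n, 1001, 4) float32
    y: np.ndarray  # (n,) float64 — regression target or 0/1 label
    folds: np.ndarray  # (n,) object — ints or 'holdout'
    provenance: pd.DataFrame  # region_id, chrom, start, end, strand

    def __post_init__(self):
        n = len(self.X)
        if not (len(self.y) == len(self.folds) == len(self.provenance) == n):
            raise ValueError("EncodedDataset components have mismatched lengths")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            self.X[mask], self.y[mask], self.folds[mask], self.provenance.iloc[mask].reset_index(drop=True)
        )

    @classmethod
    def concatenate(cls, parts: list["EncodedDataset"]) -> "EncodedDataset":
        return cls(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.folds for p in parts]),
            pd.concat([p.provenance for p in parts], ignore_index=True),
        )

    def save(self, path: str | os.PathLike) -> None:
        np.savez_compressed(
            path,
            X=self.X,
            y=self.y,
            folds=self.folds.astype(str),
            **{f"prov_{c}": self.provenance[c].to_numpy().astype(str) for c in self.provenance.columns},
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "EncodedDataset":
        with np.load(path, allow_pickle=False) as data:
            folds = np.array([int(f) if f != HOLDOUT else HOLDOUT for f in data["folds"]], dtype=object)
            prov_cols = {k[5:]: data[k] for k in data.files if k.startswith("prov_")}
            prov = pd.DataFrame(prov_cols)
            for c in ("start", "end"):
                if c in prov:
                    prov[c] = prov[c].astype(int)
            return cls(data["X"], data["y"], folds, prov)


# ---------------------------------------------------------------------------
# interval geometry


def resize_interval(
    interval: GenomicInterval, target_length: int, mode: str, chrom_length: int | None = None
) -> GenomicInterval:
    """Resize to exactly ``target_length`` (fixed) or at least it (minimum)."""
    if mode == "fixed":
        if target_length % 2 == 0:
            raise ValueError("fixed-mode target_length must be odd (symmetric flanks)")
        half = (target_length - 1) // 2
        c = interval.center
        start, end = c - half, c + half + 1
    elif mode == "minimum":
        if interval.length >= target_length:
            return interval
        deficit = target_length - interval.length
        left = deficit // 2
        start, end = interval.start - left, interval.end + (deficit - left)
    else:
        raise ValueError(f"unknown resize mode {mode!r}")
    if start < 0 or (chrom_length is not None and end > chrom_length):
        raise BoundaryError(f"resized interval {interval.chrom}:{start}-{end} exits chromosome")
    return replace(interval, start=start, end=end)


def tile_windows(
    region: GenomicInterval,
    mode: str,
    window: int = WINDOW,
    chrom_length: int | None = None,
) -> list[GenomicInterval]:
    """Tile a region with fixed-size windows.

    standard: 5 windows at center offsets -400..+400, 200 bp stride.
    dense:    17 windows at center offsets -400..+400, 50 bp stride.
    vista:    windows on a 50 bp grid anchored at the region start, with one
              grid step of overhang allowed per side, keeping windows with
              >= 950 bp overlap with the region.
    """
    half = (window - 1) // 2
    starts: list[int] = []
    if mode in ("standard", "dense"):
        stride = 200 if mode == "standard" else 50
        c = region.center
        starts = [c + off - half for off in range(-400, 401, stride)]
    elif mode == "vista":
        grid = 50
        last_in = region.length - window  # may be negative for short regions
        lo = -grid
        hi = (last_in // grid) * grid + grid if last_in >= 0 else grid
        for off in range(lo, hi + 1, grid):
            w_start = region.start + off
            overlap = min(region.end, w_start + window) - max(region.start, w_start)
            if overlap >= 950:
                starts.append(w_start)
    else:
        raise ValueError(f"unknown tiling mode {mode!r}")

    out, dropped = [], 0
    for s in starts:
        if s < 0 or (chrom_length is not None and s + window > chrom_length):
            dropped += 1
            continue
        out.append(replace(region, start=s, end=s + window))
    if dropped:
        warnings.warn(f"{dropped} window(s) dropped at chromosome boundary", stacklevel=2)
    return out


def filter_vista_table(table: pd.DataFrame, max_length: int = 5000) -> pd.DataFrame:
    """Drop mutant variants and elements longer than ``max_length`` from a
    VISTA-style activity table (columns id, chrom, start, end, ...)."""
    keep = (table["end"] - table["start"]) <= max_length
    if "id" in table.columns:
        keep &= ~table["id"].astype(str).str.contains("mut", case=False, regex=False)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# signal scaling and control sampling


def scale_and_filter_signal(signal: pd.DataFrame, percentile: float = 99.95) -> tuple[pd.DataFrame, list]:
    """CPM-style log2 scaling per tissue plus outlier removal.

    ``signal``: region x tissue matrix of mean signals (>= 0).  Returns the
    scaled matrix and the ids of regions whose scaled value strictly exceeds
    the per-tissue ``percentile`` in any tissue.
    """
    if (signal.to_numpy() < 0).any():
        raise ValueError("signals must be >= 0")
    sums = signal.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise DegenerateNormalizationError(f"all-zero signal for tissue(s) {bad}")
    with np.errstate(divide="ignore"):
        scaled = np.log2(signal / sums * 1e6)
    cutoffs = scaled.quantile(percentile / 100.0)
    removed = scaled.index[(scaled > cutoffs).any(axis=1)]
    return scaled, list(removed)


def sample_inaccessible_controls(
    genome: Genome,
    exclusion_regions: pd.DataFrame,
    n: int,
    seed: int,
    bin_length: int = WINDOW,
    min_distance: int = MIN_GAP,
) -> pd.DataFrame:
    """Sample ``n`` contiguous bins at >= ``min_distance`` from every exclusion."""
    eligible = []
    for chrom in genome.names:
        length = genome.length(chrom)
        starts = np.arange(0, length - bin_length + 1, bin_length)
        sub = exclusion_regions[exclusion_regions["chrom"] == chrom].sort_values("start")
        if len(sub):
            ex_start = sub["start"].to_numpy()
            ex_end = np.maximum.accumulate(sub["end"].to_numpy())
            ends = starts + bin_length
            nxt = np.searchsorted(ex_start, starts, side="left")
            gap_right = np.where(nxt < len(ex_start), ex_start[np.minimum(nxt, len(ex_start) - 1)] - ends, np.inf)
            prv = nxt - 1
            gap_left = np.where(prv >= 0, starts - ex_end[np.maximum(prv, 0)], np.inf)
            dist = np.minimum(gap_left, gap_right)
            keep = dist >= min_distance
        else:
            keep = np.ones(len(starts), dtype=bool)
        for s in starts[keep]:
            eligible.append((chrom, int(s)))
    if len(eligible) < n:
        raise CapacityError(f"only {len(eligible)} eligible control bins, {n} requested")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    rows = [eligible[i] for i in sorted(idx)]
    return pd.DataFrame(
        {
            "region_id": [f"control_{i:06d}" for i in range(len(rows))],
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[1] + bin_length for r in rows],
            "strand": "+",
            "source": "control",
        }
    )


# ---------------------------------------------------------------------------
# fold assignment


def assign_folds(
    regions: pd.DataFrame,
    n_folds: int = 20,
    min_gap: int = MIN_GAP,
    holdout_chrom: str | None = None,
) -> FoldAssignment:
    """Group gap-linked regions into blocks; greedily balance blocks over folds.

    Regions closer than ``min_gap`` on the same chromosome share a block and
    therefore a fold; every region on ``holdout_chrom`` maps to 'holdout'.
    """
    df = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    blocks: list[list[str]] = []
    holdout_ids: list[str] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        if chrom == holdout_chrom:
            holdout_ids.extend(sub["region_id"])
            continue
        prev_end = None
        for row in sub.itertuples(index=False):
            if prev_end is None or row.start - prev_end >= min_gap:
                blocks.append([])
            blocks[-1].append(row.region_id)
            prev_end = max(prev_end or row.end, row.end)
    if len(blocks) < n_folds:
        raise InfeasiblePartitionError(f"{len(blocks)} blocks cannot fill {n_folds} folds")

    mapping: dict[str, int | str] = {rid: HOLDOUT for rid in holdout_ids}
    sizes = np.zeros(n_folds, dtype=int)
    for block in sorted(blocks, key=len, reverse=True):  # largest first, stable
        fold = int(np.argmin(sizes))
        sizes[fold] += len(block)
        for rid in block:
            mapping[rid] = fold + 1
    return FoldAssignment(mapping=mapping, holdout_chrom=holdout_chrom or "", n_folds=n_folds)


# ---------------------------------------------------------------------------
# encoding, augmentation, balancing


def encode_dataset(
    windows: pd.DataFrame,
    genome: Genome,
    task: str,
    signal_track: SignalTrack | None = None,
    activity: dict[str, int] | pd.Series | None = None,
    max_n_fraction: float = 0.1,
) -> EncodedDataset:
    """One-hot encode 1,001 bp windows and attach task targets.

    accessibility: target = log2(mean signal over window + 1).
    activity:      target = the window's region-level binary label.
    Windows with more than ``max_n_fraction`` N bases are dropped.
    """
    if task not in ("accessibility", "activity"):
        raise ValueError(f"unknown task {task!r}")
    if task == "accessibility" and signal_track is None:
        raise ValueError("accessibility task needs a signal track")
    if task == "activity" and activity is None:
        raise ValueError("activity task needs region labels")

    xs, ys, fold_list, prov_rows = [], [], [], []
    for row in windows.itertuples(index=False):
        if row.end - row.start != WINDOW:
            raise ValueError(f"window {row.chrom}:{row.start}-{row.end} is not {WINDOW} bp")
        mat = one_hot(genome.fetch_codes(row.chrom, row.start, row.end))
        if (mat.sum(axis=1) == 0).mean() > max_n_fraction:
            continue
        strand = getattr(row, "strand", "+")
        if strand == "-":
            mat = reverse_complement_one_hot(mat)
        if task == "accessibility":
            target = np.log2(signal_track.mean(row.chrom, row.start, row.end) + 1.0)
        else:
            target = float(activity[row.region_id])
        xs.append(mat)
        ys.append(target)
        fold_list.append(getattr(row, "fold", None))
        prov_rows.append((row.region_id, row.chrom, row.start, row.end, strand))
    prov = pd.DataFrame(prov_rows, columns=["region_id", "chrom", "start", "end", "strand"])
    X = np.stack(xs).astype(np.float32) if xs else np.zeros((0, WINDOW, 4), dtype=np.float32)
    return EncodedDataset(X, np.asarray(ys, dtype=float), np.asarray(fold_list, dtype=object), prov)


def reverse_complement_dataset(ds: EncodedDataset) -> EncodedDataset:
    X = ds.X[:, ::-1, ::-1].copy()
    prov = ds.provenance.copy()
    prov["strand"] = prov["strand"].map({"+": "-", "-": "+"})
    return EncodedDataset(X, ds.y.copy(), ds.folds.copy(), prov)


def augment_reverse_complement(ds: EncodedDataset) -> EncodedDataset:
    """Add a reverse-complement twin of every sequence (fold-preserving)."""
    return EncodedDataset.concatenate([ds, reverse_complement_dataset(ds)])


def augment_and_balance(
    positives: EncodedDataset,
    negatives: EncodedDataset,
    neg_ratio: float = 1.5,
    seed: int = 0,
) -> EncodedDataset:
    """RC-augment both sets, then down-sample negatives to ``neg_ratio`` x
    the augmented positives, stratified by fold."""
    pos = augment_reverse_complement(positives)
    neg = augment_reverse_complement(negatives)
    n_wanted = int(neg_ratio * len(pos))
    if len(neg) <= n_wanted:
        if len(neg) < n_wanted:
            warnings.warn(f"only {len(neg)} negatives available, {n_wanted} wanted; using all", stacklevel=2)
        return EncodedDataset.concatenate([pos, neg])

    rng = np.random.default_rng(seed)
    fold_values = pd.Series(neg.folds)
    # proportional allocation per fold, largest remainder
    counts = fold_values.value_counts()
    exact = counts / counts.sum() * n_wanted
    alloc = exact.astype(int)
    remainder = (exact - alloc).sort_values(ascending=False)
    for fold in remainder.index[: n_wanted - int(alloc.sum())]:
        alloc[fold] += 1
    keep_idx: list[np.ndarray] = []
    for fold, n_keep in alloc.items():
        idx = np.flatnonzero(fold_values.to_numpy() == fold)
        keep_idx.append(rng.choice(idx, size=min(n_keep, len(idx)), replace=False))
    keep = np.sort(np.concatenate(keep_idx))
    return EncodedDataset.concatenate([pos, neg.subset(keep)])
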