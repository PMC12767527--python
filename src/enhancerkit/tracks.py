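"""bedGraph-backed signal tracks.

bedGraph is the canonical interchange format here: plain text, 0-based
half-open intervals, one value per interval.  Uncovered bases have value 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SignalTrack:
    """Piecewise-constant signal per chromosome (sorted, non-overlapping)."""

    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)  # columns start, end, value

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "SignalTrack":
        track = cls()
        for chrom, sub in records.groupby("chrom", sort=True):
            sub = sub.sort_values("start").reset_index(drop=True)
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            track.intervals[chrom] = sub[["start", "end", "value"]]
        return track

    @classmethod
    def read_bedgraph(cls, path: str | os.PathLike) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        return cls.from_records(df)

    def write_bedgraph(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                sub = self.intervals[chrom]
                for start, end, value in sub.itertuples(index=False):
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")

    @classmethod
    def read_bigwig(cls, path: str | os.PathLike) -> "SignalTrack":
        """Optional bigWig reader (requires pyBigWig); bedGraph remains the
        canonical interchange format."""
        import pyBigWig

        bw = pyBigWig.open(str(path))
        rows = []
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                rows.append((chrom, start, end, value))
        bw.close()
        return cls.from_records(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Base-weighted mean signal over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty interval")
        if chrom not in self.intervals:
            return 0.0
        sub = self.intervals[chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        v = sub["value"].to_numpy()
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return 0.0
        overlap = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float((overlap * v[lo:hi]).sum() / (end - start))

    def means(self, windows: pd.DataFrame) -> np.ndarray:
        """Vector of means for a DataFrame with chrom/start/end columns."""
        return np.array([self.mean(c, s, e) for c, s, e in windows[["chrom", "start", "end"]].itertuples(index=False)])


def write_per_base_bedgraph(path: str | os.PathLike, chrom: str, values: np.ndarray, offset: int = 0) -> None:
    """Run-length-encode a per-base vector into bedGraph lines (NaN bases skipped)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        run_start = None
        run_val = None
        for i, val in enumerate(np.append(values, np.nan)):
            if run_val is not None and (np.isnan(val) or val != run_val):
                fh.write(f"{chrom}\t{offset + run_start}\t{offset + i}\t{run_val:.6g}\n")
                run_start, run_val = None, None
            if run_val is None and not np.isnan(val):
                run_start, run_val = i, val
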