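"""Genomic window grids.

All per-window vectors in the package (coverage, deviation, SNP counts)
are indexed against a :class:`WindowGrid`: an ordered, non-overlapping
tiling of each chromosome into fixed-size bins (0-based, half-open).
The last window of a chromosome may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WindowGrid"]


@dataclass(frozen=True)
class WindowGrid:
    """Ordered tiling of chromosomes into genomic windows.

    Parameters
    ----------
    windows : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end`` (0-based half-open),
        sorted by chromosome then start, tiling each chromosome.
    """

    windows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        w = self.windows
        required = {"chrom", "start", "end"}
        if not required.issubset(w.columns):
            raise ValueError(f"window table needs columns {sorted(required)}")
        if len(w) == 0:
            raise ValueError("empty window grid")
        if (w["end"] <= w["start"]).any():
            raise ValueError("windows must satisfy end > start")
        for _, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError("windows must be sorted within chromosome")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError("windows must tile the chromosome without gaps")

    @classmethod
    def from_chrom_lengths(
        cls, chrom_lengths: dict[str, int], window_size: int = 1_000_000
    ) -> "WindowGrid":
        """Tile each chromosome into ``window_size`` bins."""
        if window_size <= 0:
            raise ValueError("window_size must be positive")
        rows = []
        for chrom, length in chrom_lengths.items():
            if length < window_size:
                raise ValueError(
                    f"chromosome {chrom} shorter than one window ({length} < {window_size})"
                )
            starts = np.arange(0, length, window_size)
            ends = np.minimum(starts + window_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return cls(pd.concat(rows, ignore_index=True))

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.windows["chrom"]))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Global window indices belonging to ``chrom``, in order."""
        return np.flatnonzero((self.windows["chrom"] == chrom).to_numpy())

    def locate(self, chrom: str, pos: int) -> int:
        """Global index of the window containing 1-based position ``pos``."""
        grp = self.windows[self.windows["chrom"] == chrom]
        if grp.empty:
            raise KeyError(f"unknown chromosome {chrom!r}")
        zero_based = pos - 1
        hit = grp[(grp["start"] <= zero_based) & (zero_based < grp["end"])]
        if hit.empty:
            raise ValueError(f"position {chrom}:{pos} outside the grid")
        return int(hit.index[0])

    def locate_many(self, chroms: pd.Series, pos: pd.Series) -> np.ndarray:
        """Vectorised :meth:`locate` for 1-based positions."""
        w = self.windows
        out = np.full(len(chroms), -1, dtype=int)
        zero_based = pos.to_numpy() - 1
        for chrom, grp in w.groupby("chrom", sort=False):
            sel = (chroms == chrom).to_numpy()
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            idx = np.searchsorted(starts, zero_based[sel], side="right") - 1
            ok = (idx >= 0) & (zero_based[sel] < grp["end"].to_numpy()[np.clip(idx, 0, None)])
            global_idx = grp.index.to_numpy()[np.clip(idx, 0, None)]
            res = np.where(ok, global_idx, -1)
            out[sel] = res
        if (out < 0).any():
            bad = int(np.flatnonzero(out < 0)[0])
            raise ValueError(
                f"position {chroms.iloc[bad]}:{int(pos.iloc[bad])} outside the grid"
            )
        return out

    def to_bed(self) -> pd.DataFrame:
        return self.windows[["chrom", "start", "end"]].copy()
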