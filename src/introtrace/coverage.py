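"""Windowed mapping-coverage deviation.

Introgressed chromosome segments from a wild relative diverge from the
reference genome, so short reads from those segments map poorly and the
windowed read count of a carrier line drops below the rest of the panel.
This module turns raw per-window read counts into a normalized
*coverage deviation* statistic and flags windows whose deviation is a
significant outlier.

For line *l* with normalized count ``c_i`` in window *i* and panel
median ``m_i``, the deviation is

    d_i = c_i / (m_i * eps)

where ``eps`` is the line's median of ``c_i / m_i`` over non-masked
windows, so the genome-wide median of ``d`` is exactly 1.  Windows with
``m_i = 0`` are masked: they contribute to nothing downstream.

Significance uses the MAD z-score ``z_i = (d_i - median(d)) /
(1.4826 * MAD(d))`` with a two-sided normal quantile at the requested
probability; only *low* flags count as introgression evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowGrid

__all__ = [
    "DeviationProfile",
    "normalize_counts",
    "deviation_profile",
    "deviation_table",
    "flag_outliers",
]

MAD_CONSISTENCY = 1.4826  # normal-consistency constant for the MAD scale


@dataclass
class DeviationProfile:
    """Per-line coverage-deviation profile on a shared window grid.

    Attributes
    ----------
    line : str
        Panel line identifier.
    c : numpy.ndarray
        Normalized counts per window.
    m : numpy.ndarray
        Panel median normalized count per window.
    epsilon : float
        Per-line scaling factor: median of ``c/m`` over non-masked windows.
    d : numpy.ndarray
        Coverage deviation per window (NaN where masked).
    masked : numpy.ndarray
        Boolean mask, True where the panel median is zero.
    z : numpy.ndarray | None
        MAD z-scores (set by :func:`flag_outliers`).
    flag : numpy.ndarray | None
        Per-window flag ``{"low", "high", "none"}``.
    grid : WindowGrid | None
        The window grid the profile is indexed against.
    """

    line: str
    c: np.ndarray
    m: np.ndarray
    epsilon: float
    d: np.ndarray
    masked: np.ndarray
    z: np.ndarray | None = None
    flag: np.ndarray | None = None
    grid: WindowGrid | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "line": self.line,
                "c": self.c,
                "m": self.m,
                "epsilon": self.epsilon,
                "d": self.d,
            }
        )
        if self.z is not None:
            df["z"] = self.z
            df["flag"] = self.flag
        if self.grid is not None:
            df.insert(1, "chrom", self.grid.windows["chrom"].to_numpy())
            df.insert(2, "start", self.grid.windows["start"].to_numpy())
            df.insert(3, "end", self.grid.windows["end"].to_numpy())
        return df


def normalize_counts(raw: pd.DataFrame, mapped_totals: pd.Series) -> pd.DataFrame:
    """Divide each line's raw window counts by its total mapped reads.

    Parameters
    ----------
    raw : pandas.DataFrame
        Lines x windows matrix of raw read counts (index = line names).
    mapped_totals : pandas.Series
        Total filtered mapped reads per line (index matching ``raw``).

    Returns
    -------
    pandas.DataFrame
        Normalized counts ``c`` with the same shape and ordering.
    """
    totals = mapped_totals.reindex(raw.index)
    bad = totals.index[(totals.isna()) | (totals <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive or missing mapped-read total for line(s): {list(bad)}"
        )
    return raw.div(totals, axis=0)


def _panel_median(c: pd.DataFrame) -> np.ndarray:
    if len(c) < 3:
        raise ValueError("panel must contain at least 3 lines for a meaningful median")
    return c.median(axis=0).to_numpy()


def deviation_profile(
    c: pd.DataFrame, line: str, grid: WindowGrid | None = None
) -> DeviationProfile:
    """Compute one line's coverage-deviation profile against the panel.

    ``c`` is the full panel's normalized count matrix; the panel median
    per window and the line's scaling factor are derived from it.
    """
    m = _panel_median(c)
    row = c.loc[line].to_numpy(dtype=float)
    masked = m == 0
    if masked.all():
        raise ValueError("all windows masked (panel median zero everywhere)")
    ratio = np.full_like(row, np.nan)
    ratio[~masked] = row[~masked] / m[~masked]
    epsilon = float(np.median(ratio[~masked]))
    if epsilon == 0:
        raise ValueError(f"line {line!r} has zero median coverage ratio")
    d = ratio / epsilon
    return DeviationProfile(
        line=line, c=row, m=m, epsilon=epsilon, d=d, masked=masked, grid=grid
    )


def deviation_table(
    c: pd.DataFrame, grid: WindowGrid | None = None, prob: float = 0.99
) -> dict[str, DeviationProfile]:
    """Deviation profiles, with outlier flags, for every line of the panel."""
    out = {}
    for line in c.index:
        prof = deviation_profile(c, line, grid=grid)
        flag_outliers(prof, prob=prob)
        out[line] = prof
    return out


def flag_outliers(profile: DeviationProfile, prob: float = 0.99) -> DeviationProfile:
    """Flag windows whose deviation is a MAD outlier at probability ``prob``.

    Mutates and returns ``profile`` with ``z`` and ``flag`` filled in.
    Only "low" flags are treated as introgression evidence downstream;
    "high" flags are retained for QC.
    """
    d = profile.d
    valid = ~profile.masked
    if valid.sum() < 5:
        raise ValueError("need at least 5 non-masked windows to flag outliers")
    dv = d[valid]
    med = np.median(dv)
    mad = np.median(np.abs(dv - med))
    if mad == 0:
        raise ValueError(
            "MAD of deviation is zero; windows carry no spread "
            "(consider coarser windows)"
        )
    z = np.full_like(d, np.nan)
    z[valid] = (dv - med) / (MAD_CONSISTENCY * mad)
    thresh = stats.norm.ppf(prob)
    flag = np.full(d.shape, "none", dtype=object)
    flag[valid & (z < -thresh)] = "low"
    flag[valid & (z > thresh)] = "high"
    profile.z = z
    profile.flag = flag
    return profile
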