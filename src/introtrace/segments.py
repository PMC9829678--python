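"""Introgression segment calling, zygosity assignment and core regions.

A window is *evidence* for introgression when its coverage deviation is
flagged as a significant low outlier or its donor-SNP enrichment ratio
is retained.  Maximal runs of evidence windows are merged into blocks,
bridging short gaps when the bridged window still carries donor SNPs —
donor sequence nearly identical to the host reference maps well enough
that some windows inside a true block show no coverage deficit.  A
block is kept when it has enough evidence windows and most of its
windows are low-flagged.

Zygosity of a called segment: a heterozygous introgression carries the
donor haplotype on one homologue only, so its coverage deficit is
intermediate and its matched donor SNPs are heterozygous.

The *core region* of a focal marker is the interval present in every
carrier's segments and absent from every excluded line's: the
intersection over carriers of their segment unions, minus the union of
excluded lines' segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .coverage import DeviationProfile
from .windows import WindowGrid

__all__ = [
    "CallParams",
    "IntrogressionSegment",
    "CoreRegion",
    "call_blocks",
    "assign_zygosity",
    "core_region",
    "segment_report",
]


@dataclass(frozen=True)
class CallParams:
    """Tunables for block calling and zygosity assignment.

    gap_windows : maximum run of non-evidence windows bridged inside a
        block, provided every bridged window has >= 1 donor SNP.
    min_windows : minimum number of evidence windows per block.
    het_d_threshold : segment mean deviation at or above which the
        coverage criterion votes heterozygous (midway between the ~0.5
        expected for homozygous and 1.0 for no introgression).
    het_snp_fraction : minimum heterozygous fraction of matched donor
        SNPs for the SNP criterion to vote heterozygous.
    """

    gap_windows: int = 2
    min_windows: int = 3
    het_d_threshold: float = 0.65
    het_snp_fraction: float = 0.5


@dataclass
class IntrogressionSegment:
    """A called donor block in one line (0-based half-open, window-aligned)."""

    line: str
    chrom: str
    start: int
    end: int
    donor: str
    zygosity: str = "hom"
    n_low_windows: int = 0
    n_snp_windows: int = 0
    mean_d: float = float("nan")
    het_snp_fraction: float = float("nan")
    window_span: tuple[int, int] = field(default=(0, 0), repr=False)  # chrom-local

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CoreRegion:
    chrom: str
    start: int
    end: int
    carriers: list[str]
    excluded: list[str]
    marker: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _runs_with_bridging(
    evidence: np.ndarray, bridgeable: np.ndarray, gap_windows: int
) -> list[tuple[int, int]]:
    """Maximal evidence runs, merging across gaps of <= gap_windows
    whose every window is bridgeable. Returns half-open index spans."""
    idx = np.flatnonzero(evidence)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        gap = np.arange(prev + 1, i)
        if len(gap) <= gap_windows and bool(bridgeable[gap].all() if len(gap) else True):
            prev = i
            continue
        runs.append((start, prev + 1))
        start = prev = i
    runs.append((start, prev + 1))
    return runs


def call_blocks(
    dev: DeviationProfile,
    ratio: pd.DataFrame,
    grid: WindowGrid,
    params: CallParams = CallParams(),
    matched_snps: pd.DataFrame | None = None,
) -> list[IntrogressionSegment]:
    """Call introgression blocks for one line.

    Parameters
    ----------
    dev : DeviationProfile
        Flagged deviation profile of the line (see
        :func:`introtrace.coverage.flag_outliers`).
    ratio : pandas.DataFrame
        This line's rows of the SNP-ratio profile (columns ``window,
        count, het_count, ratio, retained``), on the same grid.
    grid : WindowGrid
        Shared window grid.
    params : CallParams
    matched_snps : pandas.DataFrame, optional
        This line's matched donor SNPs (for donor labelling and
        zygosity); when absent the dominant donor label in ``ratio``
        is unavailable and segments are labelled "unknown".
    """
    if dev.flag is None:
        raise ValueError("deviation profile has no outlier flags; run flag_outliers")
    if len(dev.d) != len(grid):
        raise ValueError("deviation profile and window grid sizes differ")
    n_win = len(grid)
    low = np.asarray(dev.flag == "low") & ~dev.masked
    retained = np.zeros(n_win, dtype=bool)
    snp_count = np.zeros(n_win, dtype=int)
    r = ratio.set_index("window")
    retained[r.index.to_numpy()] = r["retained"].to_numpy(dtype=bool)
    snp_count[r.index.to_numpy()] = r["count"].to_numpy(dtype=int)

    segments: list[IntrogressionSegment] = []
    for chrom in grid.chroms:
        widx = grid.chrom_slice(chrom)
        ev = (low | retained)[widx]
        low_c = low[widx]
        bridge = snp_count[widx] >= 1
        for s_local, e_local in _runs_with_bridging(ev, bridge, params.gap_windows):
            # retained-SNP windows are interior evidence only: donor SNPs
            # rescue well-mapping windows *within* a run of low-coverage
            # windows, so block boundaries must themselves be low-flagged
            while s_local < e_local and not low_c[s_local]:
                s_local += 1
            while e_local > s_local and not low_c[e_local - 1]:
                e_local -= 1
            if e_local <= s_local:
                continue
            span = widx[s_local : e_local]
            n_evidence = int(ev[s_local:e_local].sum())
            if n_evidence < params.min_windows:
                continue
            n_low = int(low[span].sum())
            if n_low <= len(span) / 2:  # most windows must show the coverage deficit
                continue
            d_seg = dev.d[span]
            seg = IntrogressionSegment(
                line=dev.line,
                chrom=chrom,
                start=int(grid.windows["start"].iloc[span[0]]),
                end=int(grid.windows["end"].iloc[span[-1]]),
                donor=_dominant_donor(matched_snps, grid, span),
                n_low_windows=n_low,
                n_snp_windows=int((snp_count[span] > 0).sum()),
                mean_d=float(np.nanmean(d_seg)),
                window_span=(s_local, e_local),
            )
            assign_zygosity(seg, dev, matched_snps, grid, params)
            segments.append(seg)
    return segments


def _dominant_donor(
    matched_snps: pd.DataFrame | None, grid: WindowGrid, span: np.ndarray
) -> str:
    if matched_snps is None or len(matched_snps) == 0 or "donor" not in matched_snps:
        return "unknown"
    widx = grid.locate_many(matched_snps["chrom"], matched_snps["pos"])
    inside = np.isin(widx, span)
    if not inside.any():
        return "unknown"
    return matched_snps.loc[inside, "donor"].mode().iloc[0]


def assign_zygosity(
    segment: IntrogressionSegment,
    dev: DeviationProfile,
    matched_snps: pd.DataFrame | None,
    grid: WindowGrid,
    params: CallParams = CallParams(),
) -> str:
    """Assign hom/het zygosity to a called segment (mutates ``segment``).

    Heterozygous requires both the intermediate coverage deficit
    (mean d >= ``het_d_threshold``) and a heterozygous majority of the
    matched donor SNPs inside the segment; with no matched SNPs the
    coverage criterion decides alone (with a warning).
    """
    mean_d = segment.mean_d
    het_frac = float("nan")
    if matched_snps is not None and len(matched_snps):
        widx = grid.locate_many(matched_snps["chrom"], matched_snps["pos"])
        span_start = grid.locate(segment.chrom, segment.start + 1)
        span_end = grid.locate(segment.chrom, segment.end)  # last covered pos
        inside = (widx >= span_start) & (widx <= span_end)
        sub = matched_snps[inside]
        if len(sub):
            het_frac = float((sub["gt"] == "het").mean())
    if np.isnan(het_frac):
        warnings.warn(
            f"no matched donor SNPs in segment {segment.chrom}:{segment.start}-"
            f"{segment.end} of {segment.line}; zygosity from coverage alone"
        )
        zyg = "het" if mean_d >= params.het_d_threshold else "hom"
    else:
        zyg = (
            "het"
            if (mean_d >= params.het_d_threshold and het_frac >= params.het_snp_fraction)
            else "hom"
        )
    segment.zygosity = zyg
    segment.het_snp_fraction = het_frac
    return zyg


def core_region(
    segments_by_line: dict[str, list[IntrogressionSegment]],
    carriers: list[str],
    excluded: list[str],
    chrom: str,
    marker: str | None = None,
) -> CoreRegion | None:
    """Largest interval shared by all carriers and absent from excluded lines.

    Intersection over carriers of the union of their segments on
    ``chrom``, minus every interval overlapping an excluded line's
    segment; the largest remaining interval is returned (``None`` when
    the result is empty, a valid outcome).
    """
    core: list[tuple[int, int]] | None = None
    for line in carriers:
        segs = [
            s.interval() for s in segments_by_line.get(line, []) if s.chrom == chrom
        ]
        if not segs:
            raise ValueError(
                f"carrier {line!r} has no segment on {chrom}; contradicts carrier status"
            )
        union = iv.merge(segs)
        core = union if core is None else iv.intersect(core, union)
    if not core:
        return None
    excluded_ivs = [
        s.interval()
        for line in excluded
        for s in segments_by_line.get(line, [])
        if s.chrom == chrom
    ]
    remaining = iv.subtract(core, iv.merge(excluded_ivs)) if excluded_ivs else core
    if not remaining:
        return None
    start, end = max(remaining, key=lambda t: t[1] - t[0])
    return CoreRegion(
        chrom=chrom,
        start=start,
        end=end,
        carriers=list(carriers),
        excluded=list(excluded),
        marker=marker,
    )


def segment_report(
    segments: list[IntrogressionSegment],
    truth: list[IntrogressionSegment] | None = None,
    window_size: int = 1_000_000,
) -> dict:
    """Per-line segment summary, plus recovery metrics against a truth set.

    A truth segment is *recovered* when a called segment of the same
    line and chromosome overlaps it; its boundary error is the larger
    of the start and end discrepancies of the best-overlapping call,
    in windows.  Precision counts calls overlapping any truth segment.
    """
    table = pd.DataFrame(
        [
            {
                "line": s.line,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "donor": s.donor,
                "zygosity": s.zygosity,
                "mean_d": s.mean_d,
            }
            for s in segments
        ]
    )
    out: dict = {"table": table}
    if truth is None:
        return out
    recovered = 0
    boundary_errors = []
    for t in truth:
        overlaps = [
            s
            for s in segments
            if s.line == t.line
            and s.chrom == t.chrom
            and iv.overlap_length(s.interval(), t.interval()) > 0
        ]
        if not overlaps:
            boundary_errors.append(np.nan)
            continue
        best = max(
            overlaps, key=lambda s: iv.overlap_length(s.interval(), t.interval())
        )
        recovered += 1
        err = max(abs(best.start - t.start), abs(best.end - t.end)) / window_size
        boundary_errors.append(err)
    matched_calls = sum(
        1
        for s in segments
        if any(
            t.line == s.line
            and t.chrom == s.chrom
            and iv.overlap_length(s.interval(), t.interval()) > 0
            for t in truth
        )
    )
    zyg_correct = 0
    zyg_total = 0
    for t in truth:
        for s in segments:
            if (
                s.line == t.line
                and s.chrom == t.chrom
                and iv.overlap_length(s.interval(), t.interval()) > 0
            ):
                zyg_total += 1
                zyg_correct += int(s.zygosity == t.zygosity)
                break
    out.update(
        recall=recovered / len(truth) if truth else float("nan"),
        precision=matched_calls / len(segments) if segments else float("nan"),
        n_false_calls=len(segments) - matched_calls,
        boundary_errors=boundary_errors,
        max_boundary_error=float(np.nanmax(boundary_errors))
        if boundary_errors and not all(np.isnan(boundary_errors))
        else float("nan"),
        zygosity_accuracy=zyg_correct / zyg_total if zyg_total else float("nan"),
    )
    return out


def segments_to_bed(segments: list[IntrogressionSegment]) -> pd.DataFrame:
    """BED6 frame: name = line|donor|zygosity, score = n low windows."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "name": f"{s.line}|{s.donor}|{s.zygosity}",
                "score": s.n_low_windows,
                "strand": ".",
            }
            for s in segments
        ]
    )
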