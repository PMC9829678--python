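"""End-to-end introgression mapping on a panel bundle.

Ties together normalization, deviation profiling, SNP-ratio
computation, block calling and core-region intersection, so the whole
analysis runs with one call on either a synthetic panel or a fixture
bundle read from disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .coverage import DeviationProfile, deviation_table, normalize_counts
from .donor_snps import snp_ratio_profile
from .segments import CallParams, CoreRegion, IntrogressionSegment, core_region
from .segments import call_blocks
from .synthetic import SyntheticPanel
from .windows import WindowGrid

__all__ = ["PanelResult", "run_panel", "core_region_for_marker"]


@dataclass
class PanelResult:
    """Everything the mapping stage computes for a panel."""

    grid: WindowGrid
    profiles: dict[str, DeviationProfile]
    ratio: pd.DataFrame
    segments: list[IntrogressionSegment]
    core: CoreRegion | None = None

    def segments_by_line(self) -> dict[str, list[IntrogressionSegment]]:
        out: dict[str, list[IntrogressionSegment]] = {}
        for seg in self.segments:
            out.setdefault(seg.line, []).append(seg)
        return out


def run_panel(
    panel: SyntheticPanel,
    params: CallParams = CallParams(),
    prob: float = 0.99,
) -> PanelResult:
    """Run coverage deviation + SNP enrichment + segment calling."""
    counts = panel.counts
    totals = counts.sum(axis=1)
    c = normalize_counts(counts, totals)
    profiles = deviation_table(c, grid=panel.grid, prob=prob)
    lines = list(counts.index)
    ratio = snp_ratio_profile(panel.snps, panel.grid, lines)
    ratio_by_line = dict(tuple(ratio.groupby("line", sort=False)))
    snps_by_line = (
        dict(tuple(panel.snps.groupby("line", sort=False)))
        if len(panel.snps)
        else {}
    )
    segments: list[IntrogressionSegment] = []
    empty_ratio = ratio.iloc[0:0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-segment zygosity warnings
        for line in lines:
            segs = call_blocks(
                profiles[line],
                ratio_by_line.get(line, empty_ratio),
                panel.grid,
                params,
                matched_snps=snps_by_line.get(line),
            )
            segments.extend(segs)
    return PanelResult(grid=panel.grid, profiles=profiles, ratio=ratio, segments=segments)


def core_region_for_marker(
    result: PanelResult,
    markers: pd.DataFrame,
    focal_marker: str,
    fav_allele: str,
    chrom: str,
    marker_pos: int | None = None,
) -> CoreRegion | None:
    """Core region across carriers of a focal marker's favourable allele.

    Carriers are lines whose genotype at ``focal_marker`` contains the
    favourable allele (homozygous or heterozygous); excluded lines are
    all non-carriers with a called segment on ``chrom``.  A carrier
    with no called segment overlapping the marker position contradicts
    its genotype (an under-called segment or a genotyping error); such
    lines are dropped from the intersection with a warning rather than
    voiding the core.  ``marker_pos`` defaults to the position encoded
    in the marker id (``<chrom>-<pos>``).
    """
    if marker_pos is None:
        try:
            marker_pos = int(focal_marker.rsplit("-", 1)[1])
        except (IndexError, ValueError):
            raise ValueError(
                f"cannot parse position from marker id {focal_marker!r}; "
                "give marker_pos explicitly"
            )
    geno = markers[markers["marker"] == focal_marker].set_index("line")["allele"]
    is_carrier = geno.astype(str).str.contains(fav_allele)
    carriers = list(geno.index[is_carrier])
    by_line = result.segments_by_line()
    covering = [
        line
        for line in carriers
        if any(
            s.chrom == chrom and s.start <= marker_pos - 1 < s.end
            for s in by_line.get(line, [])
        )
    ]
    discordant = sorted(set(carriers) - set(covering))
    if discordant:
        warnings.warn(
            f"carrier line(s) without a called segment at {chrom}:{marker_pos}: "
            f"{discordant}; dropped from the core intersection"
        )
    if not covering:
        raise ValueError(f"no carrier has a called segment at {chrom}:{marker_pos}")
    excluded = [
        line
        for line in geno.index[~is_carrier]
        if any(s.chrom == chrom for s in by_line.get(line, []))
    ]
    core = core_region(by_line, covering, excluded, chrom, marker=focal_marker)
    if core is not None:
        core.excluded = excluded
    return core
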