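"""Donor-species-specific SNP sets and per-window enrichment ratios.

A SNP private to one wild-relative donor species (present in at least
one of its accessions, absent from every accession of every other donor
and from every wheat cultivar) evidences donor ancestry wherever a
panel line carries it.  The per-window *SNP ratio* — a line's matched
donor-SNP count divided by the panel mean for that window — highlights
windows where one line is enriched for donor alleles; ratios below the
enrichment cutoff (1.45) are dropped from evidence.

Also houses the panel genotype filters applied upstream of association
analyses (het/quality/depth call filters; missing-data and MAF locus
filters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import WindowGrid

__all__ = [
    "DonorSNPSet",
    "filter_accession_snps",
    "derive_species_specific",
    "match_panel_snps",
    "snp_ratio_profile",
    "filter_panel_genotypes",
]

SNP_RATIO_CUTOFF = 1.45  # ratios below this are removed from evidence

# retention rules for accession SNP calls
HOM_ALT_READS = (10, 60)
HOM_MIN_AF = 0.8
HET_TOTAL_READS = (10, 60)
HET_MIN_ALLELE_READS = 5
HET_MIN_AF = 0.3


@dataclass(frozen=True)
class DonorSNPSet:
    """SNPs private to one donor species: sorted set of (chrom, pos, alt)."""

    donor: str
    snps: frozenset[tuple[str, int, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.snps)
        return pd.DataFrame(rows, columns=["chrom", "pos", "alt"]).assign(
            donor=self.donor
        )

    def __len__(self) -> int:
        return len(self.snps)


def filter_accession_snps(snps: pd.DataFrame) -> pd.DataFrame:
    """Apply per-accession SNP retention rules.

    Homozygous calls are kept with 10-60 reads supporting the
    alternative allele and allele frequency >= 0.8.  Heterozygous calls
    are kept with 10-60 total reads, both alleles supported by >= 5
    reads, and allele frequency >= 0.3.

    ``snps`` needs columns ``chrom, pos, ref, alt, gt, alt_reads,
    total_reads, af`` with ``gt`` in {"hom", "het"}.
    """
    bad_gt = ~snps["gt"].isin(["hom", "het"])
    if bad_gt.any():
        first = snps.loc[bad_gt].iloc[0]
        raise ValueError(
            f"malformed genotype class {first['gt']!r} at {first['chrom']}:{first['pos']}"
        )
    hom = snps["gt"] == "hom"
    keep_hom = (
        hom
        & snps["alt_reads"].between(*HOM_ALT_READS)
        & (snps["af"] >= HOM_MIN_AF)
    )
    ref_reads = snps["total_reads"] - snps["alt_reads"]
    keep_het = (
        ~hom
        & snps["total_reads"].between(*HET_TOTAL_READS)
        & (snps["alt_reads"] >= HET_MIN_ALLELE_READS)
        & (ref_reads >= HET_MIN_ALLELE_READS)
        & (snps["af"] >= HET_MIN_AF)
    )
    return snps[keep_hom | keep_het].reset_index(drop=True)


def _as_key_set(df: pd.DataFrame) -> set[tuple[str, int, str]]:
    return set(zip(df["chrom"], df["pos"].astype(int), df["alt"]))


def derive_species_specific(
    accession_snps: dict[str, list[pd.DataFrame]],
    wheat_cultivar_snps: list[pd.DataFrame] | None = None,
) -> dict[str, DonorSNPSet]:
    """Derive the SNP set private to each donor species.

    Parameters
    ----------
    accession_snps : dict
        Donor label -> list of filtered per-accession SNP tables
        (columns ``chrom, pos, alt`` at minimum).
    wheat_cultivar_snps : list of DataFrame, optional
        SNP tables of wheat cultivars; any SNP seen in one is excluded
        from every donor set.

    Returns
    -------
    dict mapping donor label -> :class:`DonorSNPSet`.  Sets are pairwise
    disjoint by construction.
    """
    for donor, tables in accession_snps.items():
        if len(tables) == 0:
            raise ValueError(f"donor {donor!r} has no accessions")
    union_by_donor = {
        donor: set().union(*(_as_key_set(t) for t in tables))
        for donor, tables in accession_snps.items()
    }
    wheat = set()
    for t in wheat_cultivar_snps or []:
        wheat |= _as_key_set(t)
    out = {}
    for donor, snps in union_by_donor.items():
        others = set().union(
            *(s for d, s in union_by_donor.items() if d != donor), wheat
        )
        out[donor] = DonorSNPSet(donor=donor, snps=frozenset(snps - others))
    return out


def match_panel_snps(
    panel_snps: pd.DataFrame, donor_set: DonorSNPSet
) -> pd.DataFrame:
    """Match panel-line SNPs into a donor-specific set.

    A panel SNP matches iff (chrom, pos, alt) is identical; the
    genotype class (hom/het) is carried through for zygosity inference.
    Multi-allelic alt fields (comma-separated) are decomposed into
    biallelic records before matching.
    """
    df = panel_snps.copy()
    if df["alt"].astype(str).str.contains(",").any():
        df = df.assign(alt=df["alt"].astype(str).str.split(",")).explode(
            "alt", ignore_index=True
        )
    keys = list(zip(df["chrom"], df["pos"].astype(int), df["alt"]))
    hit = np.fromiter((k in donor_set.snps for k in keys), dtype=bool, count=len(keys))
    out = df[hit].reset_index(drop=True)
    out["donor"] = donor_set.donor
    return out


def snp_ratio_profile(
    matched: pd.DataFrame,
    grid: WindowGrid,
    lines: list[str],
    cutoff: float = SNP_RATIO_CUTOFF,
    hom_only: bool = False,
) -> pd.DataFrame:
    """Per line x window donor-SNP counts, panel means and enrichment ratios.

    ``matched`` is the output of :func:`match_panel_snps` for the whole
    panel (column ``line`` present).  The panel mean for a window is
    the plain mean over all ``lines`` (zero-count lines included).  A
    row is ``retained`` iff its ratio >= ``cutoff``; windows whose
    panel mean is zero yield no evidence.

    Returns a long-format DataFrame with columns ``line, window, count,
    het_count, panel_mean, ratio, retained``; ``window`` is the global
    window index in ``grid``.
    """
    if len(lines) < 2:
        raise ValueError("need at least 2 lines for a panel mean")
    n_win = len(grid)
    line_pos = {l: i for i, l in enumerate(lines)}
    count_arr = np.zeros((len(lines), n_win), dtype=int)
    het_arr = np.zeros_like(count_arr)
    if len(matched):
        df = matched[matched["gt"] == "hom"] if hom_only else matched
        if len(df):
            widx = grid.locate_many(df["chrom"], df["pos"])
            lidx = df["line"].map(line_pos).to_numpy()
            np.add.at(count_arr, (lidx, widx), 1)
        het = matched[matched["gt"] == "het"]
        if len(het):
            widx = grid.locate_many(het["chrom"], het["pos"])
            lidx = het["line"].map(line_pos).to_numpy()
            np.add.at(het_arr, (lidx, widx), 1)
    counts = pd.DataFrame(
        count_arr, index=pd.Index(lines, name="line"), columns=range(n_win)
    )
    het_counts = pd.DataFrame(
        het_arr, index=pd.Index(lines, name="line"), columns=range(n_win)
    )
    panel_mean = counts.mean(axis=0)
    long = counts.stack().rename("count").reset_index()
    long.columns = ["line", "window", "count"]
    long["het_count"] = het_counts.stack().to_numpy()
    long["panel_mean"] = long["window"].map(panel_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            long["panel_mean"] > 0, long["count"] / long["panel_mean"], 0.0
        )
    long["ratio"] = ratio
    long["retained"] = (long["ratio"] >= cutoff) & (long["panel_mean"] > 0)
    return long


def filter_panel_genotypes(
    calls: pd.DataFrame,
    min_qual: float = 30,
    min_depth: int = 5,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Panel genotype filtering for association input.

    Per call: heterozygous calls, quality < ``min_qual`` and depth <
    ``min_depth`` are set missing; a line is asserted homozygous
    reference where >= ``min_depth`` reads map and no alternative
    allele was called.  Per locus: drop loci with more than
    ``max_missing`` missing calls or minor allele frequency below
    ``min_maf``.

    ``calls`` is long-format with columns ``line, chrom, pos, gt, qual,
    depth`` where ``gt`` in {"hom_ref", "hom_alt", "het", "missing"}.
    Returns a locus x line genotype matrix with entries in
    {0, 2, nan} (alt-allele dosage; het calls were removed).
    """
    df = calls.copy()
    dropped = (
        (df["gt"] == "het")
        | (df["qual"] < min_qual)
        | (df["depth"] < min_depth)
    )
    # hom-ref assertion needs depth only (no variant was called, so no qual)
    hom_ref = (df["gt"] == "hom_ref") & (df["depth"] >= min_depth)
    df.loc[dropped & ~hom_ref, "gt"] = "missing"
    dosage = df["gt"].map({"hom_ref": 0.0, "hom_alt": 2.0}).astype(float)
    mat = (
        df.assign(dosage=dosage)
        .pivot_table(
            index=["chrom", "pos"],
            columns="line",
            values="dosage",
            aggfunc="first",
            dropna=False,
        )
    )
    n_lines = mat.shape[1]
    missing_frac = mat.isna().sum(axis=1) / n_lines
    alt_freq = mat.mean(axis=1, skipna=True) / 2.0
    maf = np.minimum(alt_freq, 1 - alt_freq)
    keep = (missing_frac <= max_missing) & (maf >= min_maf)
    return mat[keep]
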