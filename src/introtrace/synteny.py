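"""Synteny-based interval anchoring between assemblies.

Lifts a host-genome interval (e.g. a core introgressed region on the
wheat reference) onto a donor assembly through filtered whole-genome
alignment blocks (PAF), projecting each boundary linearly through the
block that covers it, and extracts annotated genes from the anchored
donor interval.

Filter presets follow the two alignment passes used for this kind of
liftover: host-to-donor (minimum block 2.5 kb, MAPQ >= 40) and
donor-to-donor between accessions (minimum block 5 kb, MAPQ >= 40).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AnchoredInterval",
    "FILTER_PRESETS",
    "read_paf",
    "filter_alignments",
    "anchor_interval",
    "extract_genes",
]

PAF_COLUMNS = [
    "qname", "qlen", "qstart", "qend", "strand",
    "tname", "tlen", "tstart", "tend", "nmatch", "alnlen", "mapq",
]

FILTER_PRESETS = {
    "wheat_tauschii": (2500, 40),
    "tauschii_tauschii": (5000, 40),
}


@dataclass
class AnchoredInterval:
    """A host interval projected onto a donor assembly."""

    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    n_blocks: int
    anchor_type: str = "alignment"

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start


def read_paf(path) -> pd.DataFrame:
    """Read the 12 mandatory PAF columns (extra tags ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=range(12), names=PAF_COLUMNS
    )
    return df


def filter_alignments(
    blocks: pd.DataFrame,
    min_len: int | None = None,
    min_q: int | None = None,
    preset: str | None = None,
) -> pd.DataFrame:
    """Drop alignment blocks shorter than ``min_len`` or below ``min_q``.

    Either give thresholds directly or name a ``preset``
    (``wheat_tauschii``: 2500 bp / Q40; ``tauschii_tauschii``:
    5000 bp / Q40).  Retention is length >= min_len and quality >=
    min_q.
    """
    if preset is not None:
        min_len, min_q = FILTER_PRESETS[preset]
    if min_len is None or min_q is None:
        raise ValueError("give min_len and min_q, or a preset")
    if min_len < 0 or min_q < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (blocks["alnlen"] >= min_len) & (blocks["mapq"] >= min_q)
    return blocks[keep].reset_index(drop=True)


def _project(pos: int, block: pd.Series) -> float:
    """Linear projection of a query position through one block."""
    qspan = block["qend"] - block["qstart"]
    tspan = block["tend"] - block["tstart"]
    frac = (pos - block["qstart"]) / qspan
    if block["strand"] == "+":
        return block["tstart"] + frac * tspan
    return block["tend"] - frac * tspan


def _covering_block(blocks: pd.DataFrame, pos: int, side: str) -> pd.Series:
    hit = blocks[(blocks["qstart"] <= pos) & (pos < blocks["qend"])]
    if len(hit):
        # prefer the longest covering block
        return hit.loc[hit["alnlen"].idxmax()]
    # boundary falls in an alignment gap: snap to the nearest block edge
    dist_left = pos - blocks["qend"]
    dist_right = blocks["qstart"] - pos
    dist = pd.concat([dist_left, dist_right], axis=1).max(axis=1).clip(lower=0)
    nearest = blocks.loc[dist.idxmin()]
    warnings.warn(
        f"{side} boundary at {pos} lies in an alignment gap; "
        f"snapping to nearest block edge"
    )
    return nearest


def anchor_interval(
    chrom: str, start: int, end: int, blocks: pd.DataFrame
) -> AnchoredInterval:
    """Project a host interval onto the donor assembly through alignments.

    Each boundary is projected linearly through the block covering it
    (snapping to the nearest block edge when it falls in a gap).  The
    target interval is the span between the projected boundaries on the
    majority target chromosome (by aligned length among blocks
    overlapping the interval).  Block input order is irrelevant.
    """
    if end <= start:
        raise ValueError("interval end must exceed start")
    rel = blocks[blocks["qname"] == chrom]
    overlapping = rel[(rel["qstart"] < end) & (rel["qend"] > start)]
    if overlapping.empty:
        raise ValueError(f"no alignment blocks overlap {chrom}:{start}-{end}")
    weights = overlapping.groupby("tname")["alnlen"].sum()
    target_chrom = weights.idxmax()
    onto = overlapping[overlapping["tname"] == target_chrom]
    if onto.empty:
        raise ValueError("no blocks on the majority target chromosome; unanchorable")
    left_block = _covering_block(onto, start, "left")
    right_block = _covering_block(onto, max(start, end - 1), "right")
    p_left = _project(min(max(start, left_block["qstart"]), left_block["qend"]), left_block)
    p_right = _project(min(max(end, right_block["qstart"]), right_block["qend"]), right_block)
    t_start, t_end = sorted((p_left, p_right))
    return AnchoredInterval(
        source_chrom=chrom,
        source_start=start,
        source_end=end,
        target_chrom=str(target_chrom),
        target_start=int(round(t_start)),
        target_end=int(round(t_end)),
        n_blocks=len(onto),
    )


def extract_genes(anchored: AnchoredInterval, gff_path, assembly: str | None = None) -> pd.DataFrame:
    """Genes overlapping the anchored donor interval, from a GFF3 file.

    GFF3 coordinates are 1-based closed; a gene is included when its
    span intersects the (0-based half-open) target interval at all.
    ``assembly`` (when given) must match the annotation's sequence
    naming: the target chromosome must appear in the annotation.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    seqids = {f.seqid for f in db.all_features()}
    if anchored.target_chrom not in seqids:
        raise ValueError(
            f"annotation has no sequence {anchored.target_chrom!r}"
            + (f" (assembly {assembly})" if assembly else "")
        )
    rows = []
    for gene in db.features_of_type("gene"):
        if gene.seqid != anchored.target_chrom:
            continue
        g_start0, g_end0 = gene.start - 1, gene.end  # convert to half-open
        if g_start0 < anchored.target_end and g_end0 > anchored.target_start:
            rows.append(
                {
                    "gene_id": gene.id,
                    "chrom": gene.seqid,
                    "start": g_start0,
                    "end": g_end0,
                    "strand": gene.strand,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
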