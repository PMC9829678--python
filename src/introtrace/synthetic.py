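"""Synthetic wheat-panel generator.

Emulates the data structure of an enrichment-capture diversity panel
(~149 inbred lines) carrying alien introgressions from wild relatives:

* a lines x windows read-count matrix with per-line sequencing depth,
  per-window mappability shared across lines, and negative-binomial
  overdispersion; windows inside a planted donor segment have their
  expected count multiplied by a coverage factor (0.5 homozygous,
  0.75 heterozygous — reads from diverged donor sequence map poorly,
  and a heterozygous carrier still maps one host haplotype);
* per-line donor-matching SNP tables, Poisson per window: enriched
  inside a line's segments, sparse background elsewhere; heterozygous
  genotype codes inside heterozygous segments;
* two-environment phenotypes (yield potential vs heat) in which
  favourable-allele effects at three focal markers express only under
  heat: the full favourable stack multiplies heat yield by 1.565 and
  cools the canopy by 2 °C relative to the all-unfavourable class, and
  heat cuts panel yield by 48.1%;
* a ground-truth record of planted segments, marker genotypes and
  elite/exotic group labels.

All randomness derives from one integer seed via fixed sub-streams,
so identical configurations give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .segments import IntrogressionSegment
from .windows import WindowGrid

__all__ = [
    "PhenoModel",
    "PanelConfig",
    "IntrogressionSpec",
    "TruthSet",
    "SyntheticPanel",
    "default_config",
    "simulate_coverage",
    "simulate_donor_snps",
    "simulate_phenotypes",
    "generate_panel",
    "build_truth",
    "write_fixtures",
    "read_fixtures",
]

# focal marker-trait-association loci and their favourable / unfavourable alleles
MARKER_6D = "chr6D-6276646"
MARKER_1B = "chr1B-63398861"
MARKER_2B = "chr2B-820002"
FOCAL_MARKERS = [MARKER_6D, MARKER_1B, MARKER_2B]
FAV_ALLELES = {MARKER_6D: "T", MARKER_1B: "C", MARKER_2B: "C"}
UNFAV_ALLELES = {MARKER_6D: "A", MARKER_1B: "A", MARKER_2B: "G"}

# stacked-effect anchors: the full favourable stack yields 1.565x the
# all-unfavourable class under heat, the 1B+2B partial stack 1.243x
FULL_STACK_YIELD = 1.565
PARTIAL_STACK_YIELD = 1.243

DONOR_TAUSCHII = "Ae_tauschii"
DONOR_RYE = "S_cereale"
DONOR_PONTICUM = "Th_ponticum"

_BASES = np.array(list("ACGT"))


def _default_yield_effects() -> dict[str, dict[str, tuple[str, float]]]:
    m_partial = PARTIAL_STACK_YIELD ** 0.5  # 1B and 2B share the partial stack
    m_6d = FULL_STACK_YIELD / PARTIAL_STACK_YIELD
    return {
        MARKER_6D: {"YLD": ("mult", m_6d), "CT": ("add", -1.0)},
        MARKER_1B: {"YLD": ("mult", m_partial), "CT": ("add", -0.5)},
        MARKER_2B: {"YLD": ("mult", m_partial), "CT": ("add", -0.5)},
    }


@dataclass
class PhenoModel:
    """Trait-generation model for the two-environment trial.

    ``allele_effects`` maps marker -> trait -> ("mult"|"add", value);
    effects apply only under heat, and heterozygous carriers of a
    favourable allele receive the full effect (dominant expression).
    ``residual_sd`` is either a scalar applied to every trait or a dict
    trait -> sd (optionally env -> sd).
    """

    yp_yield_mean: float = 600.0  # g m^-2
    yp_yield_sd: float = 45.0
    heat_reduction: float = 0.481  # panel-level fractional yield loss under heat
    allele_effects: dict = field(default_factory=_default_yield_effects)
    ct_effect: float = -2.0  # total deg C shift of the favourable stack
    ct_yp_mean: float = 22.0
    ct_heat_mean: float = 30.0
    residual_sd: float | dict = field(
        default_factory=lambda: {
            "YLD": {"YP": 45.0, "Heat": 30.0},
            "CT": 0.4,
            "TGW": 2.5,
            "HI": 0.03,
            "DTA": 2.0,
            "DTM": 3.0,
        }
    )
    exotic_fraction: float = 66 / 149

    def __post_init__(self) -> None:
        if not (0 <= self.heat_reduction < 1):
            raise ValueError("heat_reduction must be in [0, 1)")
        for sd in (
            [self.residual_sd]
            if np.isscalar(self.residual_sd)
            else self.residual_sd.values()
        ):
            vals = [sd] if np.isscalar(sd) else sd.values()
            if any(v < 0 for v in vals):
                raise ValueError("residual_sd must be >= 0")

    def resid(self, trait: str, env: str) -> float:
        if np.isscalar(self.residual_sd):
            return float(self.residual_sd)
        sd = self.residual_sd.get(trait, 0.0)
        if np.isscalar(sd):
            return float(sd)
        return float(sd.get(env, 0.0))


@dataclass(frozen=True)
class IntrogressionSpec:
    """A planted donor segment shared by a subset of lines."""

    lines: tuple[str, ...]
    chrom: str
    start: int
    end: int
    donor: str
    zygosity: str  # "hom" | "het"


@dataclass
class PanelConfig:
    """Full specification of a synthetic panel."""

    n_lines: int = 149
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            c: 60_000_000
            for c in ["chr1B", "chr2B", "chr3A", "chr4A", "chr5A", "chr6D", "chr7A"]
        }
    )
    window_size: int = 1_000_000
    seq_depth_range: tuple[float, float] = (800.0, 1600.0)  # mean reads/window
    introgression_specs: list[IntrogressionSpec] | None = None  # None -> defaults
    hom_coverage_factor: float = 0.5
    het_coverage_factor: float = 0.75
    dispersion: float | None = 200.0  # NB size parameter; None = Poisson
    mappability_sigma: float = 0.25  # log-normal sd of shared window mappability
    donor_snp_rate: float = 5.0  # donor-matching SNPs / window inside segments
    background_snp_rate: float = 0.2  # spurious donor-matching SNPs / window
    pheno_model: PhenoModel = field(default_factory=PhenoModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not (0 < self.hom_coverage_factor < 1):
            raise ValueError("hom_coverage_factor must be in (0, 1)")
        if not (0 < self.het_coverage_factor < 1):
            raise ValueError("het_coverage_factor must be in (0, 1)")
        if self.donor_snp_rate < 0 or self.background_snp_rate < 0:
            raise ValueError("SNP rates must be non-negative")
        if self.introgression_specs is None:
            self.introgression_specs = default_introgression_specs(
                self.line_names, self.window_size
            )
        for spec in self.introgression_specs:
            length = self.chrom_lengths.get(spec.chrom)
            if length is None:
                raise ValueError(f"segment on unknown chromosome {spec.chrom!r}")
            if not (0 <= spec.start < spec.end <= length):
                raise ValueError(
                    f"segment {spec.chrom}:{spec.start}-{spec.end} outside chromosome"
                )

    @property
    def line_names(self) -> list[str]:
        return [f"L{i:03d}" for i in range(self.n_lines)]

    def grid(self) -> WindowGrid:
        return WindowGrid.from_chrom_lengths(self.chrom_lengths, self.window_size)


@dataclass
class TruthSet:
    """Ground truth of a synthetic panel."""

    segments: list[IntrogressionSegment]
    allele_assignments: pd.DataFrame  # long: line, marker, allele
    group_labels: pd.Series  # line -> {"elite", "exotic"}

    def segments_by_line(self) -> dict[str, list[IntrogressionSegment]]:
        out: dict[str, list[IntrogressionSegment]] = {}
        for seg in self.segments:
            out.setdefault(seg.line, []).append(seg)
        return out


@dataclass
class SyntheticPanel:
    """Generated panel bundle: everything downstream stages consume."""

    config: PanelConfig
    grid: WindowGrid
    counts: pd.DataFrame  # lines x windows raw counts
    truth: TruthSet
    snps: pd.DataFrame  # line, chrom, pos, ref, alt, gt, donor
    pheno: pd.DataFrame  # line, group, environment, traits
    markers: pd.DataFrame  # line, marker, allele


# (start_window, end_window) cycle for chr6D-like carrier segments; every
# pair contains the true core [5, 7) and spans at least 5 windows, the
# first emulating a full-length unbroken telomeric segment
_SEGMENT_CYCLE = [
    (0, 31), (1, 14), (2, 7), (3, 12), (4, 9), (5, 16),
    (0, 8), (2, 20), (3, 10), (5, 13), (1, 7), (4, 25),
]
HOM_CARRIER_FRAC = 33 / 149
HET_CARRIER_FRAC = 7 / 149
PARTIAL_STACK_FRAC = 14 / 149
TRUE_CORE_WINDOWS = (5, 7)  # intersection of the segment cycle


def default_introgression_specs(
    line_names: list[str], window_size: int
) -> list[IntrogressionSpec]:
    """Study-like planted segments for a panel of the given size.

    ~22% of lines carry a homozygous donor segment at the start of
    chr6D and ~5% a heterozygous one, all sharing a 2-window core;
    a handful of lines carry segments from other donors elsewhere;
    two lines carry non-core chr6D segments (exclusion controls).
    """
    n = len(line_names)
    n_hom = round(HOM_CARRIER_FRAC * n)
    n_het = round(HET_CARRIER_FRAC * n)
    specs = []
    for i in range(n_hom):
        s, e = _SEGMENT_CYCLE[i % len(_SEGMENT_CYCLE)]
        specs.append(
            IntrogressionSpec(
                (line_names[i],), "chr6D", s * window_size, e * window_size,
                DONOR_TAUSCHII, "hom",
            )
        )
    for j in range(n_het):
        s, e = _SEGMENT_CYCLE[(j + 3) % len(_SEGMENT_CYCLE)]
        specs.append(
            IntrogressionSpec(
                (line_names[n_hom + j],), "chr6D", s * window_size, e * window_size,
                DONOR_TAUSCHII, "het",
            )
        )
    k = n_hom + n_het
    if k + 7 <= n:
        for j in range(3):  # rye segments on chr1B
            specs.append(
                IntrogressionSpec(
                    (line_names[k + j],), "chr1B",
                    20 * window_size, 28 * window_size, DONOR_RYE, "hom",
                )
            )
        for j in range(2):  # Thinopyrum segments on chr2B
            specs.append(
                IntrogressionSpec(
                    (line_names[k + 3 + j],), "chr2B",
                    40 * window_size, 48 * window_size, DONOR_PONTICUM, "hom",
                )
            )
        for j in range(2):  # non-core chr6D segments in unfavourable-allele lines
            specs.append(
                IntrogressionSpec(
                    (line_names[k + 5 + j],), "chr6D",
                    20 * window_size, 27 * window_size, DONOR_TAUSCHII, "hom",
                )
            )
    return specs


def build_truth(config: PanelConfig) -> TruthSet:
    lines = config.line_names
    segments = [
        IntrogressionSegment(
            line=line, chrom=spec.chrom, start=spec.start, end=spec.end,
            donor=spec.donor, zygosity=spec.zygosity,
        )
        for spec in config.introgression_specs
        for line in spec.lines
    ]
    # marker genotypes: chr6D carriers whose segment covers the core get
    # the favourable 6D allele (het carriers heterozygous) plus the
    # favourable 1B/2B alleles; a partial-stack class carries 1B/2B only
    core_lo = TRUE_CORE_WINDOWS[0] * config.window_size
    core_hi = TRUE_CORE_WINDOWS[1] * config.window_size
    geno = {line: dict(UNFAV_ALLELES) for line in lines}
    carrier_lines: list[str] = []
    for seg in segments:
        if (
            seg.chrom == "chr6D"
            and seg.start <= core_lo
            and seg.end >= core_hi
        ):
            carrier_lines.append(seg.line)
            geno[seg.line][MARKER_6D] = (
                FAV_ALLELES[MARKER_6D]
                if seg.zygosity == "hom"
                else f"{UNFAV_ALLELES[MARKER_6D]}/{FAV_ALLELES[MARKER_6D]}"
            )
            geno[seg.line][MARKER_1B] = FAV_ALLELES[MARKER_1B]
            geno[seg.line][MARKER_2B] = FAV_ALLELES[MARKER_2B]
    n_partial = round(PARTIAL_STACK_FRAC * config.n_lines)
    non_carriers = [l for l in lines if l not in set(carrier_lines)]
    seg_lines = {s.line for s in segments}
    partial_pool = [l for l in non_carriers if l not in seg_lines]
    for line in partial_pool[-n_partial:] if n_partial else []:
        geno[line][MARKER_1B] = FAV_ALLELES[MARKER_1B]
        geno[line][MARKER_2B] = FAV_ALLELES[MARKER_2B]
    alleles = pd.DataFrame(
        [
            {"line": line, "marker": m, "allele": geno[line][m]}
            for line in lines
            for m in FOCAL_MARKERS
        ]
    )
    # exotic group: all segment carriers and partial-stack lines, topped
    # up with further lines to the configured exotic fraction
    n_exotic = round(config.pheno_model.exotic_fraction * config.n_lines)
    exotic = list(dict.fromkeys(
        list(seg_lines) + (partial_pool[-n_partial:] if n_partial else [])
    ))
    for line in reversed(lines):
        if len(exotic) >= n_exotic:
            break
        if line not in exotic:
            exotic.append(line)
    groups = pd.Series(
        ["exotic" if l in set(exotic) else "elite" for l in lines],
        index=pd.Index(lines, name="line"),
        name="group",
    )
    return TruthSet(segments=segments, allele_assignments=alleles, group_labels=groups)


def _segment_window_factors(config: PanelConfig, grid: WindowGrid, truth: TruthSet) -> np.ndarray:
    """Lines x windows multiplicative coverage factors from planted segments."""
    lines = config.line_names
    factors = np.ones((len(lines), len(grid)))
    line_idx = {l: i for i, l in enumerate(lines)}
    w = grid.windows
    for seg in truth.segments:
        on = (
            (w["chrom"] == seg.chrom)
            & (np.minimum(w["end"], seg.end) - np.maximum(w["start"], seg.start)
               >= (w["end"] - w["start"]) / 2)
        ).to_numpy()
        f = (
            config.hom_coverage_factor
            if seg.zygosity == "hom"
            else config.het_coverage_factor
        )
        factors[line_idx[seg.line], on] *= f
    return factors


def simulate_coverage(config: PanelConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Draw the raw lines x windows read-count matrix and the truth set.

    Counts are negative binomial around per-line mean depth x shared
    per-window mappability, scaled down inside planted segments.
    """
    grid = config.grid()
    if len(grid) == 0:
        raise ValueError("empty window grid")
    truth = build_truth(config)
    rng = np.random.default_rng([config.seed, 11])
    lines = config.line_names
    depth = rng.uniform(*config.seq_depth_range, size=len(lines))
    mappability = rng.lognormal(0.0, config.mappability_sigma, size=len(grid))
    # short terminal windows carry proportionally fewer reads
    w = grid.windows
    size_frac = ((w["end"] - w["start"]) / config.window_size).to_numpy()
    mu = depth[:, None] * mappability[None, :] * size_frac[None, :]
    mu *= _segment_window_factors(config, grid, truth)
    if config.dispersion is None or not np.isfinite(config.dispersion):
        counts = rng.poisson(mu)
    else:
        k = config.dispersion
        counts = rng.negative_binomial(k, k / (k + mu))
    return (
        pd.DataFrame(counts, index=pd.Index(lines, name="line"), columns=range(len(grid))),
        truth,
    )


def simulate_donor_snps(config: PanelConfig, truth: TruthSet) -> pd.DataFrame:
    """Per-line donor-matching SNP table.

    Poisson counts per window: ``donor_snp_rate`` inside a line's
    segments (heterozygous genotype codes inside heterozygous
    segments), ``background_snp_rate`` elsewhere with a rotating donor
    label.  Positions are unique within a line.
    """
    grid = config.grid()
    rng = np.random.default_rng([config.seed, 22])
    by_line = truth.segments_by_line()
    donors = sorted({s.donor for s in truth.segments}) or [DONOR_TAUSCHII]
    w = grid.windows
    rows: list[dict] = []
    for line in config.line_names:
        taken: set[int] = set()
        seg_windows: dict[int, IntrogressionSegment] = {}
        for seg in by_line.get(line, []):
            on = np.flatnonzero(
                (
                    (w["chrom"] == seg.chrom)
                    & (np.minimum(w["end"], seg.end) - np.maximum(w["start"], seg.start)
                       >= (w["end"] - w["start"]) / 2)
                ).to_numpy()
            )
            for wi in on:
                seg_windows[int(wi)] = seg
        for wi in range(len(grid)):
            seg = seg_windows.get(wi)
            rate = config.donor_snp_rate if seg else config.background_snp_rate
            n = int(rng.poisson(rate))
            if n == 0:
                continue
            wstart = int(w["start"].iloc[wi])
            wend = int(w["end"].iloc[wi])
            chrom = w["chrom"].iloc[wi]
            span = wend - wstart
            n = min(n, span)
            offsets = rng.choice(span, size=n, replace=False)
            for off in sorted(offsets):
                pos = wstart + int(off) + 1  # 1-based
                key = hash((chrom, pos))
                if key in taken:
                    continue
                taken.add(key)
                ref, alt = rng.choice(4, size=2, replace=False)
                rows.append(
                    {
                        "line": line,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": _BASES[ref],
                        "alt": _BASES[alt],
                        "gt": ("het" if seg is not None and seg.zygosity == "het" else "hom"),
                        "donor": seg.donor if seg else donors[wi % len(donors)],
                    }
                )
    return pd.DataFrame(
        rows, columns=["line", "chrom", "pos", "ref", "alt", "gt", "donor"]
    )


def _line_multipliers(
    truth: TruthSet, model: PhenoModel, trait: str
) -> tuple[pd.Series, pd.Series]:
    """Per-line multiplicative and additive heat-environment allele effects."""
    geno = truth.allele_assignments.pivot_table(
        index="line", columns="marker", values="allele", aggfunc="first"
    )
    mult = pd.Series(1.0, index=geno.index)
    add = pd.Series(0.0, index=geno.index)
    for marker, effects in model.allele_effects.items():
        if marker not in geno.columns:
            raise ValueError(f"unknown marker {marker!r} in allele_effects")
        eff = effects.get(trait)
        if eff is None:
            continue
        kind, value = eff
        fav = FAV_ALLELES.get(marker)
        has_fav = geno[marker].astype(str).str.contains(str(fav))
        if kind == "mult":
            mult = mult.where(~has_fav, mult * value)
        else:
            add = add.where(~has_fav, add + value)
    return mult, add


def simulate_phenotypes(config: PanelConfig, truth: TruthSet) -> pd.DataFrame:
    """Line x environment adjusted-mean phenotype table.

    Allele effects express only in the heat environment; the total CT
    shift of the full favourable stack is rescaled to ``ct_effect``.
    """
    model = config.pheno_model
    rng = np.random.default_rng([config.seed, 33])
    lines = config.line_names
    n = len(lines)
    yld_mult, _ = _line_multipliers(truth, model, "YLD")
    _, ct_add = _line_multipliers(truth, model, "CT")
    # rescale CT additive effects so the full stack totals ct_effect
    total_ct = sum(
        eff["CT"][1]
        for eff in model.allele_effects.values()
        if "CT" in eff and eff["CT"][0] == "add"
    )
    if total_ct != 0:
        ct_add = ct_add * (model.ct_effect / total_ct)
    base = {
        "TGW": (42.0, 38.0),
        "HI": (0.48, 0.42),
        "DTA": (80.0, 65.0),
        "DTM": (125.0, 95.0),
    }
    records = []
    for env in ("YP", "Heat"):
        heat = env == "Heat"
        yld_mean = model.yp_yield_mean * (
            (1 - model.heat_reduction) if heat else 1.0
        )
        yld = yld_mean * (yld_mult.loc[lines].to_numpy() if heat else np.ones(n))
        yld_sd = model.resid("YLD", env)
        if yld_sd > 0:
            yld = np.maximum(yld + rng.normal(0, yld_sd, n), 0.0)
        ct_mean = model.ct_heat_mean if heat else model.ct_yp_mean
        ct = ct_mean + (ct_add.loc[lines].to_numpy() if heat else np.zeros(n))
        ct_sd = model.resid("CT", env)
        if ct_sd > 0:
            ct = ct + rng.normal(0, ct_sd, n)
        row_traits = {"YLD": yld, "CT": ct}
        for trait, (yp_val, heat_val) in base.items():
            mean = heat_val if heat else yp_val
            sd = model.resid(trait, env)
            vals = np.full(n, float(mean))
            if sd > 0:
                vals = vals + rng.normal(0, sd, n)
            if trait == "HI":
                vals = np.clip(vals, 1e-6, 1.0)
            row_traits[trait] = vals
        for i, line in enumerate(lines):
            rec = {
                "line": line,
                "group": truth.group_labels[line],
                "environment": env,
            }
            rec.update({t: float(v[i]) for t, v in row_traits.items()})
            records.append(rec)
    return pd.DataFrame(records)


def generate_panel(config: PanelConfig | None = None) -> SyntheticPanel:
    """Generate the full synthetic panel bundle."""
    config = config or PanelConfig()
    counts, truth = simulate_coverage(config)
    snps = simulate_donor_snps(config, truth)
    pheno = simulate_phenotypes(config, truth)
    return SyntheticPanel(
        config=config,
        grid=config.grid(),
        counts=counts,
        truth=truth,
        snps=snps,
        pheno=pheno,
        markers=truth.allele_assignments,
    )


def default_config(seed: int = 0, **overrides) -> PanelConfig:
    """The study-like default configuration with a given seed."""
    return PanelConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# fixture bundle IO


def write_fixtures(panel: SyntheticPanel, outdir: str | Path) -> None:
    """Write the panel to a plain-text fixture bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = panel.grid
    long = panel.counts.stack().rename("count").reset_index()
    long.columns = ["line", "window", "count"]
    long["chrom"] = grid.windows["chrom"].to_numpy()[long["window"]]
    long["window_start"] = grid.windows["start"].to_numpy()[long["window"]]
    long[["line", "chrom", "window_start", "count"]].to_csv(
        outdir / "counts.tsv", sep="\t", index=False
    )
    panel.snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    panel.pheno.to_csv(outdir / "pheno.tsv", sep="\t", index=False)
    panel.markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    bed = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "name": f"{s.line}|{s.donor}|{s.zygosity}",
            }
            for s in panel.truth.segments
        ]
    )
    bed.to_csv(outdir / "truth.bed", sep="\t", index=False, header=False)
    cfg = asdict(panel.config)
    cfg["introgression_specs"] = [
        {**asdict(s), "lines": list(s.lines)} for s in panel.config.introgression_specs
    ]
    cfg["seq_depth_range"] = list(panel.config.seq_depth_range)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_config(path: str | Path) -> PanelConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["introgression_specs"] = [
        IntrogressionSpec(
            lines=tuple(s["lines"]), chrom=s["chrom"], start=s["start"],
            end=s["end"], donor=s["donor"], zygosity=s["zygosity"],
        )
        for s in cfg.get("introgression_specs") or []
    ] or None
    cfg["seq_depth_range"] = tuple(cfg["seq_depth_range"])
    pm = cfg.get("pheno_model")
    if isinstance(pm, dict):
        ae = pm.get("allele_effects")
        if ae:
            pm["allele_effects"] = {
                m: {t: (k, v) for t, (k, v) in eff.items()} for m, eff in ae.items()
            }
        cfg["pheno_model"] = PhenoModel(**pm)
    return PanelConfig(**cfg)


def read_fixtures(indir: str | Path) -> SyntheticPanel:
    """Read back a fixture bundle written by :func:`write_fixtures`."""
    indir = Path(indir)
    config = read_config(indir / "config.yaml")
    grid = config.grid()
    long = pd.read_csv(indir / "counts.tsv", sep="\t")
    key = grid.windows.reset_index().set_index(["chrom", "start"])["index"]
    long["window"] = [
        key[(c, s)] for c, s in zip(long["chrom"], long["window_start"])
    ]
    counts = long.pivot_table(
        index="line", columns="window", values="count", aggfunc="first"
    )
    counts = counts.reindex(index=config.line_names, columns=range(len(grid)))
    snps = pd.read_csv(indir / "snps.tsv", sep="\t")
    pheno = pd.read_csv(indir / "pheno.tsv", sep="\t")
    markers = pd.read_csv(indir / "markers.tsv", sep="\t")
    bed = pd.read_csv(
        indir / "truth.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "name"],
    )
    segments = []
    for _, r in bed.iterrows():
        line, donor, zyg = r["name"].split("|")
        segments.append(
            IntrogressionSegment(
                line=line, chrom=r["chrom"], start=int(r["start"]),
                end=int(r["end"]), donor=donor, zygosity=zyg,
            )
        )
    groups = pheno.drop_duplicates("line").set_index("line")["group"]
    truth = TruthSet(
        segments=segments, allele_assignments=markers, group_labels=groups
    )
    return SyntheticPanel(
        config=config, grid=grid, counts=counts, truth=truth,
        snps=snps, pheno=pheno, markers=markers,
    )
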