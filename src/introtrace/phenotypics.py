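"""Stress phenotypics: derived traits, SSI, heritability, group tests,
correlations and allele-stacking effects.

Works on a long-format phenotype table of across-year adjusted means,
one record per line x environment, with environments ``YP`` (yield
potential) and ``Heat``.

Stress susceptibility index for a line with yields Yht (heat) and Yyp
(yield potential), against panel means Ȳht, Ȳyp:

    SSI = (1 - Yht/Yyp) / (1 - Ȳht/Ȳyp)

Lower SSI means greater tolerance: SSI = 1 is a line losing exactly the
panel-average fraction of its yield; SSI = 0 is a lossless line.

Broad-sense heritability from variance components over ``e``
environments (years) and ``r`` replicates:

    H² = σg² / (σg² + σge²/e + σ²/(re))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "VarianceComponents",
    "derive_traits",
    "compute_ssi",
    "heritability",
    "group_compare",
    "correlate",
    "allele_stack",
    "single_allele_effect",
]

ENV_CONTROL = "YP"
ENV_STRESS = "Heat"


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of a multi-environment trial."""

    sigma_g2: float  # genotypic variance
    sigma_ge2: float  # genotype x environment (year) variance
    sigma_e2: float  # error variance
    e: int  # environments (years)
    r: int  # replicates

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")
        if self.e < 1 or self.r < 1:
            raise ValueError("e and r must be >= 1")


def derive_traits(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add derived agronomic traits to a phenotype table.

    GM2 (grains m⁻²) = (YLD / TGW) x 1000;
    BM_PM (biomass at physiological maturity, g m⁻²) = YLD / HI;
    SM2 (spikes m⁻²) = BM_PM / (shoot dry weight / shoot number);
    PGF (grain-filling fraction of the cycle) = (DTM − DTA) / DTM.

    Each trait is computed only where its components are present;
    zero divisors raise with the offending record.
    """
    out = pheno.copy()

    def _div(num, den, name):
        den_vals = out[den]
        zero = den_vals.notna() & (den_vals == 0) & out[num].notna()
        if zero.any():
            row = out[zero].iloc[0]
            raise ValueError(
                f"zero {den} for line {row.get('line', '?')} while deriving {name}"
            )
        return out[num] / den_vals

    if {"YLD", "TGW"}.issubset(out.columns):
        out["GM2"] = _div("YLD", "TGW", "GM2") * 1000
    if {"YLD", "HI"}.issubset(out.columns):
        out["BM_PM"] = _div("YLD", "HI", "BM_PM")
    if {"BM_PM", "shoot_dw", "shoot_n"}.issubset(out.columns):
        per_shoot = out["shoot_dw"] / out["shoot_n"]
        zero = per_shoot.notna() & (per_shoot == 0) & out["BM_PM"].notna()
        if zero.any():
            raise ValueError("zero shoot dry weight per shoot while deriving SM2")
        out["SM2"] = out["BM_PM"] / per_shoot
    if {"DTA", "DTM"}.issubset(out.columns):
        zero = out["DTM"].notna() & (out["DTM"] == 0)
        if zero.any():
            raise ValueError("zero DTM while deriving PGF")
        out["PGF"] = (out["DTM"] - out["DTA"]) / out["DTM"]
    return out


def compute_ssi(
    pheno: pd.DataFrame, trait: str = "YLD"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line stress susceptibility index and per-group summaries.

    Lines missing either environment are skipped with a warning column
    rather than raising.  Returns ``(per_line, by_group)``.
    """
    wide = pheno.pivot_table(
        index="line", columns="environment", values=trait, aggfunc="first"
    )
    for env in (ENV_CONTROL, ENV_STRESS):
        if env not in wide.columns:
            raise ValueError(f"phenotype table lacks environment {env!r}")
    complete = wide.dropna()
    skipped = wide.index.difference(complete.index)
    mean_ht = complete[ENV_STRESS].mean()
    mean_yp = complete[ENV_CONTROL].mean()
    denom = 1 - mean_ht / mean_yp
    if denom == 0:
        raise ValueError("panel mean stress/control ratio is 1; SSI undefined")
    ssi = (1 - complete[ENV_STRESS] / complete[ENV_CONTROL]) / denom
    per_line = pd.DataFrame({"line": complete.index, "ssi": ssi.to_numpy()})
    if "group" in pheno.columns:
        groups = pheno.drop_duplicates("line").set_index("line")["group"]
        per_line["group"] = per_line["line"].map(groups)
        by_group = (
            per_line.groupby("group")["ssi"].agg(["count", "mean", "std"]).reset_index()
        )
    else:
        by_group = per_line["ssi"].agg(["count", "mean", "std"]).to_frame().T
    per_line.attrs["skipped_lines"] = list(skipped)
    return per_line, by_group


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H² from variance components."""
    denom = vc.sigma_g2 + vc.sigma_ge2 / vc.e + vc.sigma_e2 / (vc.r * vc.e)
    if denom == 0:
        raise ValueError("all variance components zero; H² undefined")
    return vc.sigma_g2 / denom


def _star_tier(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return "ns"


def group_compare(
    pheno: pd.DataFrame, trait: str, environment: str, group_col: str = "group"
) -> dict:
    """Welch two-sample t-test between the two line groups for a trait.

    Two-tailed, no equal-variance assumption; significance tiers:
    p < 0.01 "*", p < 0.001 "**", p < 0.0001 "***".
    """
    sub = pheno[pheno["environment"] == environment]
    groups = sorted(sub[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    a = sub.loc[sub[group_col] == groups[0], trait].dropna()
    b = sub.loc[sub[group_col] == groups[1], trait].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 lines")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return {
        "groups": groups,
        "n": (len(a), len(b)),
        "means": (a.mean(), b.mean()),
        "sds": (a.std(ddof=1), b.std(ddof=1)),
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "ci": (float(ci.low), float(ci.high)),
        "tier": _star_tier(float(res.pvalue)),
    }


def correlate(
    pheno: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    by: list[str] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlations per stratum with significance display rule.

    Strata are combinations of the ``by`` columns (e.g. group x
    environment).  Pairs with missing values are dropped pairwise.
    Strata failing ``p <= alpha`` are marked non-significant.
    """
    by = by or []
    rows = []
    grouped = pheno.groupby(by, sort=True) if by else [((), pheno)]
    for key, sub in grouped:
        xy = sub[[trait_x, trait_y]].dropna()
        if len(xy) < 3:
            raise ValueError(f"stratum {key}: need >= 3 paired observations")
        if xy[trait_x].nunique() == 1 or xy[trait_y].nunique() == 1:
            raise ValueError(f"stratum {key}: zero variance; r undefined")
        res = stats.pearsonr(xy[trait_x], xy[trait_y])
        ci = res.confidence_interval(0.95)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=len(xy),
            r=float(res.statistic),
            p=float(res.pvalue),
            ci_low=float(ci.low),
            ci_high=float(ci.high),
            significant=float(res.pvalue) <= alpha,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def allele_stack(
    pheno: pd.DataFrame,
    markers: pd.DataFrame,
    focal_markers: list[str],
    trait: str,
    environment: str = ENV_STRESS,
    reference_class: str | None = None,
    as_celsius: bool = False,
) -> dict:
    """Effect of stacked alleles at focal markers on a trait.

    Lines are classed by their allele combination across
    ``focal_markers`` (e.g. "T+C+C"); the reference class is the
    all-major (unfavourable) combination, or the largest class when not
    given.  Reports per-class n, mean ± sd, percent change versus the
    reference (or °C difference for temperature traits), one-way ANOVA
    F/p and Tukey HSD pairwise p-values.

    ``markers`` is long-format: columns ``line, marker, allele`` where
    ``allele`` is the line's genotype at the marker (e.g. "T", "A",
    "A/T").
    """
    missing = set(focal_markers) - set(markers["marker"].unique())
    if missing:
        raise ValueError(f"unknown marker(s) in focal set: {sorted(missing)}")
    geno = markers.pivot_table(
        index="line", columns="marker", values="allele", aggfunc="first"
    )[focal_markers]
    combo = geno.apply(lambda r: "+".join(str(a) for a in r), axis=1)
    sub = pheno[pheno["environment"] == environment].set_index("line")
    values = sub[trait].dropna()
    combo = combo.reindex(values.index).dropna()
    values = values.loc[combo.index]
    class_sizes = combo.value_counts()
    empty = class_sizes[class_sizes == 0]
    classes = class_sizes[class_sizes > 0].index.tolist()
    if len(classes) < 2:
        raise ValueError("need at least 2 non-empty allele-combination classes")
    if reference_class is None:
        reference_class = class_sizes.idxmax()
    elif reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} has no lines")
    ref_mean = values[combo == reference_class].mean()
    per_class = []
    for cls in classes:
        vals = values[combo == cls]
        row = {
            "class": cls,
            "n": len(vals),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1),
        }
        if as_celsius:
            row["delta_c"] = vals.mean() - ref_mean
        else:
            row["pct_change"] = 100 * (vals.mean() / ref_mean - 1)
        per_class.append(row)
    groups_vals = [values[combo == cls].to_numpy() for cls in classes]
    f, p = stats.f_oneway(*groups_vals)
    tukey = pairwise_tukeyhsd(values.to_numpy(), combo.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {
        "classes": pd.DataFrame(per_class),
        "reference_class": reference_class,
        "anova_F": float(f),
        "anova_p": float(p),
        "tukey": tukey_df,
        "dropped_classes": list(empty.index),
    }


def single_allele_effect(stacked_pct: float, partial_pct: float) -> dict:
    """Estimate one allele's effect from full- and partial-stack effects.

    Assuming no epistasis between the stacked alleles, the remaining
    allele's effect can be read two ways from percent changes versus
    the common reference class: additively (difference of percent
    changes) or multiplicatively (ratio of the two fold-changes).  Both
    conventions are reported; they disagree slightly on rounded values.
    """
    additive = stacked_pct - partial_pct
    multiplicative = 100 * ((1 + stacked_pct / 100) / (1 + partial_pct / 100) - 1)
    return {"additive_pct": additive, "multiplicative_pct": multiplicative}
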