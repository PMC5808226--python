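"""Relative expression by the 2^-ddCt (Livak) method with group statistics.

The workflow mirrors standard qPCR practice: technical replicates are
averaged per biological replicate, dCt = Ct_target - Ct_reference is
computed per biological replicate, ddCt centers dCt on the calibrator
condition's mean, and relative quantity is rq = 2^-ddCt.  Equal
amplification efficiencies of target and reference are assumed (no Pfaffl
correction).

Group statistics follow the screening-then-testing scheme common in
entomological expression studies: Shapiro-Wilk normality and Levene
variance-homogeneity screens on log-transformed folds, then one-way ANOVA
with Tukey HSD when variances are homogeneous, Dunnett's T3-style Welch
pairwise tests otherwise, and Student's t for two-condition designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CT_COLUMNS",
    "ExpressionConfig",
    "collapse_technical",
    "relative_quantity",
    "group_stats",
    "GroupStatsResult",
    "validate_ct_table",
]

#: Required columns of a tidy Ct table.
CT_COLUMNS = ["sample_id", "condition", "gene", "bio_rep", "tech_rep", "ct"]

#: Technical replicates more dispersed than this (cycles) get a QC flag.
TECH_SD_FLAG_CYCLES = 0.5


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy Ct-table contract (columns present, Ct finite and > 0)."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("all Ct values must be finite and > 0")
    return table


@dataclass(frozen=True)
class ExpressionConfig:
    """Target/reference/calibrator configuration for one experiment.

    ``calibrator`` may be None, in which case the condition with the
    lowest mean expression (largest mean dCt) is used, so every reported
    fold is >= 1-ish relative to the weakest condition.
    """

    target_gene: str
    reference_gene: str
    calibrator: str | None = None

    def __post_init__(self) -> None:
        if self.target_gene == self.reference_gene:
            raise ValueError("reference gene must differ from target gene")


def collapse_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (condition, gene, biological replicate).

    Returns columns condition, gene, bio_rep, ct, tech_sd, high_variance;
    ``high_variance`` flags cells whose technical SD exceeds 0.5 cycles.
    """
    validate_ct_table(table)
    grouped = (
        table.groupby(["condition", "gene", "bio_rep"], sort=True)["ct"]
        .agg(ct="mean", tech_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .reset_index()
    )
    grouped["high_variance"] = grouped["tech_sd"] > TECH_SD_FLAG_CYCLES
    return grouped


def relative_quantity(mean_cts: pd.DataFrame, config: ExpressionConfig) -> pd.DataFrame:
    """Per-biological-replicate relative quantities, rq = 2^-ddCt.

    ``mean_cts`` is the output of :func:`collapse_technical` (or any frame
    with condition/gene/bio_rep/ct).  ddCt centering uses the calibrator
    condition's mean dCt across its biological replicates.
    """
    needed = {"condition", "gene", "bio_rep", "ct"}
    if not needed <= set(mean_cts.columns):
        raise ValueError(f"mean_cts must have columns {sorted(needed)}")
    tgt = mean_cts[mean_cts["gene"] == config.target_gene]
    ref = mean_cts[mean_cts["gene"] == config.reference_gene]
    if tgt.empty:
        raise ValueError(f"target gene {config.target_gene!r} absent from table")
    if ref.empty:
        raise ValueError(f"reference gene {config.reference_gene!r} absent from table")
    merged = tgt.merge(
        ref, on=["condition", "bio_rep"], how="outer", suffixes=("_tgt", "_ref"), indicator=True
    )
    gaps = merged[merged["_merge"] != "both"]
    if not gaps.empty:
        row = gaps.iloc[0]
        which = config.reference_gene if row["_merge"] == "left_only" else config.target_gene
        raise ValueError(
            f"missing {which!r} Ct for condition {row['condition']!r}, "
            f"biological replicate {row['bio_rep']!r}"
        )
    merged["delta_ct"] = merged["ct_tgt"] - merged["ct_ref"]

    per_condition_mean = merged.groupby("condition")["delta_ct"].mean()
    calibrator = config.calibrator
    if calibrator is None:
        calibrator = per_condition_mean.idxmax()  # lowest expression
    if calibrator not in per_condition_mean.index:
        raise ValueError(f"calibrator condition {calibrator!r} absent from table")
    center = per_condition_mean[calibrator]

    out = merged[["condition", "bio_rep", "delta_ct"]].copy()
    out["delta_delta_ct"] = out["delta_ct"] - center
    out["rq"] = 2.0 ** (-out["delta_delta_ct"])
    out.attrs["calibrator"] = calibrator
    return out.sort_values(["condition", "bio_rep"]).reset_index(drop=True)


@dataclass
class PairwiseResult:
    a: str
    b: str
    statistic: float
    p_adj: float
    significant: bool


@dataclass
class GroupStatsResult:
    """Omnibus + pairwise comparison of per-condition fold changes."""

    method: str  # "t" | "anova_tukey" | "dunnett_t3"
    omnibus_stat: float
    omnibus_p: float
    shapiro_p: dict[str, float]
    levene_p: float
    variances_homogeneous: bool
    pairwise: list[PairwiseResult] = field(default_factory=list)
    letters: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "shapiro_p": self.shapiro_p,
            "levene_p": self.levene_p,
            "variances_homogeneous": self.variances_homogeneous,
            "pairwise": [vars(p) for p in self.pairwise],
            "letters": self.letters,
            "degenerate": self.degenerate,
            "alpha": self.alpha,
        }


def _welch_sidak_pairs(
    groups: dict[str, np.ndarray], alpha: float
) -> list[PairwiseResult]:
    # Dunnett's T3-style pairwise tests for unequal variances: Welch t with
    # Welch-Satterthwaite df, Sidak-adjusted across all pairs (an accepted
    # approximation to the studentized-maximum-modulus critical values).
    names = sorted(groups)
    m = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        p_adj = min(1.0, 1.0 - (1.0 - res.pvalue) ** m)
        out.append(
            PairwiseResult(a=a, b=b, statistic=float(res.statistic), p_adj=float(p_adj),
                           significant=bool(p_adj < alpha))
        )
    return out


def _compact_letters(
    names: list[str], distinct: set[frozenset[str]]
) -> dict[str, str]:
    """Compact letter display: conditions sharing a letter are not distinct."""
    letter_groups: list[set[str]] = []
    for name in names:
        placed = False
        for grp in letter_groups:
            if all(frozenset((name, other)) not in distinct for other in grp):
                grp.add(name)
                placed = True
        if not placed:
            letter_groups.append({name})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {n: "" for n in names}
    for i, grp in enumerate(letter_groups):
        for n in sorted(grp):
            out[n] += alphabet[i % len(alphabet)]
    return out


def group_stats(rqs: pd.DataFrame, alpha: float = 0.05) -> GroupStatsResult:
    """Screen-then-test comparison of fold changes across conditions.

    ``rqs`` needs columns condition and rq.  Folds are log-transformed
    before testing, which symmetrizes multiplicative noise.  With exactly
    two conditions a Student's t-test is used; with more, one-way ANOVA
    plus Tukey HSD under variance homogeneity (Levene p > alpha), or
    Welch/Sidak pairwise tests (Dunnett's T3 style) otherwise.
    """
    if not {"condition", "rq"} <= set(rqs.columns):
        raise ValueError("rqs must have columns 'condition' and 'rq'")
    groups = {
        str(name): np.log(np.asarray(sub["rq"], dtype=float))
        for name, sub in rqs.groupby("condition")
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("need at least 2 replicates per condition")
    names = sorted(groups)
    arrays = [groups[n] for n in names]

    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        return GroupStatsResult(
            method="degenerate", omnibus_stat=0.0, omnibus_p=1.0,
            shapiro_p={n: 1.0 for n in names}, levene_p=1.0,
            variances_homogeneous=True, degenerate=True, alpha=alpha,
            letters={n: "a" for n in names},
        )

    shapiro_p = {}
    for n in names:
        a = groups[n]
        shapiro_p[n] = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 1.0
    try:
        levene_p = float(stats.levene(*arrays).pvalue)
    except ValueError:
        levene_p = 1.0
    homogeneous = levene_p > alpha

    if len(names) == 2:
        res = stats.ttest_ind(*arrays, equal_var=homogeneous)
        p = float(res.pvalue)
        sig = p < alpha
        distinct = {frozenset(names)} if sig else set()
        return GroupStatsResult(
            method="t", omnibus_stat=float(res.statistic), omnibus_p=p,
            shapiro_p=shapiro_p, levene_p=levene_p, variances_homogeneous=homogeneous,
            pairwise=[PairwiseResult(names[0], names[1], float(res.statistic), p, sig)],
            letters=_compact_letters(names, distinct), alpha=alpha,
        )

    if homogeneous:
        f_res = stats.f_oneway(*arrays)
        values = np.concatenate(arrays)
        labels = np.concatenate([[n] * groups[n].size for n in names])
        tuk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        summ = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        pairwise = [
            PairwiseResult(
                a=str(r["group1"]), b=str(r["group2"]),
                statistic=float(r["meandiff"]), p_adj=float(r["p-adj"]),
                significant=bool(r["reject"]),
            )
            for _, r in summ.iterrows()
        ]
        method, stat, p = "anova_tukey", float(f_res.statistic), float(f_res.pvalue)
    else:
        pairwise = _welch_sidak_pairs(groups, alpha)
        w_res = stats.f_oneway(*arrays)  # descriptive omnibus alongside Welch pairs
        method, stat, p = "dunnett_t3", float(w_res.statistic), float(w_res.pvalue)

    distinct = {frozenset((pr.a, pr.b)) for pr in pairwise if pr.significant}
    return GroupStatsResult(
        method=method, omnibus_stat=stat, omnibus_p=p, shapiro_p=shapiro_p,
        levene_p=levene_p, variances_homogeneous=homogeneous,
        pairwise=pairwise, letters=_compact_letters(names, distinct), alpha=alpha,
    )
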