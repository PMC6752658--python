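"""Expression thresholds, pair correlation, group tests and ΔΔCt.

The detection rule is the study's published one: an RPKM below 0.3 means
not expressed in that stage (detection is therefore >= 0.3), a gene is
expressed when detected in at least two stages, and has low expression
when its RPKM is below 1 in at least two thirds of the stages (ceiling:
9 of 13). Pair correlation is Pearson's r over the stages where both
genes are detected, with at least ``min_shared_stages`` shared stages
required for a defined value; a pair is "correlated" when r > 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisConfig, ExpressionMatrix, QpcrRecord

log = logging.getLogger("tandemdiv")


# ---------------------------------------------------------------------------
# Detection and low-expression calls
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCallSet:
    """Per-gene expressed/low flags plus the per-stage detection mask."""

    detected: pd.DataFrame  # genes x stages, bool
    expressed: pd.Series  # genes, bool
    low_expression: pd.Series  # genes, bool
    n_low_stages_required: int


def call_expression(
    m: ExpressionMatrix, config: AnalysisConfig | None = None
) -> ExpressionCallSet:
    config = config or AnalysisConfig()
    if m.values.empty:
        raise ValueError("empty expression matrix")
    if m.n_stages < 2:
        raise ValueError("need at least 2 stages")
    detected = m.values >= config.detection_threshold
    expressed = detected.sum(axis=1) >= config.min_expressed_stages
    n_required = math.ceil(config.low_expr_fraction * m.n_stages)
    low = (m.values < config.low_expr_threshold).sum(axis=1) >= n_required
    return ExpressionCallSet(
        detected=detected,
        expressed=expressed,
        low_expression=low,
        n_low_stages_required=n_required,
    )


# ---------------------------------------------------------------------------
# Pair correlation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPairResult:
    gene1: str
    gene2: str
    n_shared_stages: int
    r: float | None
    correlated: bool


def pair_correlation(
    m: ExpressionMatrix,
    g1: str,
    g2: str,
    config: AnalysisConfig | None = None,
) -> ExpressionPairResult:
    """Correlation of two expression profiles over co-detected stages.

    Values below the detection threshold in either gene are excluded, as
    are pairs with fewer than ``min_shared_stages`` co-detected stages
    (r = NA, not correlated).
    """
    config = config or AnalysisConfig()
    for g in (g1, g2):
        if g not in m.values.index:
            raise KeyError(f"gene {g} absent from expression matrix")
    v1 = m.profile(g1).to_numpy(dtype=float)
    v2 = m.profile(g2).to_numpy(dtype=float)
    mask = (v1 >= config.detection_threshold) & (v2 >= config.detection_threshold)
    n_shared = int(mask.sum())
    if n_shared < config.min_shared_stages:
        return ExpressionPairResult(g1, g2, n_shared, None, False)
    x, y = v1[mask], v2[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        return ExpressionPairResult(g1, g2, n_shared, None, False)
    if config.correlation_method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return ExpressionPairResult(g1, g2, n_shared, r, r > config.corr_threshold)


# ---------------------------------------------------------------------------
# Group comparison (Welch t-test)
# ---------------------------------------------------------------------------


def group_comparison(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch t-test between two groups of measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            log.warning("degenerate t-test: both groups constant and equal; p = 1")
            return 0.0, 1.0
        log.warning("degenerate t-test: both groups constant, unequal means; p = 0")
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# qPCR ΔΔCt
# ---------------------------------------------------------------------------


@dataclass
class DdctResult:
    gene_id: str
    condition: str
    timepoint: str
    n_replicates: int
    mean_dct: float
    ddct: float
    fold_change: float
    t_statistic: float | None
    p_value: float | None
    replicate_dct: tuple[float, ...] = field(default_factory=tuple)


def ddct_fold_change(
    records: Sequence[QpcrRecord], control_condition: str
) -> list[DdctResult]:
    """Relative expression by the 2^(−ΔΔCt) method.

    ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt is each
    (condition, timepoint) mean ΔCt minus the gene's control-condition
    mean; the control group pools all its timepoints. Significance against
    the control comes from a Welch t-test on replicate ΔCt values whenever
    both groups carry >= 2 replicates.
    """
    by_gene: dict[str, dict[tuple[str, str], list[float]]] = {}
    control: dict[str, list[float]] = {}
    for rec in records:
        dct = rec.ct_target - rec.ct_reference
        by_gene.setdefault(rec.gene_id, {}).setdefault(
            (rec.condition, rec.timepoint), []
        ).append(dct)
        if rec.condition == control_condition:
            control.setdefault(rec.gene_id, []).append(dct)

    results: list[DdctResult] = []
    for gene_id, groups in by_gene.items():
        if gene_id not in control:
            raise ValueError(
                f"{gene_id}: no control condition {control_condition!r} records"
            )
        ctrl_mean = float(np.mean(control[gene_id]))
        for (condition, timepoint), dcts in sorted(groups.items()):
            ddct = float(np.mean(dcts)) - ctrl_mean
            if condition != control_condition and len(dcts) >= 2 and len(
                control[gene_id]
            ) >= 2:
                t, p = group_comparison(dcts, control[gene_id])
            else:
                t = p = None
            results.append(
                DdctResult(
                    gene_id=gene_id,
                    condition=condition,
                    timepoint=timepoint,
                    n_replicates=len(dcts),
                    mean_dct=float(np.mean(dcts)),
                    ddct=ddct,
                    fold_change=2.0 ** (-ddct),
                    t_statistic=t,
                    p_value=p,
                    replicate_dct=tuple(dcts),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Class summaries
# ---------------------------------------------------------------------------


def percent(numerator: int, denominator: int) -> float | None:
    """Percentage at one decimal; None for an empty denominator."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


def format_percent(numerator: int, denominator: int) -> str:
    p = percent(numerator, denominator)
    return "NA" if p is None else f"{p}%"


def fold_ratio(pct_a: float | None, pct_b: float | None) -> float | None:
    """Ratio between two percentages at one decimal; None when undefined."""
    if pct_a is None or pct_b is None or pct_b == 0:
        return None
    return round(pct_a / pct_b, 1)


def summarize_class_statistics(
    labels: Sequence,
    calls: ExpressionCallSet,
    pairs: Sequence[ExpressionPairResult] = (),
    pair_classes: Mapping[tuple[str, str], str] | None = None,
) -> dict:
    """Class-level counts, percentages and fold ratios.

    ``labels`` are DuplicateLabels over the focal gene universe. Low
    expression is compared between tandem-or-clustered genes (type I or
    in a repeat) and the rest, and between lineage-specific and ancestral
    tandem genes. Exact fractions ride alongside the rounded percentages.
    """
    from .classify import ANCESTRAL, BOTH, LINEAGE_SPECIFIC, NONE

    by_id = {l.gene_id: l for l in labels}
    genes = list(by_id)
    low = {g: bool(calls.low_expression.get(g, False)) for g in genes}

    tandem = [g for g in genes if by_id[g].tandem_class != NONE]
    ls = [g for g in genes if by_id[g].tandem_class in (LINEAGE_SPECIFIC, BOTH)]
    anc = [g for g in genes if by_id[g].tandem_class in (ANCESTRAL, BOTH)]
    both = [g for g in genes if by_id[g].tandem_class == BOTH]
    clustered = [g for g in genes if by_id[g].gene_type == "I"]
    tand_clust = sorted(set(tandem) | set(clustered))
    others = [g for g in genes if g not in set(tand_clust)]

    def low_stats(group: list[str]) -> dict:
        n_low = sum(1 for g in group if low[g])
        return {
            "n": len(group),
            "n_low": n_low,
            "fraction_low": (n_low / len(group)) if group else None,
            "pct_low": percent(n_low, len(group)),
        }

    tc_stats = low_stats(tand_clust)
    other_stats = low_stats(others)
    ls_stats = low_stats(ls)
    anc_stats = low_stats(anc)

    summary = {
        "n_genes": len(genes),
        "n_tandem": len(tandem),
        "pct_tandem": percent(len(tandem), len(genes)),
        "n_lineage_specific": len(ls),
        "n_ancestral": len(anc),
        "n_both": len(both),
        "inclusion_exclusion_ok": len(ls) + len(anc) - len(both) == len(tandem),
        "tandem_or_clustered": tc_stats,
        "other_genes": other_stats,
        "low_expression_fold_ratio": fold_ratio(
            tc_stats["pct_low"], other_stats["pct_low"]
        ),
        "lineage_specific_tandem": ls_stats,
        "ancestral_tandem": anc_stats,
    }

    if pairs:
        def corr_stats(selected: list[ExpressionPairResult]) -> dict:
            n_corr = sum(1 for p in selected if p.correlated)
            return {
                "n_pairs": len(selected),
                "n_correlated": n_corr,
                "fraction_correlated": (n_corr / len(selected)) if selected else None,
                "pct_correlated": percent(n_corr, len(selected)),
            }

        summary["pairs"] = corr_stats(list(pairs))
        if pair_classes:
            for cls in (LINEAGE_SPECIFIC, ANCESTRAL):
                sel = [
                    p
                    for p in pairs
                    if pair_classes.get((p.gene1, p.gene2))
                    == cls or pair_classes.get((p.gene2, p.gene1)) == cls
                ]
                summary[f"pairs_{cls}"] = corr_stats(sel)
    return summary


def log_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """log2(RPKM + 1) transform used for heatmap export."""
    return np.log2(m.values + 1.0)
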