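"""Variability filtering, expression~psi regression and UHP/DHP/type-0 labels.

For each cassette event that passes the variability filter, total gene
expression is regressed on psi by ordinary least squares,

    Y(g) ~ beta0 + beta1 * psi,

the slope p-value is corrected with Benjamini-Hochberg within each sample
group, and the event is labelled:

* UHP   -- adjusted p <= alpha, R^2 >= 0.5, 95/5 percentile ratio >= 2,
           beta1 > 0 (higher inclusion predicts higher expression);
* DHP   -- same with beta1 < 0;
* TYPE0 -- adjusted p >= 0.5 with the same variability evidence: substantial
           expression variability but strong evidence of no coupling;
* INDETERMINATE otherwise (including degenerate fits).

The 95/5 percentile ratio appears both in the upstream filter (exon
expression) and in the classification criteria.  Both ratios are computed and
reported; classification uses the exon-level one by default (``ratio_basis``)
-- with the package's generative model the gene-level ratio of an expression-
coupled event is bounded near (1+b*0.86)/(1+b*0.14) and sits below 2 at
moderate effect sizes, which would veto genuinely coupled exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError
from .expression import EventQuant

UHP = "UHP"
DHP = "DHP"
TYPE0 = "TYPE0"
INDETERMINATE = "INDETERMINATE"

UHP_GENE = "UHP_GENE"
DHP_GENE = "DHP_GENE"
TYPE0_GENE = "TYPE0_GENE"
MIXED = "MIXED"
NONE = "NONE"


@dataclass
class Thresholds:
    """Filter and classification thresholds.

    min_mean : minimum mean exon expression (expression units; the
        published analysis used 20 counts).
    min_expressed_fraction : minimum fraction of samples with exon
        expression >= 1.
    min_ratio : minimum 95th/5th percentile ratio of expression values.
    alpha : adjusted-p significance threshold (inclusive).
    type0_min_p : minimum adjusted p for a type-0 call (inclusive).
    min_r2 : minimum coefficient of determination for UHP/DHP.
    ratio_basis : which percentile ratio the classification criteria use,
        "exon" (default) or "gene"; both are always reported.
    """

    min_mean: float = 20.0
    min_expressed_fraction: float = 0.5
    min_ratio: float = 2.0
    alpha: float = 0.05
    type0_min_p: float = 0.5
    min_r2: float = 0.5
    ratio_basis: str = "exon"

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with open(path) as handle:
            doc = yaml.safe_load(handle) or {}
        doc = doc.get("thresholds", doc)
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterDecision:
    """Outcome of the expression-variability filter for one event."""

    event_id: str
    expressed_fraction: float
    mean_expr: float
    p95_p5_ratio: float  # NaN when the 5th percentile is 0
    passed: bool


@dataclass
class RegressionFit:
    """OLS fit of gene expression on psi for one event."""

    event_id: str
    beta0: float
    beta1: float
    p_slope: float
    r2: float
    n_used: int
    gene_p95_p5_ratio: float
    degenerate: bool = False


@dataclass
class ClassifiedEvent:
    """A labelled event within one sample group."""

    event_id: str
    gene_id: str
    group: str
    fit: RegressionFit
    adj_p: float
    label: str
    filter_decision: FilterDecision | None = None


def _percentile_ratio(values: np.ndarray) -> float:
    """95th/5th percentile ratio (linear interpolation); NaN when p5 <= 0."""
    p5, p95 = np.percentile(values, [5, 95])
    if p5 <= 0:
        return float("nan")
    return float(p95 / p5)


def variability_filter(quant: EventQuant, thresholds: Thresholds | None = None) -> FilterDecision:
    """Apply the expression-variability filter to one event.

    An event passes when its exon expression (ITinc) is >= 1 in at least
    half the samples, has mean >= 20 and a 95/5 percentile ratio >= 2.
    An undefined ratio (5th percentile zero) fails the filter.
    """
    th = thresholds or Thresholds()
    exon = np.asarray(quant.exon_expr, dtype=float)
    if exon.size == 0:
        raise ValidationError("variability_filter: no samples")
    expressed_fraction = float(np.mean(exon >= 1))
    mean_expr = float(np.mean(exon))
    ratio = _percentile_ratio(exon)
    passed = (
        expressed_fraction >= th.min_expressed_fraction
        and mean_expr >= th.min_mean
        and not np.isnan(ratio)
        and ratio >= th.min_ratio
    )
    return FilterDecision(
        event_id=quant.event_id,
        expressed_fraction=expressed_fraction,
        mean_expr=mean_expr,
        p95_p5_ratio=ratio,
        passed=passed,
    )


def fit_expression_psi(quant: EventQuant) -> RegressionFit:
    """OLS of gene expression on psi over samples with defined psi.

    The slope p-value is the two-sided t test with n-2 degrees of freedom;
    R^2 = 1 - SSres/SStot.  Fewer than 3 defined samples or constant psi
    yield a degenerate fit (flagged, never raising) so the event becomes
    INDETERMINATE downstream.
    """
    mask = quant.defined_mask()
    psi = quant.psi[mask]
    y = quant.gene_expr[mask]
    n = int(mask.sum())

    def _degenerate() -> RegressionFit:
        gene_ratio = _percentile_ratio(y) if n else float("nan")
        return RegressionFit(
            event_id=quant.event_id,
            beta0=float("nan"), beta1=float("nan"),
            p_slope=float("nan"), r2=float("nan"),
            n_used=n, gene_p95_p5_ratio=gene_ratio, degenerate=True,
        )

    if n < 3 or np.ptp(psi) == 0:
        return _degenerate()
    gene_ratio = _percentile_ratio(y)
    if np.ptp(y) == 0:
        # constant response: flat line explains nothing, slope is exactly 0
        return RegressionFit(
            event_id=quant.event_id,
            beta0=float(y[0]), beta1=0.0, p_slope=1.0, r2=0.0,
            n_used=n, gene_p95_p5_ratio=gene_ratio,
        )
    res = stats.linregress(psi, y)
    return RegressionFit(
        event_id=quant.event_id,
        beta0=float(res.intercept),
        beta1=float(res.slope),
        p_slope=float(res.pvalue),
        r2=float(res.rvalue**2),
        n_used=n,
        gene_p95_p5_ratio=gene_ratio,
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p[i] = min over j with p[j] >= p[i] of p[j] * n / rank(j), capped at
    1; invariant under permutation of the input order.  Values outside [0,1]
    raise ValidationError.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def classify_event(
    fit: RegressionFit,
    adj_p: float,
    filter_decision: FilterDecision,
    thresholds: Thresholds | None = None,
) -> str:
    """Assign UHP / DHP / TYPE0 / INDETERMINATE from a fit and its context."""
    th = thresholds or Thresholds()
    if fit.degenerate or np.isnan(adj_p):
        return INDETERMINATE
    ratio = (
        filter_decision.p95_p5_ratio
        if th.ratio_basis == "exon"
        else fit.gene_p95_p5_ratio
    )
    ratio_ok = not np.isnan(ratio) and ratio >= th.min_ratio
    significant = adj_p <= th.alpha and fit.r2 >= th.min_r2 and ratio_ok
    if significant and fit.beta1 > 0:
        return UHP
    if significant and fit.beta1 < 0:
        return DHP
    if adj_p >= th.type0_min_p and ratio_ok and filter_decision.passed:
        return TYPE0
    return INDETERMINATE


def label_genes(events: Iterable[ClassifiedEvent]) -> dict[str, str]:
    """Gene-level labels from one group's classified events.

    UHP_GENE: at least one UHP exon, no DHP and no type-0 exon; DHP_GENE and
    TYPE0_GENE symmetric; MIXED when labelled exons of several kinds coexist;
    NONE when the gene has no labelled exon (indeterminate only).
    """
    per_gene: dict[str, set[str]] = {}
    for ev in events:
        per_gene.setdefault(ev.gene_id, set()).add(ev.label)
    out = {}
    for gene_id, labels in per_gene.items():
        labels = labels & {UHP, DHP, TYPE0}
        if not labels:
            out[gene_id] = NONE
        elif labels == {UHP}:
            out[gene_id] = UHP_GENE
        elif labels == {DHP}:
            out[gene_id] = DHP_GENE
        elif labels == {TYPE0}:
            out[gene_id] = TYPE0_GENE
        else:
            out[gene_id] = MIXED
    return out


@dataclass
class ConsistencySummary:
    """Cross-group agreement of UHP/DHP assignments."""

    n_multi_group: int
    n_consistent: int
    n_conflicts: int
    conflict_events: list[str] = field(default_factory=list)
    crosstab: pd.DataFrame | None = None


def consistency_report(
    results_by_group: Mapping[str, Sequence[ClassifiedEvent]],
    other: Mapping[str, str] | None = None,
) -> ConsistencySummary:
    """Agreement of coupled-exon calls across >= 2 sample groups.

    Counts events called UHP or DHP in two or more groups, how many carry
    the same label everywhere, and how many conflict (UHP in one group, DHP
    in another).  When ``other`` maps event_id -> label from an independent
    result set, a label x label cross-tabulation is attached (replication-
    style comparison).
    """
    if len(results_by_group) < 2 and other is None:
        raise ValidationError("consistency_report needs >= 2 groups")
    coupled: dict[str, set[str]] = {}
    any_label: dict[str, set[str]] = {}
    for group, events in results_by_group.items():
        for ev in events:
            any_label.setdefault(ev.event_id, set()).add(ev.label)
            if ev.label in (UHP, DHP):
                coupled.setdefault(ev.event_id, set()).add((group, ev.label))
    multi = {
        eid: {lab for _, lab in calls}
        for eid, calls in coupled.items()
        if len(calls) >= 2
    }
    conflicts = sorted(eid for eid, labs in multi.items() if len(labs) > 1)
    crosstab = None
    if other is not None:
        rows = []
        for eid, labels in any_label.items():
            if eid not in other:
                continue
            # one row per (event, label-in-this-run)
            for lab in labels:
                rows.append((lab, other[eid]))
        if rows:
            df = pd.DataFrame(rows, columns=["this", "other"])
            crosstab = pd.crosstab(df["this"], df["other"])
        else:
            crosstab = pd.DataFrame()
    return ConsistencySummary(
        n_multi_group=len(multi),
        n_consistent=len(multi) - len(conflicts),
        n_conflicts=len(conflicts),
        conflict_events=conflicts,
        crosstab=crosstab,
    )


@dataclass
class SlopeMeanFit:
    """OLS of per-event slopes against mean gene expression."""

    coefficient: float
    stderr: float
    intercept: float
    n: int


def slope_vs_mean_expression(
    beta1: Sequence[float] | np.ndarray,
    mean_expr: Sequence[float] | np.ndarray,
) -> SlopeMeanFit:
    """Regress per-event slopes beta1 on mean gene expression.

    For coupled exons the fitted slope scales with the gene's expression
    level; the returned coefficient is the OLS slope of beta1 against mean
    expression (with intercept).  Degenerate input (fewer than 3 events or
    constant mean expression) yields NaN fields.
    """
    b = np.asarray(beta1, dtype=float)
    m = np.asarray(mean_expr, dtype=float)
    if b.size != m.size:
        raise ValidationError("slope_vs_mean_expression: length mismatch")
    if b.size < 3 or np.ptp(m) == 0:
        return SlopeMeanFit(float("nan"), float("nan"), float("nan"), int(b.size))
    res = stats.linregress(m, b)
    return SlopeMeanFit(
        coefficient=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        n=int(b.size),
    )
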