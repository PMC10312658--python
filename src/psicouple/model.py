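"""Statsmodels-style front end: CouplingModel.fit() -> CouplingResults.

The model object bundles an annotation (transcript models and derived
cassette events), an expression matrix and the thresholds; ``fit`` runs
quantification, filtering, per-event OLS, within-group BH correction and
classification for every sample group and returns a results object carrying
the per-event table, label counts, cross-group consistency and summary
reporting.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classify as cl
from .classify import (
    ClassifiedEvent, ConsistencySummary, SlopeMeanFit, Thresholds,
)
from .errors import MissingGeneError, ValidationError
from .expression import ExpressionMatrix, event_psi, read_gct

logger = logging.getLogger(__name__)

_TABLE_COLUMNS = [
    "group", "event_id", "gene_id", "n_samples", "n_used",
    "expressed_fraction", "mean_exon_expr", "mean_gene_expr",
    "exon_p95_p5_ratio", "gene_p95_p5_ratio", "filter_passed",
    "beta0", "beta1", "p", "adj_p", "r2", "label",
]


class CouplingModel:
    """Expression-splicing coupling model over one annotation and matrix.

    Parameters
    ----------
    genes : mapping gene_id -> list of TranscriptModel
    events : list of CassetteEvent, optional
        Collapsed cassette events; derived from ``genes`` when omitted.
    matrix : ExpressionMatrix
    thresholds : Thresholds, optional
    """

    def __init__(
        self,
        genes: Mapping[str, Sequence[ann.TranscriptModel]],
        matrix: ExpressionMatrix,
        events: Sequence[ann.CassetteEvent] | None = None,
        thresholds: Thresholds | None = None,
    ) -> None:
        self.genes = dict(genes)
        self.matrix = matrix
        self.events = (
            list(events) if events is not None else ann.discover_events(self.genes)
        )
        self.thresholds = thresholds or Thresholds()

    @classmethod
    def from_files(
        cls,
        gtf_path,
        gct_path,
        sample_groups: Mapping[str, str] | None = None,
        thresholds: Thresholds | None = None,
    ) -> "CouplingModel":
        genes = ann.read_gtf(gtf_path)
        matrix = read_gct(gct_path, sample_groups=sample_groups)
        return cls(genes, matrix, thresholds=thresholds)

    def fit(self, groups: Sequence[str] | None = None) -> "CouplingResults":
        """Run the per-group analysis for every (or the given) sample group."""
        if groups is None:
            groups = self.matrix.groups() or ["all"]
        rows = []
        classified: dict[str, list[ClassifiedEvent]] = {}
        stage_counts: dict[str, dict[str, int]] = {}
        for group in groups:
            sub = (
                self.matrix.subset_group(group)
                if self.matrix.sample_groups
                else self.matrix
            )
            group_rows, group_events, counts = self._fit_group(group, sub)
            rows.extend(group_rows)
            classified[group] = group_events
            stage_counts[group] = counts
        table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
        return CouplingResults(self, table, classified, stage_counts)

    def _fit_group(self, group: str, matrix: ExpressionMatrix):
        quants, filters, fits = [], [], []
        counts = {"events": len(self.events), "quantified": 0, "filter_passed": 0}
        for event in self.events:
            try:
                quant = event_psi(matrix, event)
            except MissingGeneError:
                logger.warning("group %s: event %s absent from matrix",
                               group, event.event_id)
                continue
            counts["quantified"] += 1
            decision = cl.variability_filter(quant, self.thresholds)
            if not decision.passed:
                continue
            counts["filter_passed"] += 1
            quants.append(quant)
            filters.append(decision)
            fits.append(cl.fit_expression_psi(quant))

        # BH within the group over events with a defined slope p-value
        defined_idx = [i for i, f in enumerate(fits) if not f.degenerate]
        adj = np.full(len(fits), np.nan)
        if defined_idx:
            adj[defined_idx] = cl.bh_adjust([fits[i].p_slope for i in defined_idx])

        rows, events_out = [], []
        label_counts = {lab: 0 for lab in (cl.UHP, cl.DHP, cl.TYPE0, cl.INDETERMINATE)}
        for quant, decision, fit, adj_p in zip(quants, filters, fits, adj):
            label = cl.classify_event(fit, adj_p, decision, self.thresholds)
            label_counts[label] += 1
            events_out.append(
                ClassifiedEvent(
                    event_id=quant.event_id,
                    gene_id=quant.gene_id,
                    group=group,
                    fit=fit,
                    adj_p=float(adj_p),
                    label=label,
                    filter_decision=decision,
                )
            )
            mask = quant.defined_mask()
            rows.append({
                "group": group,
                "event_id": quant.event_id,
                "gene_id": quant.gene_id,
                "n_samples": len(quant.sample_ids),
                "n_used": fit.n_used,
                "expressed_fraction": decision.expressed_fraction,
                "mean_exon_expr": decision.mean_expr,
                "mean_gene_expr": float(np.mean(quant.gene_expr[mask]))
                if mask.any() else float("nan"),
                "exon_p95_p5_ratio": decision.p95_p5_ratio,
                "gene_p95_p5_ratio": fit.gene_p95_p5_ratio,
                "filter_passed": decision.passed,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "p": fit.p_slope,
                "adj_p": float(adj_p),
                "r2": fit.r2,
                "label": label,
            })
        counts.update({f"label_{k}": v for k, v in label_counts.items()})
        return rows, events_out, counts


class CouplingResults:
    """Results of CouplingModel.fit().

    Attributes
    ----------
    table : DataFrame
        One row per analyzed event per group (events failing the
        variability filter are not analyzed and do not appear).
    classified : dict group -> list of ClassifiedEvent
    stage_counts : dict group -> dict of stage-by-stage event counts
    """

    def __init__(self, model, table, classified, stage_counts) -> None:
        self.model = model
        self.table = table
        self.classified = classified
        self.stage_counts = stage_counts
        self.thresholds = model.thresholds

    # -- label accounting ------------------------------------------------

    def label_counts(self, group: str | None = None) -> pd.Series:
        df = self.table
        if group is not None:
            df = df[df["group"] == group]
        counts = df["label"].value_counts()
        return counts.reindex(
            [cl.UHP, cl.DHP, cl.TYPE0, cl.INDETERMINATE], fill_value=0
        )

    def coupled_event_ids(self) -> set[str]:
        mask = self.table["label"].isin([cl.UHP, cl.DHP])
        return set(self.table.loc[mask, "event_id"])

    def gene_labels(self, group: str | None = None) -> dict[str, str]:
        if group is None:
            groups = list(self.classified)
            if len(groups) != 1:
                raise ValidationError("gene_labels: specify a group")
            group = groups[0]
        return cl.label_genes(self.classified[group])

    # -- cross-group comparisons ----------------------------------------

    def consistency(
        self, other: Mapping[str, str] | None = None
    ) -> ConsistencySummary:
        return cl.consistency_report(self.classified, other=other)

    def slope_vs_mean(
        self,
        mean_expr: Mapping[str, float] | None = None,
        labels: Sequence[str] = (cl.UHP, cl.DHP),
        fold_sign: bool = True,
    ) -> SlopeMeanFit:
        """Regression of fitted slopes against mean gene expression.

        Uses the observed mean gene expression per event unless a mapping
        event_id -> mean expression is supplied (e.g. a known baseline).
        With ``fold_sign`` DHP slopes enter with flipped sign so both
        coupling directions share one scale.
        """
        df = self.table[self.table["label"].isin(labels)]
        b = df["beta1"].to_numpy(dtype=float)
        if fold_sign:
            b = np.where(df["label"].to_numpy() == cl.DHP, -b, b)
        if mean_expr is None:
            m = df["mean_gene_expr"].to_numpy(dtype=float)
        else:
            m = np.array([mean_expr[e] for e in df["event_id"]], dtype=float)
        return cl.slope_vs_mean_expression(b, m)

    # -- reporting -------------------------------------------------------

    def run_summary(self):
        from .pipeline import aggregate_summary

        return aggregate_summary(self)

    def summary(self) -> str:
        """Human-readable per-group summary table."""
        lines = ["Expression-splicing coupling results", "=" * 38]
        lines.append(
            f"events: {len(self.model.events)}  groups: {len(self.classified)}"
        )
        lines.append(
            f"thresholds: alpha={self.thresholds.alpha} "
            f"min_r2={self.thresholds.min_r2} "
            f"min_ratio={self.thresholds.min_ratio} "
            f"(basis={self.thresholds.ratio_basis}) "
            f"type0_min_p={self.thresholds.type0_min_p}"
        )
        header = f"{'group':<12}{'analyzed':>9}{'UHP':>7}{'DHP':>7}{'TYPE0':>7}{'INDET':>7}"
        lines.append(header)
        lines.append("-" * len(header))
        for group in self.classified:
            c = self.label_counts(group)
            lines.append(
                f"{group:<12}{int(c.sum()):>9}{c[cl.UHP]:>7}{c[cl.DHP]:>7}"
                f"{c[cl.TYPE0]:>7}{c[cl.INDETERMINATE]:>7}"
            )
        return "\n".join(lines)

    def to_tsv(self, path=None) -> str | None:
        text = self.table.to_csv(sep="\t", index=False, float_format="%.6g")
        if path is None:
            return text
        with open(path, "w") as handle:
            handle.write(text)
        return None
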