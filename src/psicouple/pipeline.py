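"""End-to-end orchestration and summary reporting.

``run_group_analysis`` executes annotation -> quantification -> filtering ->
regression -> classification for one sample group; ``aggregate_summary``
combines per-group results into a run summary: unique coupled exons across
groups, prevalence percentages (one-decimal, round half away from zero) and
a characterization table of exon/intron lengths, transcript counts,
inclusion proportions and biotype fractions per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classify as cl
from .errors import ValidationError
from .expression import ExpressionMatrix
from .occupancy import rank_sum_test


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with round-half-away-from-zero at ``decimals`` places.

    Integer inputs are computed exactly through Decimal so printed-count
    arithmetic (e.g. 6874 of 141043 -> 4.9) is reproducible bit-for-bit.
    """
    if denominator == 0:
        raise ValidationError("percent: zero denominator")
    if float(numerator) == int(numerator) and float(denominator) == int(denominator):
        value = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    else:
        value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def run_group_analysis(
    genes: Mapping[str, Sequence[ann.TranscriptModel]],
    matrix: ExpressionMatrix,
    group: str | None = None,
    thresholds: cl.Thresholds | None = None,
):
    """Classify every cassette event for one sample group.

    Returns (CouplingResults restricted to the group, stage-count dict).
    A failing event is logged and skipped, never aborting the run.
    """
    from .model import CouplingModel

    model = CouplingModel(genes, matrix, thresholds=thresholds)
    groups = [group] if group is not None else None
    results = model.fit(groups=groups)
    key = group if group is not None else next(iter(results.stage_counts))
    return results, results.stage_counts[key]


@dataclass
class RunSummary:
    """Aggregated results across sample groups."""

    per_group: pd.DataFrame          # analyzed/UHP/DHP/TYPE0/INDETERMINATE counts
    n_unique_analyzed: int
    n_unique_coupled: int            # distinct exons called UHP or DHP anywhere
    coupled_exon_percent: float
    n_identifications: int           # UHP/DHP calls with multiplicity
    n_genes: int                     # genes with >= 1 classified (UHP/DHP/TYPE0) exon
    n_coupled_genes: int
    coupled_gene_percent: float
    characterization: pd.DataFrame | None = None
    biotype_fractions: pd.DataFrame | None = None

    def to_json(self) -> str:
        doc = {
            "per_group": self.per_group.to_dict(orient="index"),
            "n_unique_analyzed": self.n_unique_analyzed,
            "n_unique_coupled": self.n_unique_coupled,
            "coupled_exon_percent": self.coupled_exon_percent,
            "n_identifications": self.n_identifications,
            "n_genes": self.n_genes,
            "n_coupled_genes": self.n_coupled_genes,
            "coupled_gene_percent": self.coupled_gene_percent,
        }
        if self.characterization is not None:
            doc["characterization"] = json.loads(
                self.characterization.to_json(orient="index")
            )
        if self.biotype_fractions is not None:
            doc["biotype_fractions"] = json.loads(
                self.biotype_fractions.to_json(orient="index")
            )
        return json.dumps(doc, indent=2)


def summary_from_counts(
    n_coupled_exons: int,
    n_analyzed_exons: int,
    n_coupled_genes: int,
    n_genes: int,
    n_identifications: int | None = None,
) -> RunSummary:
    """RunSummary arithmetic from plain counts (prevalence reporting)."""
    return RunSummary(
        per_group=pd.DataFrame(),
        n_unique_analyzed=n_analyzed_exons,
        n_unique_coupled=n_coupled_exons,
        coupled_exon_percent=percent(n_coupled_exons, n_analyzed_exons),
        n_identifications=(
            n_identifications if n_identifications is not None else n_coupled_exons
        ),
        n_genes=n_genes,
        n_coupled_genes=n_coupled_genes,
        coupled_gene_percent=percent(n_coupled_genes, n_genes),
    )


def aggregate_summary(
    results,
    genes: Mapping[str, Sequence[ann.TranscriptModel]] | None = None,
    events: Sequence[ann.CassetteEvent] | None = None,
) -> RunSummary:
    """Aggregate a CouplingResults across its sample groups.

    ``genes``/``events`` default to the fitted model's own; when present the
    summary additionally carries the per-class characterization table
    (medians with rank-sum p-values between classes) and biotype fractions.
    """
    table = results.table
    genes = genes if genes is not None else results.model.genes
    events = events if events is not None else results.model.events

    groups = list(dict.fromkeys(table["group"]))
    rows = {}
    for group in groups:
        sub = table[table["group"] == group]
        counts = sub["label"].value_counts()
        rows[group] = {
            "analyzed": int(len(sub)),
            cl.UHP: int(counts.get(cl.UHP, 0)),
            cl.DHP: int(counts.get(cl.DHP, 0)),
            cl.TYPE0: int(counts.get(cl.TYPE0, 0)),
            cl.INDETERMINATE: int(counts.get(cl.INDETERMINATE, 0)),
        }
    per_group = pd.DataFrame.from_dict(rows, orient="index")

    coupled_mask = table["label"].isin([cl.UHP, cl.DHP])
    unique_analyzed = table["event_id"].nunique()
    unique_coupled = table.loc[coupled_mask, "event_id"].nunique()
    classed_mask = table["label"].isin([cl.UHP, cl.DHP, cl.TYPE0])
    gene_universe = table.loc[classed_mask, "gene_id"].nunique()
    coupled_genes = table.loc[coupled_mask, "gene_id"].nunique()

    characterization = None
    biotypes = None
    if genes and events:
        characterization, biotypes = _characterize(table, genes, events)

    return RunSummary(
        per_group=per_group,
        n_unique_analyzed=int(unique_analyzed),
        n_unique_coupled=int(unique_coupled),
        coupled_exon_percent=(
            percent(unique_coupled, unique_analyzed) if unique_analyzed else float("nan")
        ),
        n_identifications=int(coupled_mask.sum()),
        n_genes=int(gene_universe),
        n_coupled_genes=int(coupled_genes),
        coupled_gene_percent=(
            percent(coupled_genes, gene_universe) if gene_universe else float("nan")
        ),
        characterization=characterization,
        biotype_fractions=biotypes,
    )


_CLASS_ORDER = (cl.TYPE0, cl.UHP, cl.DHP)


def _characterize(table, genes, events):
    """Per-class medians of structural features + pairwise rank-sum tests.

    An exon called e.g. UHP in one group and TYPE0 in another contributes to
    both classes (multi-class genes count for each of their classes).
    """
    by_id = {ev.event_id: ev for ev in events}
    # class -> event_ids (unique, any group)
    class_events: dict[str, set[str]] = {c: set() for c in _CLASS_ORDER}
    for _, row in table.iterrows():
        if row["label"] in class_events and row["event_id"] in by_id:
            class_events[row["label"]].add(row["event_id"])

    features: dict[str, dict[str, list[float]]] = {
        c: {"exon_length": [], "upstream_intron": [], "downstream_intron": [],
            "transcripts_per_gene": [], "inclusion_proportion": []}
        for c in _CLASS_ORDER
    }
    biotype_counts: dict[str, dict[str, int]] = {c: {} for c in _CLASS_ORDER}
    for label, ids in class_events.items():
        for event_id in sorted(ids):
            ev = by_id[event_id]
            gene = list(genes[ev.gene_id])
            feats = features[label]
            feats["exon_length"].append(ev.end - ev.start)
            fl = ann.flanking_intron_lengths(ev, gene)
            if fl.upstream_length is not None:
                feats["upstream_intron"].append(fl.upstream_length)
            if fl.downstream_length is not None:
                feats["downstream_intron"].append(fl.downstream_length)
            feats["transcripts_per_gene"].append(len(gene))
            feats["inclusion_proportion"].append(
                len(ev.inclusion_set)
                / (len(ev.inclusion_set) + len(ev.exclusion_set))
            )
            for tx in gene:
                if tx.transcript_id in ev.inclusion_set:
                    biotype_counts[label][tx.biotype] = (
                        biotype_counts[label].get(tx.biotype, 0) + 1
                    )

    rows = []
    for feat in ("exon_length", "upstream_intron", "downstream_intron",
                 "transcripts_per_gene", "inclusion_proportion"):
        row = {"feature": feat}
        for c in _CLASS_ORDER:
            vals = features[c][feat]
            row[f"median_{c}"] = float(np.median(vals)) if vals else float("nan")
        for a, b in ((cl.TYPE0, cl.UHP), (cl.TYPE0, cl.DHP), (cl.UHP, cl.DHP)):
            va, vb = features[a][feat], features[b][feat]
            if len(va) >= 1 and len(vb) >= 1 and (len(set(va)) > 1 or len(set(vb)) > 1):
                _, p = rank_sum_test(va, vb)
            else:
                p = float("nan")
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    characterization = pd.DataFrame(rows).set_index("feature")

    bio_rows = {}
    for c in _CLASS_ORDER:
        total = sum(biotype_counts[c].values())
        bio_rows[c] = {
            bt: count / total for bt, count in sorted(biotype_counts[c].items())
        } if total else {}
    biotypes = pd.DataFrame.from_dict(bio_rows, orient="index").fillna(0.0)
    return characterization, biotypes
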