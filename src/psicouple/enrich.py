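"""Label-permutation motif enrichment, GO over-representation and
psi-vs-marker correlation.

The motif statistic is Delta: the difference, in percentage points, between
the proportions of focus-class and type-0 units (genes/promoters) carrying a
hit of a binding-factor model.  Significance comes from permuting the class
labels over units while retaining class sizes: the empirical p-value is the
proportion of permutation replicates whose Delta' strictly exceeds the
observed Delta.  Isoform-level GO over-representation uses the upper-tail
hypergeometric test over the classed-isoform universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import DHP_GENE, TYPE0_GENE, UHP_GENE
from .errors import ValidationError

_REPORT_DECIMALS = 10  # reporting precision for percentage-point quantities


@dataclass
class HitMatrix:
    """Binary unit x factor hit matrix with a class label per unit."""

    hits: pd.DataFrame  # index unit_id, columns factor ids, values {0,1}
    labels: pd.Series   # index unit_id -> class label

    def __post_init__(self) -> None:
        values = self.hits.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("HitMatrix: hits must be 0/1")
        self.labels = self.labels.reindex(self.hits.index)
        if self.labels.isna().any():
            missing = self.hits.index[self.labels.isna()].tolist()
            raise ValidationError(f"HitMatrix: unlabeled units {missing[:5]}")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.hits.index)

    @property
    def factor_ids(self) -> list[str]:
        return list(self.hits.columns)

    @classmethod
    def from_tsv(cls, source) -> "HitMatrix":
        df = pd.read_csv(source, sep="\t", index_col=0)
        if "label" not in df.columns:
            raise ValidationError("hit TSV needs a 'label' column")
        labels = df["label"]
        hits = df.drop(columns=["label"]).astype(int)
        return cls(hits=hits, labels=labels)

    def to_tsv(self) -> str:
        df = self.hits.copy()
        df.insert(0, "label", self.labels)
        return df.to_csv(sep="\t", index_label="unit_id")


@dataclass
class EnrichmentResult:
    """Permutation-test outcome for one factor and one class comparison."""

    factor_id: str
    focus_class: str
    baseline_class: str
    prop_focus: float   # percent of focus units with a hit
    prop_baseline: float
    delta: float        # percentage points
    p_emp: float
    p_bonf: float
    excluded: bool
    exclusion_reason: str = ""


@dataclass
class GoEnrichment:
    """Hypergeometric over-representation of UHP isoforms in one GO term."""

    go_id: str
    n_term: int     # classed isoforms annotated to the term
    k_uhp: int      # UHP isoforms among them
    coverage: float
    p: float
    adj_p: float


def proportion_difference(prop_focus: float, prop_baseline: float) -> float:
    """Delta between two hit proportions already expressed in percent.

    Rounded to reporting precision so printed one-decimal proportions give
    the exact printed difference (e.g. 32.6 and 17.2 -> 15.4).
    """
    return round(prop_focus - prop_baseline, _REPORT_DECIMALS)


def _class_proportions(
    hits: np.ndarray, labels: np.ndarray, focus: str, baseline: str
) -> tuple[float, float]:
    focus_mask = labels == focus
    base_mask = labels == baseline
    if not focus_mask.any() or not base_mask.any():
        raise ValidationError(
            f"delta_statistic: empty class ({focus if not focus_mask.any() else baseline})"
        )
    return (
        100.0 * hits[focus_mask].mean(),
        100.0 * hits[base_mask].mean(),
    )


def delta_statistic(
    matrix: HitMatrix,
    factor_id: str,
    focus_class: str = UHP_GENE,
    baseline_class: str = TYPE0_GENE,
) -> float:
    """Observed Delta (percentage points) of one factor, focus vs baseline."""
    hits = matrix.hits[factor_id].to_numpy(dtype=float)
    labels = matrix.labels.to_numpy()
    prop_f, prop_b = _class_proportions(hits, labels, focus_class, baseline_class)
    return proportion_difference(prop_f, prop_b)


def _distinct_label_assignments(labels: np.ndarray):
    """Yield every distinct assignment of the label multiset to positions."""
    classes, counts = np.unique(labels, return_counts=True)
    n = labels.size

    def recurse(positions: tuple[int, ...], class_idx: int, assignment: np.ndarray):
        if class_idx == len(classes) - 1:
            out = assignment.copy()
            out[list(positions)] = classes[class_idx]
            yield out
            return
        for chosen in combinations(positions, counts[class_idx]):
            out = assignment.copy()
            out[list(chosen)] = classes[class_idx]
            remaining = tuple(p for p in positions if p not in set(chosen))
            yield from recurse(remaining, class_idx + 1, out)

    yield from recurse(tuple(range(n)), 0, np.empty(n, dtype=labels.dtype))


def permutation_pvalue(
    matrix: HitMatrix,
    factor_id: str,
    focus_class: str = UHP_GENE,
    baseline_class: str = TYPE0_GENE,
    n_perm: int = 1_000_000,
    seed: int | None = None,
    exhaustive: bool = False,
    plus_one: bool = False,
) -> float:
    """Empirical permutation p-value for one factor's Delta.

    Labels are shuffled without replacement over all units, retaining the
    class sizes; p = (# replicates with Delta' > Delta) / n_perm with strict
    inequality, so ties count against significance.  ``exhaustive``
    enumerates every distinct assignment of the label multiset (allowed for
    up to 12 units).  ``plus_one`` applies the (b+1)/(n+1) small-sample
    correction (off by default).
    """
    hits = matrix.hits[factor_id].to_numpy(dtype=float)
    labels = matrix.labels.to_numpy()
    prop_f, prop_b = _class_proportions(hits, labels, focus_class, baseline_class)
    delta_obs = prop_f - prop_b

    if exhaustive:
        if labels.size > 12:
            raise ValidationError("exhaustive enumeration limited to <= 12 units")
        exceed = 0
        total = 0
        for assignment in _distinct_label_assignments(labels):
            pf, pb = _class_proportions(hits, assignment, focus_class, baseline_class)
            total += 1
            if pf - pb > delta_obs + 1e-12:
                exceed += 1
        return exceed / total

    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    exceed = 0
    codes = np.where(
        labels == focus_class, 1, np.where(labels == baseline_class, 2, 0)
    ).astype(np.int8)
    focus_n = int((codes == 1).sum())
    base_n = int((codes == 2).sum())
    chunk = max(1, min(n_perm, 20_000_000 // labels.size))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(codes, (m, 1)), axis=1)
        pf = (hits * (perm == 1)).sum(axis=1) / focus_n
        pb = (hits * (perm == 2)).sum(axis=1) / base_n
        exceed += int((100.0 * (pf - pb) > delta_obs + 1e-12).sum())
        done += m
    if plus_one:
        return (exceed + 1) / (n_perm + 1)
    return exceed / n_perm


_DEFAULT_COMPARISONS = (
    (UHP_GENE, TYPE0_GENE),
    (DHP_GENE, TYPE0_GENE),
    (UHP_GENE, DHP_GENE),
)


def motif_screen(
    matrix: HitMatrix,
    n_perm: int = 1_000_000,
    seed: int | None = None,
    comparisons: Sequence[tuple[str, str]] = _DEFAULT_COMPARISONS,
    min_delta: float = 0.5,
    min_relative: float = 0.05,
) -> list[EnrichmentResult]:
    """Permutation screen over every factor and class comparison.

    Bonferroni multiplicity is the number of tests actually performed.
    Tests with a tiny observed effect (|Delta| < ``min_delta`` percentage
    points, or |Delta| relative to the larger proportion < ``min_relative``)
    are flagged as excluded rather than dropped, so results stay auditable.
    """
    present = set(matrix.labels.unique())
    todo = [
        (factor, focus, base)
        for factor in matrix.factor_ids
        for focus, base in comparisons
        if focus in present and base in present
    ]
    n_tests = len(todo)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(n_tests)
    results = []
    for (factor, focus, base), child in zip(todo, child_seeds):
        hits = matrix.hits[factor].to_numpy(dtype=float)
        labels = matrix.labels.to_numpy()
        prop_f, prop_b = _class_proportions(hits, labels, focus, base)
        delta = proportion_difference(prop_f, prop_b)
        p_emp = permutation_pvalue(
            matrix, factor, focus, base,
            n_perm=n_perm, seed=child,
        )
        excluded = False
        reason = ""
        larger = max(prop_f, prop_b)
        if abs(delta) < min_delta:
            excluded = True
            reason = f"|delta| < {min_delta} percentage points"
        elif larger > 0 and abs(delta) / larger < min_relative:
            excluded = True
            reason = f"relative effect < {min_relative:.0%}"
        results.append(
            EnrichmentResult(
                factor_id=factor,
                focus_class=focus,
                baseline_class=base,
                prop_focus=prop_f,
                prop_baseline=prop_b,
                delta=delta,
                p_emp=p_emp,
                p_bonf=min(1.0, p_emp * n_tests),
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return results


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def go_hypergeometric(
    annotations: Mapping[str, Sequence[str]] | pd.DataFrame,
    isoform_classes: Mapping[str, str],
    uhp_label: str = "UHP",
    min_uhp: int = 5,
) -> list[GoEnrichment]:
    """Isoform-level GO over-representation of UHP isoforms.

    The population is all classed isoforms (UHP/DHP/type 0), successes the
    UHP isoforms.  For each GO term with >= ``min_uhp`` UHP isoforms
    annotated, the upper-tail hypergeometric p is computed, Bonferroni-
    corrected over tested terms, and results are sorted by p.  Isoforms
    annotated but not classed are ignored.
    """
    if isinstance(annotations, pd.DataFrame):
        pairs = annotations.iloc[:, :2].itertuples(index=False)
        mapping: dict[str, set[str]] = {}
        for iso, term in pairs:
            mapping.setdefault(str(iso), set()).add(str(term))
        annotations = mapping
    classed = set(isoform_classes)
    N = len(classed)
    if N == 0:
        raise ValidationError("go_hypergeometric: no classed isoforms")
    uhp = {iso for iso, lab in isoform_classes.items() if lab == uhp_label}
    K = len(uhp)
    term_members: dict[str, set[str]] = {}
    for iso, terms in annotations.items():
        if iso not in classed:
            continue
        for term in terms:
            term_members.setdefault(term, set()).add(iso)
    candidates = []
    for term, members in term_members.items():
        k = len(members & uhp)
        if k < min_uhp:
            continue
        candidates.append((term, len(members), k))
    m = len(candidates)
    results = [
        GoEnrichment(
            go_id=term,
            n_term=n_term,
            k_uhp=k,
            coverage=k / n_term,
            p=(p := hypergeom_upper_tail(k, N, K, n_term)),
            adj_p=min(1.0, p * m),
        )
        for term, n_term, k in candidates
    ]
    results.sort(key=lambda r: (r.p, r.go_id))
    return results


def psi_marker_correlation(
    psi_table: pd.DataFrame, marker_expr: pd.Series
) -> pd.Series:
    """Pearson correlation of each event's psi with a marker gene expression.

    ``psi_table`` is events x samples (NaN = undefined psi); samples are
    matched by column/index label.  Events with fewer than 3 defined pairs
    or constant psi/marker are NaN (flagged by absence of a finite value).
    """
    marker = marker_expr.reindex(psi_table.columns)
    out = {}
    m = marker.to_numpy(dtype=float)
    for event_id, row in psi_table.iterrows():
        x = row.to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(m))
        if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(m[mask]) == 0:
            out[event_id] = float("nan")
            continue
        out[event_id] = float(stats.pearsonr(x[mask], m[mask]).statistic)
    return pd.Series(out, name="pearson_r")


def enrichment_results_to_tsv(results: Sequence[EnrichmentResult]) -> str:
    lines = [
        "factor_id\tfocus_class\tbaseline_class\tprop_focus\tprop_baseline\t"
        "delta\tp_emp\tp_bonf\texcluded\texclusion_reason"
    ]
    for r in results:
        lines.append(
            f"{r.factor_id}\t{r.focus_class}\t{r.baseline_class}\t"
            f"{r.prop_focus:.6g}\t{r.prop_baseline:.6g}\t{r.delta:.6g}\t"
            f"{r.p_emp:.6g}\t{r.p_bonf:.6g}\t{int(r.excluded)}\t{r.exclusion_reason}"
        )
    return "\n".join(lines) + "\n"


def go_results_to_tsv(results: Sequence[GoEnrichment]) -> str:
    lines = ["go_id\tn_term\tk_uhp\tcoverage\tp\tadj_p"]
    for r in results:
        lines.append(
            f"{r.go_id}\t{r.n_term}\t{r.k_uhp}\t{r.coverage:.4g}\t"
            f"{r.p:.6g}\t{r.adj_p:.6g}"
        )
    return "\n".join(lines) + "\n"
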