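"""Interval arithmetic over exons/introns and BED features.

Two occupancy read-outs distinguish coupled from type-0 exons: RNAP2
ChIP-seq peak density on exons (per-gene ratio of bindings per base pair,
focus class vs type 0) and nascent-transcription (PRO-seq) read density in
the intron downstream of each exon, normalised within the gene.  Overlap
semantics follow bedtools intersect defaults: two intervals overlap iff they
share at least one base on the same chromosome, strand ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


@dataclass
class IntervalTrack:
    """A named list of (chrom, start, end) intervals, 0-based half-open."""

    name: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValidationError(
                    f"track {self.name}: interval with end <= start "
                    f"({chrom}:{start}-{end})"
                )

    def __len__(self) -> int:
        return len(self.intervals)


def read_bed(source, name: str | None = None) -> IntervalTrack:
    """Read a BED3+ file or text; browser/track/comment lines are skipped."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        text = path.read_text()
        name = name or path.stem
    else:
        text = source if isinstance(source, str) else source.read()
        name = name or "bed"
    intervals = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("browser", "track", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"BED line with <3 fields: {line!r}")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalTrack(name=name, intervals=intervals)


def write_bed(track: IntervalTrack) -> str:
    return "".join(f"{c}\t{s}\t{e}\n" for c, s, e in track.intervals)


def count_overlaps(
    features: IntervalTrack, targets: IntervalTrack | Sequence[Interval]
) -> np.ndarray:
    """Number of features overlapping each target by >= 1 bp.

    Half-open abutment ([100,200) vs [200,300)) does not overlap.  Runs in
    O((n+m) log n) using sorted start/end arrays per chromosome: a feature
    misses target [s,e) iff its start >= e or its end <= s, and those two
    miss-sets are disjoint.
    """
    target_list = targets.intervals if isinstance(targets, IntervalTrack) else list(targets)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for chrom, s, e in features.intervals:
        starts.setdefault(chrom, []).append(s)
        ends.setdefault(chrom, []).append(e)
    for chrom in starts:
        by_chrom[chrom] = (
            np.sort(np.asarray(starts[chrom])),
            np.sort(np.asarray(ends[chrom])),
        )
    counts = np.zeros(len(target_list), dtype=int)
    for i, (chrom, s, e) in enumerate(target_list):
        if chrom not in by_chrom:
            continue
        st, en = by_chrom[chrom]
        n = st.size
        n_right = n - np.searchsorted(st, e, side="left")  # start >= e
        n_left = np.searchsorted(en, s, side="right")      # end <= s
        counts[i] = n - n_right - n_left
    return counts


@dataclass
class GeneOccupancyRatio:
    """Per-gene ratio of peak bindings per bp: focus class vs type 0."""

    gene_id: str
    class_pair: tuple[str, str]
    per_bp_focus: float
    per_bp_type0: float
    ratio: float


def chip_ratio_per_gene(
    peak_tracks: Sequence[IntervalTrack],
    exon_classes: pd.DataFrame,
    focus_class: str = "UHP",
    baseline_class: str = "TYPE0",
) -> list[GeneOccupancyRatio]:
    """Per-gene ratio of peak overlaps per base pair, focus vs type-0 exons.

    ``exon_classes`` must carry columns gene_id, chrom, start, end, label.
    For each gene with at least one exon of both classes, the overlap counts
    are summed over all peak tracks (experiments) and divided by the total
    exon length of the class; genes whose type-0 exons attract no peak are
    excluded and logged.
    """
    required = {"gene_id", "chrom", "start", "end", "label"}
    if not required.issubset(exon_classes.columns):
        raise ValidationError(f"exon_classes needs columns {sorted(required)}")
    df = exon_classes[exon_classes["label"].isin([focus_class, baseline_class])]
    targets = list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))
    total = np.zeros(len(df), dtype=float)
    for track in peak_tracks:
        total += count_overlaps(track, targets)
    work = df.assign(_count=total, _len=(df["end"] - df["start"]).astype(int))
    out = []
    for gene_id, gdf in work.groupby("gene_id", sort=True):
        labels = set(gdf["label"])
        if focus_class not in labels or baseline_class not in labels:
            continue
        focus = gdf[gdf["label"] == focus_class]
        base = gdf[gdf["label"] == baseline_class]
        per_bp_focus = focus["_count"].sum() / focus["_len"].sum()
        per_bp_base = base["_count"].sum() / base["_len"].sum()
        if per_bp_base == 0:
            logger.warning(
                "chip_ratio_per_gene: gene %s excluded (no peak on %s exons)",
                gene_id, baseline_class,
            )
            continue
        out.append(
            GeneOccupancyRatio(
                gene_id=gene_id,
                class_pair=(focus_class, baseline_class),
                per_bp_focus=float(per_bp_focus),
                per_bp_type0=float(per_bp_base),
                ratio=float(per_bp_focus / per_bp_base),
            )
        )
    return out


@dataclass
class IntronDensity:
    """Downstream-intron read density of one event, gene-normalised."""

    event_id: str
    gene_id: str
    label: str
    reads_per_bp: float
    normalized: float = float("nan")


def proseq_intron_density(
    read_track: IntervalTrack, intron_table: pd.DataFrame
) -> list[IntronDensity]:
    """Read density in the intron downstream of each scored event.

    ``intron_table`` columns: event_id, gene_id, label, chrom,
    intron_start, intron_end.  reads_per_bp = (# read intervals overlapping
    the intron) / intron length; ``normalized`` divides by the per-gene sum
    over scored events so values sum to 1 within each gene.
    """
    required = {"event_id", "gene_id", "label", "chrom", "intron_start", "intron_end"}
    if not required.issubset(intron_table.columns):
        raise ValidationError(f"intron_table needs columns {sorted(required)}")
    lengths = (intron_table["intron_end"] - intron_table["intron_start"]).astype(int)
    if (lengths <= 0).any():
        raise ValidationError("proseq_intron_density: zero-length intron")
    targets = list(
        zip(
            intron_table["chrom"],
            intron_table["intron_start"].astype(int),
            intron_table["intron_end"].astype(int),
        )
    )
    counts = count_overlaps(read_track, targets)
    density = counts / lengths.to_numpy()
    work = intron_table.assign(_density=density)
    out = []
    for _, gdf in work.groupby("gene_id", sort=True):
        total = gdf["_density"].sum()
        for _, row in gdf.iterrows():
            norm = row["_density"] / total if total > 0 else float("nan")
            out.append(
                IntronDensity(
                    event_id=row["event_id"],
                    gene_id=row["gene_id"],
                    label=row["label"],
                    reads_per_bp=float(row["_density"]),
                    normalized=float(norm),
                )
            )
    return out


def _exact_rank_sum_with_ties(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration on midranks.

    Valid with ties; feasible only for tiny samples (the caller bounds the
    number of combinations).
    """
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(len(combined)), n1):
        r = ranks[list(idx)].sum()
        u = r - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Small samples (both n <= 20) without ties use the exact null
    distribution; tiny samples with ties fall back to full enumeration on
    midranks (so identical multisets give p = 1); otherwise the normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test: empty input")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = x.size <= 20 and y.size <= 20
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if has_ties and math.comb(x.size + y.size, x.size) <= 20000:
        return _exact_rank_sum_with_ties(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def ratio_vs_one_test(ratios: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon signed-rank test of log(ratio) against 0, two-sided.

    Symmetric in ratio space around 1 (log transform); exact null
    distribution for n <= 25 after removing exact ones, normal approximation
    beyond.  Non-positive ratios raise ValidationError; all-unity input
    returns (0, 1).
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValidationError("ratio_vs_one_test: empty input")
    if (r <= 0).any():
        raise ValidationError("ratio_vs_one_test: ratios must be positive")
    d = np.log(r)
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def occupancy_ratios_to_tsv(ratios: Sequence[GeneOccupancyRatio]) -> str:
    lines = ["gene_id\tfocus_class\tbaseline_class\tper_bp_focus\tper_bp_type0\tratio"]
    for r in ratios:
        lines.append(
            f"{r.gene_id}\t{r.class_pair[0]}\t{r.class_pair[1]}\t"
            f"{r.per_bp_focus:.6g}\t{r.per_bp_type0:.6g}\t{r.ratio:.6g}"
        )
    return "\n".join(lines) + "\n"


def intron_density_to_tsv(densities: Sequence[IntronDensity]) -> str:
    lines = ["event_id\tgene_id\tlabel\treads_per_bp\tnormalized"]
    for d in densities:
        lines.append(
            f"{d.event_id}\t{d.gene_id}\t{d.label}\t"
            f"{d.reads_per_bp:.6g}\t{d.normalized:.6g}"
        )
    return "\n".join(lines) + "\n"
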