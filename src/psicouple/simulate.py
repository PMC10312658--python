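"""Seeded synthetic data with planted expression-splicing coupling.

Every generator is a pure function of the configuration (including its
seed), so identical configurations yield byte-identical outputs.  The
generative model mirrors the analysis model:

* each gene carries one internal cassette exon: "full" transcripts include
  it, "skip" transcripts lack it;
* per sample, psi ~ Uniform(0.1, 0.9) and the gene total is
      Y = mu_g * (1 + b * psi)       for a planted UHP event,
      Y = mu_g * (1 + b * (1-psi))   for DHP,
      Y = mu_g                       for type 0,
  each times multiplicative noise (1 + eps), eps ~ Normal(0, noise_sd)
  truncated at -0.9 so values stay non-negative; the planted slope is
  therefore +/- mu_g * b;
* inclusion transcripts share Y*psi equally and exclusion transcripts share
  Y*(1-psi), so psi is exactly recoverable from the emitted matrix;
* occupancy tracks draw Poisson peak/read counts with class-specific per-bp
  rates; motif hits are Bernoulli with class-specific probabilities; GO
  terms sample members with planted UHP over-representation.

Defaults describe a GTEx-like study at package scale: hundreds of genes,
hundreds of samples, lognormal baseline expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import parse_gtf
from .classify import DHP, TYPE0, UHP, DHP_GENE, TYPE0_GENE, UHP_GENE
from .enrich import HitMatrix
from .errors import ValidationError
from .expression import ExpressionMatrix
from .occupancy import IntervalTrack

_BIOTYPES = ("protein_coding", "retained_intron", "nonsense_mediated_decay", "lncRNA")
_BIOTYPE_P = (0.60, 0.18, 0.08, 0.14)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    effect_b is the planted slope multiplier b (planted slope = mu_g * b);
    noise_sd is the multiplicative noise SD as a fraction of the gene mean;
    base_expr_log_mean/log_sd parameterise the lognormal baseline mu_g.
    """

    n_genes: int = 200
    transcripts_per_gene: tuple[int, int] = (2, 4)
    exons_per_transcript: tuple[int, int] = (4, 8)
    n_samples: int = 400
    n_groups: int = 1
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {UHP: 0.35, DHP: 0.35, TYPE0: 0.30}
    )
    effect_b: float = 1.0
    noise_sd: float = 0.1
    base_expr_log_mean: float = math.log(500.0)
    base_expr_log_sd: float = 0.8
    seed: int = 1
    # occupancy generator
    n_chip_experiments: int = 5
    peak_rate_per_bp: dict[str, float] = field(
        default_factory=lambda: {UHP: 0.0172, DHP: 0.0062, TYPE0: 0.02}
    )
    read_rate_per_bp: dict[str, float] = field(
        default_factory=lambda: {UHP: 0.05, DHP: 0.05, TYPE0: 0.02}
    )
    # motif-hit / GO generator
    n_factors: int = 8
    hit_prob_baseline: float = 0.20
    planted_hit_delta: float = 15.0  # percentage points, on half the factors
    n_go_terms: int = 20
    go_term_size: tuple[int, int] = (8, 30)
    n_planted_go_terms: int = 2
    planted_go_uhp_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1 or self.n_groups < 1:
            raise ValidationError("counts must be positive")
        if self.exons_per_transcript[0] < 3:
            raise ValidationError(
                "exons_per_transcript must allow >= 3 exons "
                "(an internal cassette exon needs flanking exons)"
            )
        if self.transcripts_per_gene[0] < 2:
            raise ValidationError("need >= 2 transcripts per gene")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            doc = yaml.safe_load(handle) or {}
        for key in ("transcripts_per_gene", "exons_per_transcript", "go_term_size"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_annotation(cfg: SimulationConfig) -> tuple[str, pd.DataFrame]:
    """Generate GTF text plus the planted-event truth skeleton.

    Each gene has one "full" transcript, at least one transcript skipping
    one internal exon (the cassette), and optionally further copies of
    either structure; genes are laid out without overlap on one chromosome.
    """
    rng = _rng(cfg, 0)
    classes = sorted(cfg.class_proportions)
    probs = [cfg.class_proportions[c] for c in classes]
    gtf_lines: list[str] = []
    truth_rows = []
    cursor = 10_000
    chrom = "chr1"
    for g in range(cfg.n_genes):
        gene_id = f"G{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(cfg.exons_per_transcript[0],
                                   cfg.exons_per_transcript[1] + 1))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(200, 1501, size=n_exons - 1)
        starts = np.empty(n_exons, dtype=int)
        pos = cursor
        for i in range(n_exons):
            starts[i] = pos
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        exons = [(int(s), int(s + L)) for s, L in zip(starts, exon_lens)]
        cassette_idx = int(rng.integers(1, n_exons - 1))
        cas_start, cas_end = exons[cassette_idx]
        planted_class = str(rng.choice(classes, p=probs))

        n_tx = int(rng.integers(cfg.transcripts_per_gene[0],
                                cfg.transcripts_per_gene[1] + 1))
        # transcript 1 includes, transcript 2 skips; the rest flip a coin
        is_inclusion = [True, False] + [bool(rng.random() < 0.5)
                                        for _ in range(n_tx - 2)]
        inclusion_ids, exclusion_ids = [], []
        for t, inc in enumerate(is_inclusion):
            tx_id = f"{gene_id}T{t + 1:02d}"
            biotype = str(rng.choice(_BIOTYPES, p=_BIOTYPE_P))
            tx_exons = exons if inc else exons[:cassette_idx] + exons[cassette_idx + 1:]
            (inclusion_ids if inc else exclusion_ids).append(tx_id)
            attrs = (
                f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                f'transcript_biotype "{biotype}";'
            )
            gtf_lines.append(
                f"{chrom}\tpsicouple_sim\ttranscript\t{tx_exons[0][0] + 1}\t"
                f"{tx_exons[-1][1]}\t.\t{strand}\t.\t{attrs}"
            )
            for s, e in tx_exons:
                gtf_lines.append(
                    f"{chrom}\tpsicouple_sim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
                )
        # downstream intron of the cassette exon, strand-aware
        if strand == "+":
            intron = (cas_end, exons[cassette_idx + 1][0])
        else:
            intron = (exons[cassette_idx - 1][1], cas_start)
        truth_rows.append({
            "event_id": f"{gene_id}:{chrom}:{cas_start}-{cas_end}({strand})",
            "gene_id": gene_id,
            "chrom": chrom,
            "strand": strand,
            "exon_start": cas_start,
            "exon_end": cas_end,
            "intron_start": intron[0],
            "intron_end": intron[1],
            "class": planted_class,
            "inclusion_ids": ",".join(inclusion_ids),
            "exclusion_ids": ",".join(exclusion_ids),
        })
        cursor = pos + 10_000
    gtf_text = "\n".join(gtf_lines) + "\n"
    return gtf_text, pd.DataFrame(truth_rows)


def simulate_expression(
    cfg: SimulationConfig, truth: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the transcripts x samples matrix from the truth skeleton.

    Returns the matrix (with sample_groups attached) and the truth extended
    by mu_g, the planted slope beta1 = +/- mu_g * b, and per-sample psi
    recoverability by construction.
    """
    rng = _rng(cfg, 1)
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    per_group = cfg.n_samples // cfg.n_groups
    groups = {
        s: f"group{min(i // max(per_group, 1), cfg.n_groups - 1) + 1}"
        for i, s in enumerate(sample_ids)
    }
    rows: dict[str, np.ndarray] = {}
    mu_list, beta_list = [], []
    for _, ev in truth.iterrows():
        mu = float(rng.lognormal(cfg.base_expr_log_mean, cfg.base_expr_log_sd))
        psi = rng.uniform(0.1, 0.9, size=cfg.n_samples)
        eps = np.clip(rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples), -0.9, None)
        b = cfg.effect_b
        if ev["class"] == UHP:
            y = mu * (1.0 + b * psi) * (1.0 + eps)
            beta = mu * b
        elif ev["class"] == DHP:
            y = mu * (1.0 + b * (1.0 - psi)) * (1.0 + eps)
            beta = -mu * b
        else:
            y = mu * (1.0 + eps)
            beta = 0.0
        inc = ev["inclusion_ids"].split(",")
        exc = ev["exclusion_ids"].split(",")
        for tx in inc:
            rows[tx] = y * psi / len(inc)
        for tx in exc:
            rows[tx] = y * (1.0 - psi) / len(exc)
        mu_list.append(mu)
        beta_list.append(beta)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    matrix = ExpressionMatrix(values, sample_groups=groups)
    truth_out = truth.assign(mu_g=mu_list, beta1=beta_list)
    return matrix, truth_out


def simulate_exon_class_table(
    cfg: SimulationConfig,
    n_genes: int | None = None,
    focus_classes: Sequence[str] = (UHP, DHP),
) -> pd.DataFrame:
    """Layout for the occupancy generators: genes holding exons of several
    classes (each gene gets one focus-class exon and 1-3 type-0 exons, each
    with a downstream intron), as the peak/read-density analyses require
    both classes within a gene."""
    rng = _rng(cfg, 2)
    n = n_genes if n_genes is not None else cfg.n_genes
    rows = []
    cursor = 10_000
    chrom = "chrS"
    for g in range(n):
        gene_id = f"OG{g + 1:04d}"
        focus = str(rng.choice(list(focus_classes)))
        n_type0 = int(rng.integers(1, 4))
        labels = [focus] + [TYPE0] * n_type0
        for i, label in enumerate(labels):
            exon_len = int(rng.integers(100, 251))
            intron_len = int(rng.integers(300, 1501))
            start = cursor
            end = start + exon_len
            rows.append({
                "event_id": f"{gene_id}E{i + 1}",
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "intron_start": end,
                "intron_end": end + intron_len,
                "label": label,
            })
            cursor = end + intron_len + 500
        cursor += 5_000
    return pd.DataFrame(rows)


def simulate_occupancy(
    cfg: SimulationConfig, exon_table: pd.DataFrame
) -> tuple[list[IntervalTrack], IntervalTrack]:
    """Poisson peak tracks (one per ChIP experiment) and one read track.

    Peak counts per exon follow Poisson(rate[label] * exon length) per
    experiment; read counts per downstream intron follow
    Poisson(read_rate[label] * intron length).  Features are placed uniformly
    inside their parent interval, so each overlaps exactly that interval.
    """
    rng = _rng(cfg, 3)
    tracks = []
    for e in range(cfg.n_chip_experiments):
        intervals = []
        for _, row in exon_table.iterrows():
            length = int(row["end"] - row["start"])
            rate = cfg.peak_rate_per_bp[row["label"]]
            count = int(rng.poisson(rate * length))
            width = min(50, length)
            for _ in range(count):
                s = int(rng.integers(row["start"], row["end"] - width + 1))
                intervals.append((row["chrom"], s, s + width))
        intervals.sort()
        tracks.append(IntervalTrack(name=f"chip_{e + 1}", intervals=intervals))
    reads = []
    for _, row in exon_table.iterrows():
        ilen = int(row["intron_end"] - row["intron_start"])
        rate = cfg.read_rate_per_bp[row["label"]]
        count = int(rng.poisson(rate * ilen))
        width = min(50, ilen)
        for _ in range(count):
            s = int(rng.integers(row["intron_start"], row["intron_end"] - width + 1))
            reads.append((row["chrom"], s, s + width))
    reads.sort()
    return tracks, IntervalTrack(name="proseq", intervals=reads)


def simulate_hits_and_go(
    cfg: SimulationConfig,
    gene_labels: Mapping[str, str],
    isoform_classes: Mapping[str, str],
) -> tuple[HitMatrix, pd.DataFrame, dict]:
    """Bernoulli motif hits and GO annotations with planted effects.

    Half of the factors are null (one hit probability for every class); the
    other half add ``planted_hit_delta`` percentage points to the hit
    probability of UHP and DHP genes.  ``n_planted_go_terms`` GO terms draw
    ``planted_go_uhp_frac`` of their members from UHP isoforms; the rest
    sample isoforms uniformly.  Returns (hit matrix, annotation table,
    truth dict naming planted factors/terms).
    """
    rng = _rng(cfg, 4)
    units = [u for u, lab in sorted(gene_labels.items())
             if lab in (UHP_GENE, DHP_GENE, TYPE0_GENE)]
    if not units:
        raise ValidationError("simulate_hits_and_go: no labelled units")
    labels = pd.Series({u: gene_labels[u] for u in units})
    n_planted = cfg.n_factors // 2
    hit_cols = {}
    planted_factors = []
    for f in range(cfg.n_factors):
        factor = f"F{f + 1:02d}"
        p = np.full(len(units), cfg.hit_prob_baseline)
        if f < n_planted:
            planted_factors.append(factor)
            boost = cfg.planted_hit_delta / 100.0
            mask = labels.isin([UHP_GENE, DHP_GENE]).to_numpy()
            p = np.where(mask, np.minimum(cfg.hit_prob_baseline + boost, 1.0), p)
        hit_cols[factor] = (rng.random(len(units)) < p).astype(int)
    hits = pd.DataFrame(hit_cols, index=pd.Index(units, name="unit_id"))
    matrix = HitMatrix(hits=hits, labels=labels)

    isoforms = sorted(isoform_classes)
    uhp_isoforms = [i for i in isoforms if isoform_classes[i] == UHP]
    other_isoforms = [i for i in isoforms if isoform_classes[i] != UHP]
    ann_rows = []
    planted_terms = []
    for t in range(cfg.n_go_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(cfg.go_term_size[0], cfg.go_term_size[1] + 1))
        size = min(size, len(isoforms))
        if t < cfg.n_planted_go_terms and uhp_isoforms:
            planted_terms.append(term)
            n_uhp = min(int(round(size * cfg.planted_go_uhp_frac)), len(uhp_isoforms))
            n_other = min(size - n_uhp, len(other_isoforms))
            members = list(rng.choice(uhp_isoforms, size=n_uhp, replace=False))
            if n_other > 0:
                members += list(rng.choice(other_isoforms, size=n_other, replace=False))
        else:
            members = list(rng.choice(isoforms, size=size, replace=False))
        for iso in members:
            ann_rows.append({"isoform_id": iso, "go_id": term})
    annotations = pd.DataFrame(ann_rows)
    truth = {"planted_factors": planted_factors, "planted_go_terms": planted_terms}
    return matrix, annotations, truth


def isoform_classes_from_truth(truth: pd.DataFrame) -> dict[str, str]:
    """Class of each inclusion isoform: the planted class of its event."""
    out: dict[str, str] = {}
    for _, ev in truth.iterrows():
        for tx in ev["inclusion_ids"].split(","):
            out[tx] = ev["class"]
    return out


def gene_labels_from_truth(truth: pd.DataFrame) -> dict[str, str]:
    """Gene-level labels implied by the planted event classes."""
    mapping = {UHP: UHP_GENE, DHP: DHP_GENE, TYPE0: TYPE0_GENE}
    return {ev["gene_id"]: mapping[ev["class"]] for _, ev in truth.iterrows()}


@dataclass
class SyntheticStudy:
    """A complete in-memory synthetic dataset with its planted truth."""

    config: SimulationConfig
    gtf_text: str
    genes: dict
    truth: pd.DataFrame
    matrix: ExpressionMatrix

    def model(self, thresholds=None):
        from .model import CouplingModel

        return CouplingModel(self.genes, self.matrix, thresholds=thresholds)


def simulate_study(cfg: SimulationConfig | None = None) -> SyntheticStudy:
    """Annotation + expression in one call, re-parsed through the readers."""
    cfg = cfg or SimulationConfig()
    gtf_text, skeleton = simulate_annotation(cfg)
    matrix, truth = simulate_expression(cfg, skeleton)
    genes = parse_gtf(gtf_text)
    return SyntheticStudy(
        config=cfg, gtf_text=gtf_text, genes=genes, truth=truth, matrix=matrix
    )
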