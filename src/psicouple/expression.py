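"""Transcript-level expression matrices and per-event psi quantification.

The percent-spliced-in of a cassette event in one sample is

    psi = ITinc / (ITinc + ITexcl)

where ITinc and ITexcl are the sums of expression (TPM-like units) over the
event's inclusion and exclusion transcript sets.  Total gene expression Y(g)
is the sum over all transcripts assigned to the gene; because the inclusion
and exclusion sets partition the gene's transcripts, Y = ITinc + ITexcl.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import CassetteEvent
from .errors import FormatError, MissingGeneError, ValidationError

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class ExpressionMatrix:
    """A transcripts x samples matrix of non-negative expression values.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by transcript id, columns by sample id.
    sample_groups : mapping, optional
        sample_id -> group label (tissue or donor).  Samples without an
        entry belong to no group.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_groups: Mapping[str, str] | None = None,
    ) -> None:
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate transcript ids: {dupes[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative values")
        self.values = values
        self.sample_groups = dict(sample_groups) if sample_groups else None

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> list[str]:
        if not self.sample_groups:
            return []
        return sorted(set(self.sample_groups.values()))

    def subset_group(self, group: str) -> "ExpressionMatrix":
        if not self.sample_groups:
            raise ValidationError("matrix has no sample_groups")
        cols = [s for s in self.sample_ids if self.sample_groups.get(s) == group]
        if not cols:
            raise ValidationError(f"group {group!r} has no samples")
        return ExpressionMatrix(
            self.values[cols], {c: group for c in cols}
        )


@dataclass
class EventQuant:
    """Per-sample psi, exon expression and gene expression for one event.

    psi is NaN where the denominator ITinc + ITexcl is zero (the event is
    unobserved in that sample); those samples are dropped pairwise downstream.
    """

    event_id: str
    gene_id: str
    sample_ids: list[str]
    psi: np.ndarray
    exon_expr: np.ndarray
    gene_expr: np.ndarray

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.psi)


def _gct_handle(source):
    """Text handle from a path (gz-transparent) or file-like object."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        raw = open(path, "rb")
        head = raw.read(2)
        raw.seek(0)
        if head == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.GzipFile(fileobj=raw)), True
        return io.TextIOWrapper(raw), True
    if isinstance(source, io.TextIOBase):
        return source, False
    # binary stream: sniff for gzip
    head = source.read(2)
    if hasattr(source, "seek"):
        source.seek(0)
        if head == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.GzipFile(fileobj=source)), False
        return io.TextIOWrapper(source), False
    raise ValidationError("unsupported GCT source")


def read_gct(
    source,
    sample_groups: Mapping[str, str] | None = None,
    strip_versions: bool = True,
) -> ExpressionMatrix:
    """Read a GCT v1.2 expression matrix (gz-transparent).

    The Name column supplies transcript ids; a trailing version suffix such
    as ``.5`` is stripped so ids match annotation transcript ids.  The
    Description column is discarded.

    Raises FormatError when the dimensions line disagrees with the body or a
    transcript id occurs twice.
    """
    handle, close = _gct_handle(source)
    try:
        version = handle.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"not a GCT v1.2 file (first line {version!r})")
        dims = handle.readline().split()
        if len(dims) < 2:
            raise FormatError("malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(handle, sep="\t", header=0)
    finally:
        if close:
            handle.close()
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise FormatError(
            f"GCT dimensions line says {n_rows}x{n_cols}, body is "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    names = df.iloc[:, 0].astype(str)
    if strip_versions:
        names = names.str.replace(_VERSION_SUFFIX, "", regex=True)
    values = df.iloc[:, 2:].astype(float)
    values.index = pd.Index(names, name="transcript_id")
    return ExpressionMatrix(values, sample_groups=sample_groups)


def write_gct(matrix: ExpressionMatrix, descriptions: Iterable[str] | None = None) -> str:
    """Render an ExpressionMatrix as GCT v1.2 text."""
    df = matrix.values
    desc = list(descriptions) if descriptions is not None else ["na"] * len(df)
    lines = ["#1.2", f"{df.shape[0]}\t{df.shape[1]}"]
    lines.append("\t".join(["Name", "Description", *df.columns.astype(str)]))
    body = df.copy()
    body.insert(0, "Description", desc)
    for tx_id, row in body.iterrows():
        lines.append("\t".join([str(tx_id), *map(_fmt, row.tolist())]))
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def gene_expression(
    matrix: ExpressionMatrix, transcripts_of_gene: Iterable[str]
) -> pd.Series:
    """Total gene expression Y(g): per-sample sum over the gene's transcripts.

    Transcripts absent from the matrix contribute 0 (logged); if none is
    present a MissingGeneError is raised.
    """
    wanted = list(transcripts_of_gene)
    present = [t for t in wanted if t in matrix.values.index]
    missing = sorted(set(wanted) - set(present))
    if not present:
        raise MissingGeneError(f"no transcript of {wanted[:5]}... in matrix")
    if missing:
        logger.warning(
            "gene_expression: %d transcript(s) absent from matrix: %s",
            len(missing), missing[:5],
        )
    return matrix.values.loc[present].sum(axis=0)


def event_psi(matrix: ExpressionMatrix, event: CassetteEvent) -> EventQuant:
    """Per-sample psi, exon expression and gene expression for one event.

    ITinc / ITexcl are per-sample sums over the inclusion / exclusion
    transcript sets; psi = ITinc / (ITinc + ITexcl), NaN where the
    denominator is zero.  exon_expr = ITinc and gene_expr = ITinc + ITexcl
    (the two sets partition the gene's transcripts by construction).
    """
    index = matrix.values.index
    inc = [t for t in sorted(event.inclusion_set) if t in index]
    exc = [t for t in sorted(event.exclusion_set) if t in index]
    n_missing = len(event.inclusion_set) + len(event.exclusion_set) - len(inc) - len(exc)
    if not inc and not exc:
        raise MissingGeneError(
            f"event {event.event_id}: no transcript of gene {event.gene_id} "
            "present in matrix"
        )
    if n_missing:
        logger.warning(
            "event %s: %d transcript(s) absent from matrix", event.event_id, n_missing
        )
    it_inc = matrix.values.loc[inc].sum(axis=0).to_numpy(dtype=float) if inc else np.zeros(len(matrix.sample_ids))
    it_exc = matrix.values.loc[exc].sum(axis=0).to_numpy(dtype=float) if exc else np.zeros(len(matrix.sample_ids))
    denom = it_inc + it_exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, it_inc / denom, np.nan)
    return EventQuant(
        event_id=event.event_id,
        gene_id=event.gene_id,
        sample_ids=matrix.sample_ids,
        psi=psi,
        exon_expr=it_inc,
        gene_expr=denom,
    )


def quant_to_tsv(quant: EventQuant) -> str:
    """TSV export of an EventQuant (one row per sample)."""
    lines = ["event_id\tsample_id\tpsi\texon_expr\tgene_expr"]
    for i, sample in enumerate(quant.sample_ids):
        psi = "" if np.isnan(quant.psi[i]) else format(quant.psi[i], ".6g")
        lines.append(
            f"{quant.event_id}\t{sample}\t{psi}\t"
            f"{format(quant.exon_expr[i], '.6g')}\t{format(quant.gene_expr[i], '.6g')}"
        )
    return "\n".join(lines) + "\n"
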