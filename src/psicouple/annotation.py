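"""Gene models and cassette-exon event discovery.

A cassette exon is an exon that is present (by exact genomic coordinates) in
some transcripts of a gene and absent from the rest.  Events whose
inclusion/exclusion transcript sets coincide are collapsed into a single event
group, so each distinct splicing pattern is tested once downstream.

Coordinates are stored 0-based half-open throughout the package; GTF I/O
converts from and to the format's 1-based inclusive convention at the
boundary.
"""

from __future__ import annotations

import gzip
import io
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, GtfParseError, ValidationError

# (chrom, start, end, strand) with 0-based half-open coordinates
ExonKey = tuple[str, int, int, str]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class TranscriptModel:
    """One transcript: an ordered set of exon intervals on a strand.

    ``exons`` are 0-based half-open, non-overlapping and sorted by genomic
    coordinate (validated on construction).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon with end <= start "
                    f"({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end

    def exon_keys(self) -> list[ExonKey]:
        return [(self.chrom, s, e, self.strand) for s, e in self.exons]


@dataclass
class CassetteEvent:
    """A cassette exon (or collapsed group of perfectly co-occurring exons).

    ``inclusion_set`` holds the transcripts containing every exon of the
    group; ``exclusion_set`` the remaining transcripts of the gene.  These two
    sets are the per-sample summation sets behind ITinc and ITexcl in the psi
    computation.
    """

    event_id: str
    gene_id: str
    exon_keys: frozenset[ExonKey]
    representative_exon: ExonKey
    inclusion_set: frozenset[str]
    exclusion_set: frozenset[str]

    @property
    def chrom(self) -> str:
        return self.representative_exon[0]

    @property
    def start(self) -> int:
        return self.representative_exon[1]

    @property
    def end(self) -> int:
        return self.representative_exon[2]

    @property
    def strand(self) -> str:
        return self.representative_exon[3]


@dataclass
class FlankingIntrons:
    """Median flanking-intron lengths of an event, in bp, strand-aware.

    ``None`` marks an absent intron: the exon is first (upstream) or last
    (downstream) in every inclusion transcript.
    """

    event_id: str
    upstream_length: float | None
    downstream_length: float | None


def _open_text(source):
    """Return (text-file-like, should_close) for a path/str/stream input."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, "rt"), True
        return open(path, "rt"), True
    if isinstance(source, bytes):
        return io.StringIO(source.decode()), True
    return source, False


def parse_gtf(source: Iterable[str] | str) -> dict[str, list[TranscriptModel]]:
    """Parse GTF text into TranscriptModels grouped by gene.

    Only ``exon`` feature rows contribute intervals; gene/transcript/CDS/UTR
    rows are ignored.  ``source`` may be an iterable of lines or a string of
    GTF text.  Attribute values are read from the ``key "value"`` syntax,
    tolerant of trailing semicolons; the transcript biotype is taken from
    ``transcript_biotype`` or ``transcript_type`` when present.

    Raises
    ------
    GtfParseError
        for a malformed line (names the 1-based line number).
    ValidationError
        for an exon with end < start.
    """
    if isinstance(source, str):
        lines: Iterable[str] = io.StringIO(source)
    else:
        lines = source

    # transcript_id -> accumulating fields
    acc: dict[str, dict] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-delimited columns, "
                f"got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
            fields[:9]
        )
        if feature != "exon":
            continue
        try:
            start1 = int(start_s)
            end1 = int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if end1 < start1:
            raise ValidationError(f"line {lineno}: exon end < start")
        attributes = dict(_ATTR_RE.findall(attrs))
        try:
            gene_id = attributes["gene_id"]
            transcript_id = attributes["transcript_id"]
        except KeyError as exc:
            raise GtfParseError(
                f"line {lineno}: exon row lacks gene_id/transcript_id"
            ) from exc
        biotype = attributes.get(
            "transcript_biotype", attributes.get("transcript_type", "unknown")
        )
        rec = acc.setdefault(
            transcript_id,
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "biotype": biotype,
                "exons": [],
            },
        )
        # 1-based inclusive -> 0-based half-open
        rec["exons"].append((start1 - 1, end1))
        if rec["biotype"] == "unknown" and biotype != "unknown":
            rec["biotype"] = biotype

    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, rec in acc.items():
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"],
        )
        genes.setdefault(model.gene_id, []).append(model)
    for models in genes.values():
        models.sort(key=lambda t: t.transcript_id)
    return genes


def read_gtf(path) -> dict[str, list[TranscriptModel]]:
    """Read a GTF file (gz-transparent) into TranscriptModels by gene."""
    handle, close = _open_text(path)
    try:
        return parse_gtf(handle)
    finally:
        if close:
            handle.close()


def write_gtf(genes: Mapping[str, Sequence[TranscriptModel]]) -> str:
    """Render TranscriptModels as GTF text (transcript + exon rows)."""
    out = []
    for gene_id in genes:
        for tx in genes[gene_id]:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            tx_start = tx.exons[0][0] + 1
            tx_end = tx.exons[-1][1]
            out.append(
                f"{tx.chrom}\tpsicouple\ttranscript\t{tx_start}\t{tx_end}\t."
                f"\t{tx.strand}\t.\t{attrs}"
            )
            for start, end in tx.exons:
                out.append(
                    f"{tx.chrom}\tpsicouple\texon\t{start + 1}\t{end}\t."
                    f"\t{tx.strand}\t.\t{attrs}"
                )
    return "\n".join(out) + ("\n" if out else "")


def _event_id(gene_id: str, key: ExonKey) -> str:
    chrom, start, end, strand = key
    return f"{gene_id}:{chrom}:{start}-{end}({strand})"


def find_cassette_events(
    transcripts: Sequence[TranscriptModel],
) -> list[CassetteEvent]:
    """Find pre-collapse cassette events in one gene.

    An event is emitted for every unique exon key (exact-coordinate match)
    present in at least one and absent from at least one transcript of the
    gene.  A transcript with a longer overlapping exon counts as excluding.
    Genes with fewer than two transcripts yield no events.
    """
    if not transcripts:
        return []
    gene_id = transcripts[0].gene_id
    all_ids = frozenset(t.transcript_id for t in transcripts)
    membership: dict[ExonKey, set[str]] = {}
    for tx in transcripts:
        if tx.gene_id != gene_id:
            raise ValidationError("find_cassette_events: mixed gene_ids")
        for key in tx.exon_keys():
            membership.setdefault(key, set()).add(tx.transcript_id)
    events = []
    for key in sorted(membership):
        inc = frozenset(membership[key])
        if inc == all_ids:
            continue
        events.append(
            CassetteEvent(
                event_id=_event_id(gene_id, key),
                gene_id=gene_id,
                exon_keys=frozenset([key]),
                representative_exon=key,
                inclusion_set=inc,
                exclusion_set=all_ids - inc,
            )
        )
    return events


def collapse_equivalent_events(
    events: Sequence[CassetteEvent],
) -> list[CassetteEvent]:
    """Merge events with identical (inclusion_set, exclusion_set) pairs.

    Exons that are perfectly correlated with respect to transcript structure
    carry the same information, so the merged event owns the union of their
    exon keys; the representative exon is the key with the smallest start
    (ties broken by smallest end).  Idempotent.
    """
    groups: dict[tuple[frozenset, frozenset], list[CassetteEvent]] = {}
    order: list[tuple[frozenset, frozenset]] = []
    for ev in events:
        sig = (ev.inclusion_set, ev.exclusion_set)
        if sig not in groups:
            groups[sig] = []
            order.append(sig)
        groups[sig].append(ev)
    collapsed = []
    for sig in order:
        members = groups[sig]
        keys = frozenset().union(*(ev.exon_keys for ev in members))
        rep = min(keys, key=lambda k: (k[1], k[2]))
        collapsed.append(
            CassetteEvent(
                event_id=_event_id(members[0].gene_id, rep),
                gene_id=members[0].gene_id,
                exon_keys=keys,
                representative_exon=rep,
                inclusion_set=sig[0],
                exclusion_set=sig[1],
            )
        )
    return collapsed


def flanking_intron_lengths(
    event: CassetteEvent, transcripts: Sequence[TranscriptModel]
) -> FlankingIntrons:
    """Median flanking-intron lengths of an event across inclusion transcripts.

    The upstream intron is the last intron transcribed 5' of the
    representative exon and the downstream intron the first one transcribed
    3' of it; on the minus strand "upstream" is the higher-coordinate side.
    The per-transcript gap lengths are aggregated with the median; a side is
    absent (None) when the exon is terminal in every inclusion transcript.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    chrom, start, end, strand = event.representative_exon
    up_gaps: list[int] = []
    down_gaps: list[int] = []
    for tx_id in sorted(event.inclusion_set):
        tx = by_id.get(tx_id)
        if tx is None:
            raise ConsistencyError(f"inclusion transcript {tx_id} not supplied")
        try:
            idx = tx.exons.index((start, end))
        except ValueError as exc:
            raise ConsistencyError(
                f"representative exon {event.representative_exon} not found in "
                f"inclusion transcript {tx_id}"
            ) from exc
        left = tx.exons[idx - 1] if idx > 0 else None
        right = tx.exons[idx + 1] if idx + 1 < len(tx.exons) else None
        left_gap = start - left[1] if left is not None else None
        right_gap = right[0] - end if right is not None else None
        if strand == "-":
            left_gap, right_gap = right_gap, left_gap
        if left_gap is not None:
            up_gaps.append(left_gap)
        if right_gap is not None:
            down_gaps.append(right_gap)
    return FlankingIntrons(
        event_id=event.event_id,
        upstream_length=statistics.median(up_gaps) if up_gaps else None,
        downstream_length=statistics.median(down_gaps) if down_gaps else None,
    )


def downstream_intron_interval(
    event: CassetteEvent, transcripts: Sequence[TranscriptModel]
) -> tuple[str, int, int] | None:
    """Genomic interval of the downstream intron (transcription 3' side).

    Uses the first inclusion transcript (sorted by id) in which the
    representative exon is not terminal; None when no such transcript exists.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    chrom, start, end, strand = event.representative_exon
    for tx_id in sorted(event.inclusion_set):
        tx = by_id.get(tx_id)
        if tx is None:
            continue
        try:
            idx = tx.exons.index((start, end))
        except ValueError:
            continue
        if strand == "-":
            if idx > 0:
                return (chrom, tx.exons[idx - 1][1], start)
        else:
            if idx + 1 < len(tx.exons):
                return (chrom, end, tx.exons[idx + 1][0])
    return None


def events_to_tsv(events: Sequence[CassetteEvent]) -> str:
    """Serialize events as TSV (one row per event)."""
    header = (
        "event_id\tgene_id\tchrom\tstrand\trepresentative_start\t"
        "representative_end\tn_exon_keys\tinclusion_ids\texclusion_ids"
    )
    rows = [header]
    for ev in events:
        rows.append(
            "\t".join(
                [
                    ev.event_id,
                    ev.gene_id,
                    ev.chrom,
                    ev.strand,
                    str(ev.start),
                    str(ev.end),
                    str(len(ev.exon_keys)),
                    ",".join(sorted(ev.inclusion_set)),
                    ",".join(sorted(ev.exclusion_set)),
                ]
            )
        )
    return "\n".join(rows) + "\n"


def discover_events(
    genes: Mapping[str, Sequence[TranscriptModel]],
) -> list[CassetteEvent]:
    """Find and collapse cassette events for every gene of an annotation."""
    events: list[CassetteEvent] = []
    for gene_id in sorted(genes):
        events.extend(
            collapse_equivalent_events(find_cassette_events(list(genes[gene_id])))
        )
    return events
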