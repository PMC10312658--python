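"""Shared fixtures: toy annotations, matrices, and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from psicouple.annotation import TranscriptModel
from psicouple.expression import ExpressionMatrix

TOY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GENE1"; transcript_id "T2";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "GENE1"; transcript_id "T2";
"""


@pytest.fixture
def toy_gtf_text():
    return TOY_GTF


@pytest.fixture
def toy_gene():
    """Three-exon transcript plus a skip form: one cassette exon [300,400)."""
    t1 = TranscriptModel("T1", "GENE1", "chr1", "+",
                         [(100, 200), (300, 400), (500, 600)])
    t2 = TranscriptModel("T2", "GENE1", "chr1", "+",
                         [(100, 200), (500, 600)])
    return [t1, t2]


@pytest.fixture
def abcde_gene():
    """Exon structures A-B-C-D-E and A-C-E: B and D are perfectly correlated."""
    exons = {
        "A": (100, 200), "B": (300, 400), "C": (500, 600),
        "D": (700, 800), "E": (900, 1000),
    }
    t1 = TranscriptModel("t1", "G", "chr1", "+", list(exons.values()))
    t2 = TranscriptModel("t2", "G", "chr1", "+",
                         [exons["A"], exons["C"], exons["E"]])
    return [t1, t2], exons


@pytest.fixture
def small_matrix():
    values = pd.DataFrame(
        {"s1": [1.0, 1.0, 2.0], "s2": [2.0, 0.0, 2.0]},
        index=pd.Index(["T1", "T2", "T3"], name="transcript_id"),
    )
    return ExpressionMatrix(values)


def brute_force_events(transcripts):
    """Independent oracle: classify every (exon key, transcript) membership."""
    ids = {t.transcript_id for t in transcripts}
    keys = set()
    for t in transcripts:
        keys.update(t.exon_keys())
    events = {}
    for key in keys:
        inc = {
            t.transcript_id
            for t in transcripts
            if (key[1], key[2]) in t.exons and t.chrom == key[0]
        }
        if inc and inc != ids:
            events[key] = (frozenset(inc), frozenset(ids - inc))
    return events


def random_toy_gene(rng, gene_id="G"):
    """A random gene with <= 6 transcripts drawn over a pool of exons."""
    n_exons = int(rng.integers(3, 7))
    bounds = np.sort(rng.choice(np.arange(100, 2000, 10),
                                size=2 * n_exons, replace=False))
    pool = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
    n_tx = int(rng.integers(1, 7))
    transcripts = []
    for t in range(n_tx):
        k = int(rng.integers(1, n_exons + 1))
        chosen = sorted(rng.choice(n_exons, size=k, replace=False))
        transcripts.append(
            TranscriptModel(f"tx{t}", gene_id, "chr1", "+",
                            [pool[i] for i in chosen])
        )
    return transcripts


def all_label_assignments(labels):
    """Every distinct assignment of a label multiset (test-side oracle)."""
    seen = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm)
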