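"""Consensus circRNA calling from two caller outputs.

circRNAs detected by both a CIRI2-style and a CIRCexplorer2-style workflow
are treated as bona fide.  The CIRCexplorer2-style output (caller "B") is
first filtered to junctions with at least two back-spliced-junction reads;
the junction lists are intersected on (chrom, start, end); and per-sample
counts for consensus junctions are the arithmetic mean of the two callers'
junction read counts, with a junction absent from one caller in a given
sample contributing 0 on that caller's side (consensus membership is decided
at the junction level, not per sample).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import CountMatrix
from .junction import (
    BackspliceJunction,
    CircRecord,
    DetectionSummary,
    detection_summary,
)

__all__ = [
    "filter_bsj_support",
    "intersect_callers",
    "records_to_counts",
    "consensus_counts",
    "consensus_from_records",
    "detect_per_condition",
    "detection_summary",
    "DetectionSummary",
]


def filter_bsj_support(
    records: Iterable[CircRecord], min_reads: int = 2, caller: str = "B"
) -> list[CircRecord]:
    """Drop records of the named caller with fewer than ``min_reads``
    junction-spanning reads; the other caller's records pass unchanged."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return [
        r for r in records if r.caller != caller or r.junction_reads >= min_reads
    ]


def intersect_callers(
    a: Iterable[BackspliceJunction], b: Iterable[BackspliceJunction]
) -> set[BackspliceJunction]:
    """Exact set intersection on (chrom, start, end); strand ignored."""
    return set(a) & set(b)


def records_to_counts(
    records: Iterable[CircRecord], sample_ids: Sequence[str] | None = None
) -> CountMatrix:
    """Pivot records into a junction x sample count matrix.

    Multiple records for the same (junction, sample) from one caller are
    summed.  ``sample_ids`` fixes the column order (and includes samples
    with no detections).
    """
    records = list(records)
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    junctions = sorted({r.junction for r in records})
    jidx = {j: i for i, j in enumerate(junctions)}
    sidx = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(junctions), len(sample_ids)))
    for r in records:
        if r.sample_id not in sidx:
            raise ValueError(f"record sample {r.sample_id!r} not in sample_ids")
        counts[jidx[r.junction], sidx[r.sample_id]] += r.junction_reads
    return CountMatrix([j.circ_id for j in junctions], list(sample_ids), counts)


def consensus_counts(
    a: CountMatrix, b: CountMatrix, junctions: Iterable[BackspliceJunction]
) -> CountMatrix:
    """Average the two callers' counts over the consensus junctions.

    Matrices are indexed by canonical circRNA ID; a junction absent from one
    caller in a sample contributes 0 for that caller (mean of (x, 0) = x/2).
    """
    if list(a.sample_ids) != list(b.sample_ids):
        raise ValueError("caller matrices cover different sample sets")
    ids = [j.circ_id for j in sorted(set(junctions))]
    da, db = a.to_dataframe(), b.to_dataframe()
    out = pd.DataFrame(0.0, index=ids, columns=a.sample_ids)
    for df in (da, db):
        present = [i for i in ids if i in df.index]
        out.loc[present] += df.loc[present].to_numpy()
    return CountMatrix(ids, list(a.sample_ids), out.to_numpy() / 2.0)


def consensus_from_records(
    records_a: Iterable[CircRecord],
    records_b: Iterable[CircRecord],
    sample_ids: Sequence[str],
    min_reads_b: int = 2,
    per_sample: bool = False,
) -> tuple[set[BackspliceJunction], CountMatrix]:
    """Full consensus step: support filter on caller B, intersection of the
    pooled candidate lists, averaged counts.

    With ``per_sample=True`` the intersection is taken within each sample
    and a junction is consensus if the callers agree in at least one sample
    (instead of intersecting the pooled candidate lists).
    """
    records_a = list(records_a)
    records_b = filter_bsj_support(list(records_b), min_reads=min_reads_b, caller="B")
    if per_sample:
        consensus: set[BackspliceJunction] = set()
        for s in sample_ids:
            ja = {r.junction for r in records_a if r.sample_id == s}
            jb = {r.junction for r in records_b if r.sample_id == s}
            consensus |= ja & jb
    else:
        consensus = intersect_callers(
            {r.junction for r in records_a}, {r.junction for r in records_b}
        )
    mat_a = records_to_counts(records_a, sample_ids)
    mat_b = records_to_counts(records_b, sample_ids)
    return consensus, consensus_counts(mat_a, mat_b, consensus)


def detect_per_condition(
    counts: CountMatrix, metadata: pd.DataFrame, tissue: str
) -> dict[str, set[str]]:
    """Junction IDs detected (count > 0 in >= 1 sample) per condition.

    ``metadata`` needs sample/tissue/condition columns; "ALS" maps to
    "case", "control" to "control".
    """
    sub = metadata[metadata["tissue"] == tissue]
    out: dict[str, set[str]] = {}
    for label, cond in (("case", "ALS"), ("control", "control")):
        samples = [s for s in sub.loc[sub["condition"] == cond, "sample"] if s in counts.sample_ids]
        if not samples:
            out[label] = set()
            continue
        m = counts.subset_samples(samples)
        present = (np.asarray(m.counts) > 0).any(axis=1)
        out[label] = {f for f, p in zip(m.feature_ids, present) if p}
    return out
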