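"""BSJ-read filtering, cross-tool consensus and count-matrix construction.

A circRNA's cross-tool identity is the coordinate key ``(chrom, start, end)``
only: caller strand assignments are unreliable, and strand-agnostic matching
maximises consensus recall. The record strand is resolved by majority vote
over the calling tools, with ties going to '+'.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .records import CircKey, CircRNACall, ConsensusRecord, circ_id

AGGREGATIONS = ("max", "mean")


def filter_bsj(calls: Sequence[CircRNACall], min_reads: int) -> List[CircRNACall]:
    """Keep calls with at least ``min_reads`` BSJ-spanning reads (inclusive)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [c for c in calls if c.bsj_reads >= min_reads]


def _round_half_up(value: float) -> int:
    return math.floor(value + 0.5)


def build_consensus(
    calls_by_tool: Mapping[str, Sequence[CircRNACall]],
    tool_filter: int = 1,
    duplicates_fun: str = "max",
) -> List[ConsensusRecord]:
    """Keep keys called by at least ``tool_filter`` distinct tools.

    ``duplicates_fun`` aggregates the per-tool BSJ read counts of a surviving
    key: 'max' takes the highest count, 'mean' the arithmetic mean (the exact
    value is retained in ``aggregated_exact``; ``aggregated_count`` rounds
    half-up to an integer for count-matrix emission).
    """
    if duplicates_fun not in AGGREGATIONS:
        raise ValueError(f"duplicates_fun must be one of {AGGREGATIONS}")
    if not 1 <= tool_filter <= max(len(calls_by_tool), 1):
        raise ValueError(
            f"tool_filter must be in [1, {len(calls_by_tool)}], got {tool_filter}"
        )

    per_key_counts: Dict[CircKey, Dict[str, int]] = {}
    per_key_strands: Dict[CircKey, List[str]] = {}
    for tool, calls in calls_by_tool.items():
        for call in calls:
            # duplicate keys within one tool merge by summing read evidence
            counts = per_key_counts.setdefault(call.key, {})
            counts[tool] = counts.get(tool, 0) + call.bsj_reads
            per_key_strands.setdefault(call.key, []).append(call.strand)

    records: List[ConsensusRecord] = []
    for key in sorted(per_key_counts):
        counts = per_key_counts[key]
        if len(counts) < tool_filter:
            continue
        votes = Counter(s for s in per_key_strands[key] if s in "+-")
        if votes and votes["+"] != votes["-"]:
            strand = votes.most_common(1)[0][0]
        elif votes:
            strand = "+"  # tie
        else:
            strand = "+"
        values = list(counts.values())
        exact = max(values) if duplicates_fun == "max" else sum(values) / len(values)
        records.append(
            ConsensusRecord(
                key=key,
                strand=strand,
                per_tool_counts=dict(counts),
                aggregated_count=_round_half_up(exact),
                aggregated_exact=float(exact),
            )
        )
    return records


def build_count_matrix(
    per_sample: Mapping[str, Sequence[ConsensusRecord]],
) -> pd.DataFrame:
    """circRNA x sample integer count matrix.

    Rows are the union of surviving keys across samples (lexicographic circRNA
    identifiers); a key absent from a sample contributes 0. Strand in the row
    identifier is re-resolved across samples by majority vote so a key maps to
    one row.
    """
    samples = list(per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample identifiers")

    strand_votes: Dict[CircKey, Counter] = {}
    for records in per_sample.values():
        for rec in records:
            strand_votes.setdefault(rec.key, Counter())[rec.strand] += 1
    row_strand = {
        key: "-" if votes.get("-", 0) > votes.get("+", 0) else "+"
        for key, votes in strand_votes.items()
    }

    cells: Dict[str, Dict[str, int]] = {}
    for sample, records in per_sample.items():
        for rec in records:
            row_id = circ_id(*rec.key, row_strand[rec.key])
            cells.setdefault(row_id, {})[sample] = rec.aggregated_count

    matrix = pd.DataFrame.from_dict(cells, orient="index", dtype="float")
    matrix = matrix.reindex(
        index=sorted(cells), columns=sorted(samples)
    ).fillna(0).astype(int)
    matrix.index.name = "circRNA_ID"
    return matrix


def write_count_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t")


def read_count_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
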