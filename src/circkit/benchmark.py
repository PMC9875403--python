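"""Benchmarking of circRNA call sets against a truth set.

Because a simulated truth set contains no true negatives, every called key
absent from the truth counts as a false positive. Precision is the fraction
of called keys that are true, sensitivity the fraction of truth keys
recovered, and F1 their harmonic mean; all three are reported as percentages
rounded to two decimals (half away from zero).

Also here: the pairwise common-candidate proportion matrix
P(i, j) = C(i, j) / N_i, and the tool-subset combinatorics sweep coupling
subset enumeration with consensus thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import AbstractSet, Dict, Iterable, List, Mapping, Sequence, Tuple
import warnings

import pandas as pd

from .records import BenchmarkResult, CircKey


def round2(value: float) -> float:
    """Round to two decimals, half away from zero."""
    quantised = Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(quantised)


def metrics_from_counts(detected: int, tp: int, truth_size: int) -> BenchmarkResult:
    """Precision/sensitivity/F1 (percent, 2 dp) from raw counts.

    F1 is computed from the unrounded precision and sensitivity, then rounded.
    """
    if truth_size <= 0:
        raise ValueError("truth set must be non-empty (sensitivity undefined)")
    if tp > detected or tp > truth_size or min(detected, tp) < 0:
        raise ValueError(f"inconsistent counts detected={detected} tp={tp}")
    precision = 100.0 * tp / detected if detected else 0.0
    sensitivity = 100.0 * tp / truth_size
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return BenchmarkResult(
        detected=detected,
        tp=tp,
        truth_size=truth_size,
        precision=round2(precision),
        sensitivity=round2(sensitivity),
        f1=round2(f1),
    )


def harmonic_f1(precision: float, sensitivity: float) -> float:
    """F1 (2 dp) from already-computed percentage precision and sensitivity."""
    if precision + sensitivity == 0:
        return 0.0
    return round2(2 * precision * sensitivity / (precision + sensitivity))


def _matches_truth(key: CircKey, truth: AbstractSet[CircKey], slack: int) -> bool:
    if slack == 0:
        return key in truth
    chrom, start, end = key
    for t_chrom, t_start, t_end in truth:
        if (
            t_chrom == chrom
            and abs(t_start - start) <= slack
            and abs(t_end - end) <= slack
        ):
            return True
    return False


def score_against_truth(
    calls: AbstractSet[CircKey],
    truth: AbstractSet[CircKey],
    slack: int = 0,
) -> BenchmarkResult:
    """Score a set of canonical keys against a truth key set.

    ``slack`` permits +/- that many bp on both coordinates when matching
    (default 0, exact). A truth key may support multiple called keys under
    slack; with the default exact matching, tp is plain set intersection.
    """
    if not truth:
        raise ValueError("truth set must be non-empty (sensitivity undefined)")
    if slack == 0:
        tp = len(calls & set(truth))
    else:
        tp = sum(1 for key in calls if _matches_truth(key, truth, slack))
    return metrics_from_counts(len(calls), tp, len(truth))


@dataclass(frozen=True)
class ProportionMatrix:
    tools: Tuple[str, ...]
    values: pd.DataFrame  # square, indexed by tools in input order

    def cell(self, tool_i: str, tool_j: str) -> float:
        return float(self.values.loc[tool_i, tool_j])


def proportion_matrix(key_sets: Mapping[str, AbstractSet[CircKey]]) -> ProportionMatrix:
    """Pairwise common-candidate proportions P(i, j) = |i ∩ j| / |i|.

    Row i, column j holds the fraction of tool i's calls also called by tool
    j; the matrix is generally asymmetric but satisfies
    P(i, j) * N_i = P(j, i) * N_j. Empty-set tools get zero rows/columns (the
    diagonal stays 1 by convention only for non-empty sets).
    """
    tools = tuple(key_sets)
    if len(tools) < 2:
        raise ValueError("need at least two tools")
    for tool, keys in key_sets.items():
        if not keys:
            warnings.warn(f"tool {tool!r} has an empty key set; row reported as 0")
    data = {
        ti: {
            tj: (
                len(key_sets[ti] & key_sets[tj]) / len(key_sets[ti])
                if key_sets[ti]
                else 0.0
            )
            for tj in tools
        }
        for ti in tools
    }
    frame = pd.DataFrame(data).T.reindex(index=tools, columns=tools)
    return ProportionMatrix(tools=tools, values=frame)


@dataclass(frozen=True)
class SweepRow:
    subset: Tuple[str, ...]
    k: int
    tool_filter: int
    result: BenchmarkResult


def consensus_keys(
    key_sets: Mapping[str, AbstractSet[CircKey]], tool_filter: int
) -> set:
    """Keys called by at least ``tool_filter`` of the given tools."""
    counts: Dict[CircKey, int] = {}
    for keys in key_sets.values():
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
    return {key for key, n in counts.items() if n >= tool_filter}


def combinatorics_sweep(
    key_sets: Mapping[str, AbstractSet[CircKey]],
    k_range: Sequence[int],
    tool_filter_values: Sequence[int],
    truth: AbstractSet[CircKey],
    slack: int = 0,
) -> List[SweepRow]:
    """Benchmark every unique tool subset at every consensus threshold.

    Subsets are enumerated order-free (combinations); a threshold exceeding
    the subset size is skipped for that subset. Each evaluated key set is
    {key called by >= tool_filter tools of the subset}, scored against truth.
    """
    tools = list(key_sets)
    n = len(tools)
    for k in k_range:
        if not 1 <= k <= n:
            raise ValueError(f"subset size {k} outside [1, {n}]")
    rows: List[SweepRow] = []
    for k in k_range:
        for subset in combinations(tools, k):
            sub_sets = {t: key_sets[t] for t in subset}
            for tool_filter in tool_filter_values:
                if tool_filter > k:
                    continue
                evaluated = consensus_keys(sub_sets, tool_filter)
                rows.append(
                    SweepRow(
                        subset=subset,
                        k=k,
                        tool_filter=tool_filter,
                        result=score_against_truth(evaluated, truth, slack),
                    )
                )
    return rows


def sweep_table(rows: Iterable[SweepRow]) -> pd.DataFrame:
    """Sweep results as a tidy table ready for tab-separated output."""
    return pd.DataFrame(
        {
            "subset": ",".join(row.subset),
            "k": row.k,
            "tool_filter": row.tool_filter,
            "detected": row.result.detected,
            "tp": row.result.tp,
            "precision": row.result.precision,
            "sensitivity": row.result.sensitivity,
            "f1": row.result.f1,
        }
        for row in rows
    )
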