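"""Differential calling: two-sample t-test, fold-change thresholds, Venn cells.

A protein (or glycosite) is called *up* in a comparison when its linear
ratio exceeds the fold-change threshold (default 1.5) and its two-tailed
Student's t-test p-value is below alpha (default 0.05); *down* when the
ratio is below the reciprocal threshold (1/1.5); otherwise *unchanged*.
Rows lacking enough replicate observations are *untestable*.  No
multiple-testing correction is applied by default; a Benjamini-Hochberg
option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_UNTESTABLE = "untestable"


@dataclass(frozen=True)
class Thresholds:
    """Differential-calling thresholds: fold change > 1.5 and p < 0.05."""

    fold_change: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.fold_change > 1:
            raise ValueError("fold_change must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def student_t_two_tailed(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-tailed pooled (equal-variance) two-sample Student's t-test.

    Degenerate conventions: if both groups are constant, p = 1 when their
    values are equal and p = 0 when they differ (zero within-group variance
    makes any difference infinitely significant).

    Each group needs at least 2 finite values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("each group needs >= 2 finite values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def call_one(ratio: float, p_value: float, thresholds: Thresholds) -> str:
    """Classify a single (ratio, p) pair."""
    if not (np.isfinite(ratio) and np.isfinite(p_value)):
        return CALL_UNTESTABLE
    if p_value < thresholds.alpha:
        if ratio > thresholds.fold_change:
            return CALL_UP
        if ratio < 1.0 / thresholds.fold_change:
            return CALL_DOWN
    return CALL_UNCHANGED


def call_differential(
    quant: pd.DataFrame,
    comparisons: Iterable[str],
    thresholds: Thresholds = Thresholds(),
    ratio_prefix: str = "ratio",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Long-format differential calls from a quantitation table.

    ``quant`` must carry, per comparison label, ``<ratio_prefix> <label>``
    and ``p_value <label>`` columns (site tables pass
    ``ratio_prefix='corrected_ratio'`` so calls use protein-corrected
    ratios).  Identifier columns (``accession``, optional ``position``) are
    taken from the index or columns.

    With ``bh_correct`` the p-values of each comparison are
    Benjamini-Hochberg adjusted before thresholding (off by default).
    """
    id_cols = {}
    if quant.index.name == "accession":
        id_cols["accession"] = quant.index.to_numpy()
    else:
        id_cols["accession"] = quant["accession"].to_numpy()
    if "position" in quant.columns:
        id_cols["position"] = quant["position"].to_numpy()

    frames = []
    for lab in comparisons:
        ratios = quant[f"{ratio_prefix} {lab}"].to_numpy(dtype=float)
        pvals = quant[f"p_value {lab}"].to_numpy(dtype=float)
        if bh_correct:
            finite = np.isfinite(pvals)
            adj = pvals.copy()
            if finite.any():
                adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
            pvals = adj
        calls = [call_one(r, p, thresholds) for r, p in zip(ratios, pvals)]
        frame = pd.DataFrame({**id_cols, "comparison": lab, "ratio": ratios,
                              "p_value": pvals, "call": calls})
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def call_sets(calls: pd.DataFrame, comparison: str) -> dict[str, set[str]]:
    """Accession sets of up/down calls for one comparison."""
    sub = calls[calls["comparison"] == comparison]
    return {
        CALL_UP: set(sub.loc[sub["call"] == CALL_UP, "accession"]),
        CALL_DOWN: set(sub.loc[sub["call"] == CALL_DOWN, "accession"]),
    }


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint cells of a 3-set Venn diagram.

    ``cells`` maps a membership key like ``'A'``, ``'AB'``, ``'ABC'`` to the
    member set; ``labels`` maps the single-letter slots to the caller's set
    names.  The triple intersection (``'ABC'``) is the *common* cell.
    """

    labels: tuple[str, str, str]
    cells: Mapping[str, frozenset]

    @property
    def common(self) -> frozenset:
        return self.cells["ABC"]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.cells.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("A", "B", "C", "AB", "AC", "BC", "ABC"):
            nice = "&".join(self.labels["ABC".index(c)] for c in key)
            rows.append({"cell": key, "sets": nice, "count": len(self.cells[key]),
                         "members": ";".join(sorted(map(str, self.cells[key])))})
        return pd.DataFrame(rows)


def venn_partition(
    set_a: Iterable, set_b: Iterable, set_c: Iterable,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Partition three sets into the 7 disjoint Venn cells."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    buckets: dict[str, set] = {
        "".join(k for k, flag in zip("ABC", flags) if flag): set()
        for flags in product((True, False), repeat=3)
        if any(flags)
    }
    for x in a | b | c:
        key = "".join(k for k, s in zip("ABC", (a, b, c)) if x in s)
        buckets[key].add(x)
    cells = {k: frozenset(v) for k, v in buckets.items()}
    return VennPartition(labels=tuple(labels), cells=cells)


def call_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison counts of up/down/unchanged/untestable calls."""
    counts = (
        calls.groupby(["comparison", "call"]).size().unstack(fill_value=0)
    )
    for col in (CALL_UP, CALL_DOWN, CALL_UNCHANGED, CALL_UNTESTABLE):
        if col not in counts.columns:
            counts[col] = 0
    return counts[[CALL_UP, CALL_DOWN, CALL_UNCHANGED, CALL_UNTESTABLE]]
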