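"""Fisher-exact functional enrichment, enrichment heatmaps, localization.

Enrichment of a foreground protein set (e.g. proteins upregulated at high
temperature) against a background (all quantified proteins by default) is
tested per category (GO term, KEGG pathway or domain) with a two-tailed
Fisher's exact test.  The two-sided p-value follows the minimum-likelihood
definition: the sum of the probabilities of all 2x2 tables with the same
margins whose point probability does not exceed the observed one (within a
relative slack of 1e-12 for floating-point ties).

Significant categories (raw p < 0.05; an optional Benjamini-Hochberg flag
exists) across several (comparison x direction) cells are assembled into a
-log10(p) matrix and clustered hierarchically (Euclidean distance, average
linkage) with a deterministic row order obtained by sorting categories by
id before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable

#: Relative slack when comparing point probabilities for the two-sided sum.
PMF_SLACK = 1e-12
#: p-value floor applied before taking -log10 for heatmaps.
P_FLOOR = 1e-15


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 enrichment counts: k of K foreground and n of N background
    members fall in the category, foreground being a subset of background."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.K <= self.N and self.k <= self.n <= self.N):
            raise ValueError(f"invalid margins: k={self.k} K={self.K} n={self.n} N={self.N}")
        if self.n - self.k > self.N - self.K:
            raise ValueError(
                f"category members outside foreground ({self.n - self.k}) exceed "
                f"background-only size ({self.N - self.K})")

    @property
    def fold_enrichment(self) -> float:
        if self.K == 0 or self.n == 0:
            return float("nan")
        return (self.k / self.K) / (self.n / self.N)


def fisher_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher's exact p-value by hypergeometric enumeration.

    Sums hypergeometric point probabilities over all k' compatible with the
    margins whose probability is <= the observed one (relative slack 1e-12).
    """
    k, K, n, N = table.k, table.K, table.n, table.N
    lo = max(0, K + n - N)
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, n, K)
    p_obs = pmf[k - lo]
    include = pmf <= p_obs * (1.0 + PMF_SLACK)
    if include.all():  # every table is at most as likely: p is exactly 1
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


@dataclass(frozen=True)
class EnrichmentRow:
    """One category's enrichment result for one foreground set."""

    category: str
    namespace: str
    table: ContingencyTable
    p_value: float
    significant: bool
    direction: str  # e.g. "up@T50/T30"

    @property
    def fold_enrichment(self) -> float:
        return self.table.fold_enrichment


def enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationTable,
    namespace: str,
    alpha: float = 0.05,
    direction: str = "",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-category Fisher-exact enrichment of foreground vs background.

    ``namespace`` is ``BP``/``MF``/``CC`` (GO), ``KEGG`` or ``DOMAIN``.
    One row per category with at least one foreground member, sorted by
    p-value.  The background defaults to the set of quantified proteins and
    must contain the foreground.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    members_of = annotations.terms_by_category(namespace)

    K, N = len(fg), len(bg)
    rows = []
    for category in sorted(members_of):
        cat_bg = members_of[category] & bg
        cat_fg = cat_bg & fg
        if not cat_fg:
            continue
        tab = ContingencyTable(k=len(cat_fg), K=K, n=len(cat_bg), N=N)
        p = fisher_two_tailed(tab)
        rows.append(
            {
                "category": category,
                "namespace": namespace,
                "k": tab.k,
                "K": tab.K,
                "n": tab.n,
                "N": tab.N,
                "fold_enrichment": tab.fold_enrichment,
                "p_value": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["category", "namespace", "k", "K", "n", "N",
                 "fold_enrichment", "p_value", "direction"],
    )
    if bh_correct and len(df):
        df["p_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["p_value"] < alpha
    return df.sort_values(["p_value", "category"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Enrichment heatmap
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentHeatmap:
    """-log10(p) matrix (categories x cells) with dendrogram leaf orders."""

    matrix: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def cluster_heatmap(
    rows: pd.DataFrame,
    alpha: float = 0.05,
    min_k: int = 2,
    p_floor: float = P_FLOOR,
) -> EnrichmentHeatmap:
    """Cluster enrichment results into a -log10(p) heatmap.

    ``rows`` is a concatenation of :func:`enrich` outputs across
    (comparison x direction) cells, distinguished by their ``direction``
    column.  Only categories significant (p < alpha) in at least one cell
    and with at least ``min_k`` foreground members somewhere are kept
    (single-protein categories make unstable -log10(p) rows).  p-values are
    floored at ``p_floor``.  Hierarchical clustering uses Euclidean
    distance with average linkage; categories are sorted by id first so the
    leaf order is deterministic and input-order independent.
    """
    keep_cats = sorted(
        set(rows.loc[(rows["p_value"] < alpha) & (rows["k"] >= min_k), "category"])
    )
    cells = sorted(set(rows["direction"]))
    mat = pd.DataFrame(0.0, index=keep_cats, columns=cells)
    for _, r in rows.iterrows():
        if r["category"] in mat.index:
            mat.at[r["category"], r["direction"]] = -np.log10(max(r["p_value"], p_floor))

    row_link = col_link = None
    row_order, col_order = list(mat.index), list(mat.columns)
    if len(mat) >= 2:
        row_link = hierarchy.linkage(pdist(mat.to_numpy()), method="average")
        row_order = [mat.index[i] for i in hierarchy.leaves_list(row_link)]
    if len(mat.columns) >= 2 and len(mat) >= 1:
        col_link = hierarchy.linkage(pdist(mat.to_numpy().T), method="average")
        col_order = [mat.columns[i] for i in hierarchy.leaves_list(col_link)]
    return EnrichmentHeatmap(mat, row_order, col_order, row_link, col_link)


# ---------------------------------------------------------------------------
# Subcellular localization summary
# ---------------------------------------------------------------------------


def localization_summary(
    accessions: Iterable[str], annotations: AnnotationTable
) -> pd.DataFrame:
    """Counts and percentages per subcellular compartment for a protein set.

    Proteins without a location label are binned as ``unknown``.  Raises on
    an empty set.  Percentages sum to 100.
    """
    accs = sorted(set(accessions))
    if not accs:
        raise ValueError("localization_summary of an empty protein set")
    labels = [annotations.subcellular_location(a) or "unknown" for a in accs]
    counts = pd.Series(labels).value_counts()
    df = pd.DataFrame({"count": counts})
    df["percent"] = 100.0 * df["count"] / df["count"].sum()
    df.index.name = "compartment"
    df = df.sort_index()
    return df.sort_values("count", ascending=False, kind="mergesort")
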