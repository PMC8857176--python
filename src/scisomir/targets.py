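"""Correlation of isomiR-category expression with predicted canonical targets.

The procedure: aggregate per-algorithm target predictions into one target set
per miRNA (a gene must be predicted by at least two algorithms; its score is
the minimum rank across algorithms), correlate each isomiR category's
per-cell normalized expression with every gene's mRNA expression across
cells, and compare the resulting Pearson-correlation distributions between
predicted targets and all remaining genes with a two-sample
Kolmogorov-Smirnov test. A left-shifted target ECDF (more negative
correlations than non-targets) is the signature of active repression.

Categories tested per miRNA: TOTAL (all of the miRNA's reads), CANONICAL,
FP_VARIANT, TP_TEMPLATED, NTA_A / NTA_U (>= 1 non-templated adenine /
uridine) and SUBSTITUTION. Expression values are counts-per-million over the
cell's miRNA-mapped reads by default; a parent-miRNA-relative mode is
available. mRNA profiles are log1p(CPM)-transformed before correlating by
default. No multiple-testing correction is applied to the per-test alpha; a
Benjamini-Hochberg column is reported alongside for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FormatError, ProcessingError

TEST_CATEGORIES = (
    "TOTAL", "CANONICAL", "FP_VARIANT", "TP_TEMPLATED", "NTA_A", "NTA_U", "SUBSTITUTION",
)

_CATEGORY_FLAG = {
    "CANONICAL": "is_canonical",
    "FP_VARIANT": "is_fp_variant",
    "TP_TEMPLATED": "is_tp_templated",
    "NTA_A": "has_nta_a",
    "NTA_U": "has_nta_u",
    "SUBSTITUTION": "is_substitution",
}


def validate_target_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"mirna", "gene", "source", "rank"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"target table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["mirna", "gene", "source"]).any():
        raise FormatError("target table has duplicate (mirna, gene, source) rows")
    if (table["rank"] <= 0).any():
        raise FormatError("target ranks must be positive")
    return table


def aggregate_targets(
    table: pd.DataFrame, method: str = "minimum", min_sources: int = 2
) -> dict[str, pd.Series]:
    """Per-miRNA aggregated target sets.

    Only genes predicted by at least ``min_sources`` distinct algorithms are
    retained; the aggregate score is the minimum rank across algorithms
    (lower = stronger), reported for ordering but never used as a cutoff.
    Returns ``{mirna: Series(score, index=gene, ascending)}``.
    """
    if method != "minimum":
        raise ConfigError(f"unsupported aggregation method {method!r}")
    if len(table) == 0:
        warnings.warn("empty target table: no aggregated targets", stacklevel=2)
        return {}
    validate_target_table(table)
    out: dict[str, pd.Series] = {}
    for mirna, sub in table.groupby("mirna"):
        by_gene = sub.groupby("gene").agg(
            n_sources=("source", "nunique"), score=("rank", "min")
        )
        kept = by_gene[by_gene["n_sources"] >= min_sources]["score"]
        out[mirna] = kept.sort_values(kind="mergesort")
    return out


def category_expression(
    ann: pd.DataFrame,
    mirna: str,
    category: str,
    normalization: str = "cpm",
) -> pd.Series:
    """Per-cell normalized expression of one miRNA's reads in one category.

    ``normalization='cpm'``: counts per million of the cell's miRNA-mapped
    reads (depth correction against the whole small-RNA content);
    ``'parent'``: fraction of the parent miRNA's own reads (the
    relative-abundance view); ``'raw'``: plain counts.
    """
    if category not in TEST_CATEGORIES:
        raise ConfigError(f"unknown category {category!r}")
    if mirna not in set(ann["mature"]):
        raise KeyError(f"miRNA {mirna!r} not present in annotations")
    cells = pd.Index(sorted(ann["cell"].unique()), name="cell")
    mine = ann[ann["mature"] == mirna]
    if category != "TOTAL":
        mine = mine[mine[_CATEGORY_FLAG[category]]]
    counts = mine.groupby("cell").size().reindex(cells, fill_value=0).astype(float)
    if normalization == "raw":
        return counts
    if normalization == "cpm":
        totals = ann.groupby("cell").size().reindex(cells, fill_value=0)
        return (counts / totals.replace(0, np.nan) * 1e6).fillna(0.0)
    if normalization == "parent":
        parent = (
            ann[ann["mature"] == mirna].groupby("cell").size().reindex(cells, fill_value=0)
        )
        return (counts / parent.replace(0, np.nan)).fillna(0.0)
    raise ConfigError(f"unknown normalization {normalization!r}")


def correlate(
    category_vec: pd.Series,
    mrna: pd.DataFrame,
    normalization: str = "log1p_cpm",
) -> pd.Series:
    """Pearson correlation of a per-cell expression vector with every gene.

    ``mrna`` is genes x cells; only cells shared with ``category_vec`` are
    used (>= 3 required). Genes with zero variance across the shared cells
    are returned as NaN and excluded from downstream ECDFs.
    """
    shared = category_vec.index.intersection(mrna.columns)
    if len(shared) < 3:
        raise ProcessingError(
            f"need >= 3 shared cells to correlate, got {len(shared)}"
        )
    x = category_vec.loc[shared].to_numpy(dtype=float)
    Y = mrna.loc[:, shared].to_numpy(dtype=float)
    if normalization == "log1p_cpm":
        col_tot = Y.sum(axis=0)
        Y = np.log1p(Y / np.where(col_tot == 0, np.nan, col_tot) * 1e6)
    elif normalization == "cpm":
        col_tot = Y.sum(axis=0)
        Y = Y / np.where(col_tot == 0, np.nan, col_tot) * 1e6
    elif normalization != "none":
        raise ConfigError(f"unknown mRNA normalization {normalization!r}")

    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / (ynorm * xnorm)
    r[~np.isfinite(r)] = np.nan
    return pd.Series(r, index=mrna.index, name="pearson_r")


@dataclass
class KsResult:
    """Two-sample KS comparison of target vs non-target correlation ECDFs."""

    mirna: str
    category: str
    target_correlations: np.ndarray
    nontarget_correlations: np.ndarray
    ks_statistic: float = np.nan
    p_value: float = np.nan
    direction: str = "none"
    category_read_share: float = np.nan
    testable: bool = True
    p_bh: float = np.nan  # informational Benjamini-Hochberg adjusted p

    def to_row(self) -> dict:
        return {
            "mirna": self.mirna,
            "category": self.category,
            "n_targets": len(self.target_correlations),
            "n_nontargets": len(self.nontarget_correlations),
            "ks_statistic": self.ks_statistic,
            "p_value": self.p_value,
            "p_bh": self.p_bh,
            "direction": self.direction,
            "category_read_share": self.category_read_share,
            "testable": self.testable,
            "median_target_r": (
                float(np.median(self.target_correlations))
                if len(self.target_correlations)
                else np.nan
            ),
            "median_nontarget_r": (
                float(np.median(self.nontarget_correlations))
                if len(self.nontarget_correlations)
                else np.nan
            ),
        }


def ks_target_test(
    target_r,
    nontarget_r,
    alpha: float = 0.05,
    mirna: str = "",
    category: str = "",
    method: str = "asymp",
) -> KsResult:
    """Two-sided two-sample KS test between correlation distributions.

    Direction is assigned only at p < alpha: "negative" when the target
    median correlation lies below the non-target median (repression
    signature), otherwise "positive". Vectors shorter than 5 after NaN
    removal are flagged untestable.
    """
    t = np.asarray(target_r, dtype=float)
    nt = np.asarray(nontarget_r, dtype=float)
    t = t[np.isfinite(t)]
    nt = nt[np.isfinite(nt)]
    res = KsResult(
        mirna=mirna, category=category,
        target_correlations=t, nontarget_correlations=nt,
    )
    if len(t) < 5 or len(nt) < 5:
        res.testable = False
        return res
    ks = stats.ks_2samp(t, nt, alternative="two-sided", method=method)
    res.ks_statistic = float(ks.statistic)
    res.p_value = float(ks.pvalue)
    if res.p_value < alpha:
        res.direction = (
            "negative" if np.median(t) < np.median(nt) else "positive"
        )
    return res


def ecdf_frame(results: list[KsResult]) -> pd.DataFrame:
    """Long-format ECDF table (mirna, category, group, r, ecdf) for plotting."""
    rows = []
    for res in results:
        for group, vec in (
            ("target", res.target_correlations),
            ("nontarget", res.nontarget_correlations),
        ):
            v = np.sort(vec)
            n = len(v)
            for i, r in enumerate(v, start=1):
                rows.append((res.mirna, res.category, group, float(r), i / n))
    return pd.DataFrame(rows, columns=["mirna", "category", "group", "r", "ecdf"])


def run_target_analysis(
    ann: pd.DataFrame,
    mrna: pd.DataFrame,
    target_table: pd.DataFrame,
    top_k_mirnas: int = 6,
    min_noncanonical_share: float = 0.1,
    alpha: float = 0.05,
    min_category_reads: int = 10,
    mirna_normalization: str = "cpm",
    mrna_normalization: str = "log1p_cpm",
    min_sources: int = 2,
) -> tuple[list[KsResult], pd.DataFrame]:
    """Full target-correlation screen over the top expressed miRNAs.

    Selects the ``top_k_mirnas`` most highly expressed miRNAs whose
    non-canonical read share exceeds ``min_noncanonical_share`` (miRNAs that
    are essentially all-canonical carry no isomiR signal to compare). For
    each, tests TOTAL and CANONICAL always and every other category with at
    least ``min_category_reads`` pooled reads. Non-targets are all mRNA genes
    outside the miRNA's aggregated target set, so targets and non-targets
    partition the gene universe per miRNA. Returns the KS results plus the
    long-format ECDF table.
    """
    shared = pd.Index(sorted(set(ann["cell"]) & set(mrna.columns)))
    if len(shared) < 3:
        raise ProcessingError("annotations and mRNA matrix share < 3 cells")
    ann = ann[ann["cell"].isin(shared)]

    per_mirna = ann.groupby("mature")
    expression = per_mirna.size().sort_values(ascending=False, kind="mergesort")
    noncanon_share = 1.0 - per_mirna["is_canonical"].mean()
    selected = [
        m for m in expression.index if noncanon_share[m] >= min_noncanonical_share
    ][:top_k_mirnas]
    if not selected:
        warnings.warn("no miRNA passed the expression/isomiR-share selection",
                      stacklevel=2)
        return [], ecdf_frame([])

    target_sets = aggregate_targets(target_table, min_sources=min_sources)
    results: list[KsResult] = []
    for mirna in selected:
        targets = pd.Index(target_sets.get(mirna, pd.Series(dtype=float)).index)
        targets = targets.intersection(mrna.index)
        nontargets = mrna.index.difference(targets)
        mine = ann[ann["mature"] == mirna]
        share = (
            mine.groupby("cell").size()
            / ann.groupby("cell").size().reindex(sorted(set(mine["cell"])))
        )
        for category in TEST_CATEGORIES:
            if category not in ("TOTAL", "CANONICAL"):
                pooled = (
                    len(mine) if category == "TOTAL"
                    else int(mine[_CATEGORY_FLAG[category]].sum())
                )
                if pooled < min_category_reads:
                    continue
            vec = category_expression(
                ann, mirna, category, normalization=mirna_normalization
            )
            r = correlate(vec, mrna, normalization=mrna_normalization)
            res = ks_target_test(
                r.loc[targets], r.loc[nontargets], alpha=alpha,
                mirna=mirna, category=category,
            )
            if category == "TOTAL":
                res.category_read_share = float(share.mean())
            else:
                cat_share = (
                    mine.groupby("cell")[_CATEGORY_FLAG[category]].mean()
                    if category != "CANONICAL"
                    else mine.groupby("cell")["is_canonical"].mean()
                )
                res.category_read_share = float(cat_share.mean())
            results.append(res)

    # informational BH adjustment across the testable results
    testable = [r for r in results if r.testable]
    if testable:
        p = np.array([r.p_value for r in testable])
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = m - rank_i  # 1-based rank from the largest p down
            prev = min(prev, p[idx] * m / i)
            adj[idx] = prev
        for r, a in zip(testable, adj):
            r.p_bh = float(a)
    return results, ecdf_frame(results)


def ks_results_frame(results: list[KsResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
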