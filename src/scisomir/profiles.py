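"""Per-cell quantification and isomiR profiling.

Everything here operates on the annotation frame produced by
:func:`scisomir.annotate.annotate_frame` (one row per aligned read, with
boolean category indicator columns). Counting can be done at three feature
levels — parent miRNA, exact isomiR (the tuple of 5'/3' offsets, tail and
substitution), or miRNA x category — in "reads" mode (pre-deduplication) or
"umis" mode (post-deduplication molecule counts).

Proportion profiles follow the cell-averaged convention: per-cell
proportions are computed first and then averaged unweighted across cells, so
deeply sequenced cells do not dominate; a pooled-read variant is available
behind ``cell_average=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .annotate import CATEGORIES, CATEGORY_COLUMNS
from .errors import ConfigError, ProcessingError

MIN_CELL_MIRNA_READS = 1000

FP_OFFSETS = tuple(range(-3, 4))
TP_OFFSETS = tuple(range(-3, 4))


@dataclass
class CellCountMatrix:
    """Cells x features count matrix with its counting metadata.

    ``mode`` is "reads" (pre-dedup) or "umis" (post-dedup molecules);
    ``level`` is "mirna", "isomir" or "category". At category level a read
    increments one feature per category it belongs to plus its parent
    ``<mirna>|TOTAL`` feature exactly once.
    """

    df: pd.DataFrame
    mode: str = "reads"
    level: str = "mirna"

    def totals(self) -> pd.Series:
        """Per-cell miRNA-mapped read (or molecule) totals."""
        if self.level == "category":
            total_cols = [c for c in self.df.columns if c.endswith("|TOTAL")]
            return self.df[total_cols].sum(axis=1)
        return self.df.sum(axis=1)

    def normalized(self, method: str = "cpm") -> pd.DataFrame:
        """Depth-normalize each cell: 'cpm' or 'fraction' of its total."""
        totals = self.totals().replace(0, np.nan)
        frac = self.df.div(totals, axis=0).fillna(0.0)
        if method == "fraction":
            return frac
        if method == "cpm":
            return frac * 1e6
        raise ConfigError(f"unknown normalization {method!r}")

    def to_anndata(self):
        """Counts as an AnnData (cells as obs, features as var)."""
        import anndata as ad

        return ad.AnnData(
            X=self.df.to_numpy(dtype=np.float64),
            obs=pd.DataFrame(index=self.df.index),
            var=pd.DataFrame(index=self.df.columns),
            uns={"mode": self.mode, "level": self.level},
        )


def _isomir_feature(row) -> str:
    sub = f"{row.sub_pos}{row.sub_ref}>{row.sub_alt}" if row.n_sub else ""
    return f"{row.mature}|{row.fp_offset:+d}|{row.tp_offset:+d}|{row.nta_tail}|{sub}"


def count_features(
    ann: pd.DataFrame, mode: str = "reads", level: str = "mirna"
) -> CellCountMatrix:
    """Aggregate an annotation frame into a cells x features count matrix."""
    if mode not in ("reads", "umis"):
        raise ConfigError(f"unknown counting mode {mode!r}")
    if mode == "umis" and (len(ann) > 0 and (ann["umi"].astype(str) == "").all()):
        raise ConfigError("umis counting mode requires UMI-tagged annotations")

    if level == "mirna":
        df = pd.crosstab(ann["cell"], ann["mature"])
    elif level == "isomir":
        feats = pd.Series(
            [_isomir_feature(r) for r in ann.itertuples(index=False)],
            index=ann.index, name="feature",
        )
        df = pd.crosstab(ann["cell"], feats)
    elif level == "category":
        pieces = {}
        for cat in CATEGORIES:
            sub = ann[ann[CATEGORY_COLUMNS[cat]]]
            tab = pd.crosstab(sub["cell"], sub["mature"])
            for mature in tab.columns:
                pieces[f"{mature}|{cat}"] = tab[mature]
        total = pd.crosstab(ann["cell"], ann["mature"])
        for mature in total.columns:
            pieces[f"{mature}|TOTAL"] = total[mature]
        df = pd.DataFrame(pieces).fillna(0).astype(np.int64)
    else:
        raise ConfigError(f"unknown counting level {level!r}")

    df = df.sort_index(axis=0).sort_index(axis=1)
    df.index.name = "cell"
    df.columns.name = "feature"
    return CellCountMatrix(df=df, mode=mode, level=level)


def filter_cells(
    m: CellCountMatrix, min_mirna_reads: int = MIN_CELL_MIRNA_READS
) -> CellCountMatrix:
    """Drop cells with fewer than ``min_mirna_reads`` miRNA-mapped reads.

    Applied to pre-deduplication read counts; a cell with exactly the
    threshold is retained.
    """
    if m.mode != "reads":
        raise ConfigError("cell filtering uses pre-deduplication read totals")
    keep = m.totals() >= min_mirna_reads
    if not keep.any():
        warnings.warn("all cells fall below the miRNA read threshold", stacklevel=2)
    return CellCountMatrix(df=m.df.loc[keep], mode=m.mode, level=m.level)


def isomir_parent_fractions(m: CellCountMatrix) -> pd.DataFrame:
    """Relative-abundance normalization: each isomiR feature divided by the
    per-cell total of its parent miRNA (rather than the whole cell)."""
    if m.level != "isomir":
        raise ConfigError("parent-relative normalization needs an isomir-level matrix")
    parents = pd.Series(
        [f.split("|", 1)[0] for f in m.df.columns], index=m.df.columns
    )
    parent_totals = m.df.T.groupby(parents).sum().T  # cells x parents
    denom = parent_totals.loc[:, parents.to_numpy()]
    denom.columns = m.df.columns
    return (m.df / denom.replace(0, np.nan)).fillna(0.0)


# ---------------------------------------------------------------------------
# distributions and profiles
# ---------------------------------------------------------------------------

def length_distribution(ann: pd.DataFrame, scope: str = "all") -> pd.Series:
    """Proportion of miRNA-mapped reads at each read length.

    ``scope='canonical_only'`` restricts the numerator to canonical reads
    while the denominator remains all miRNA-mapped reads, so the two curves
    are directly comparable.
    """
    if scope not in ("all", "canonical_only"):
        raise ConfigError(f"unknown scope {scope!r}")
    total = len(ann)
    if total == 0:
        return pd.Series(dtype=float, name="proportion")
    sub = ann[ann["is_canonical"]] if scope == "canonical_only" else ann
    counts = sub["read_len"].value_counts().sort_index()
    out = counts / total
    out.index.name = "length"
    out.name = "proportion"
    return out


def _indicator_frame(ann: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    fp = ann["fp_offset"].to_numpy()
    tp = ann["tp_offset"].to_numpy()
    for k in FP_OFFSETS:
        cols[f"fp_{k}"] = fp == k
    for k in TP_OFFSETS:
        cols[f"tp_{k}"] = tp == k
    cols["nta_A"] = ann["has_nta_a"].to_numpy()
    cols["nta_U"] = ann["has_nta_u"].to_numpy()
    return pd.DataFrame(cols, index=ann.index)


PROFILE_COLUMNS = (
    [f"fp_{k}" for k in FP_OFFSETS] + [f"tp_{k}" for k in TP_OFFSETS] + ["nta_A", "nta_U"]
)


def positional_profile(
    ann: pd.DataFrame,
    group_by: str | None = None,
    cell_average: bool = True,
    min_group_reads: int = 50,
) -> pd.DataFrame:
    """Proportion mass at each 5'/3' offset in -3..+3 plus A/U-tail shares.

    With ``group_by=None`` a single aggregate row (index "all") is returned;
    ``group_by='mature'`` produces one row per mature miRNA with at least
    ``min_group_reads`` reads pooled across cells. Proportions are computed
    per cell first and averaged unweighted across cells unless
    ``cell_average`` is False (read-pooled denominators). The A/U columns use
    the at-least-one-base rule and may overlap with each other and with the
    offset columns.
    """
    if len(ann) == 0:
        raise ProcessingError("cannot profile an empty annotation frame")
    ind = _indicator_frame(ann)
    ind["cell"] = ann["cell"].to_numpy()
    if group_by is None:
        if cell_average:
            prof = ind.groupby("cell").mean().mean(axis=0).to_frame().T
        else:
            prof = ind.drop(columns="cell").mean(axis=0).to_frame().T
        prof.index = pd.Index(["all"], name="group")
        return prof[PROFILE_COLUMNS]
    if group_by != "mature":
        raise ConfigError(f"unknown group_by {group_by!r}")

    ind["mature"] = ann["mature"].to_numpy()
    pooled_n = ann.groupby("mature").size()
    keep = pooled_n[pooled_n >= min_group_reads].index
    dropped = sorted(set(pooled_n.index) - set(keep))
    if dropped:
        warnings.warn(
            f"{len(dropped)} miRNA(s) below the {min_group_reads}-read profile filter",
            stacklevel=2,
        )
    ind = ind[ind["mature"].isin(keep)]
    if cell_average:
        per = ind.groupby(["mature", "cell"]).mean()
        prof = per.groupby("mature").mean()
    else:
        prof = ind.groupby("mature").mean().drop(columns="cell", errors="ignore")
    prof.index.name = "group"
    return prof[PROFILE_COLUMNS].sort_index()


def category_proportions(ann: pd.DataFrame) -> pd.DataFrame:
    """Per cell, the fraction of miRNA-mapped reads carrying each category.

    Multi-membership means rows need not sum to 1.
    """
    ind = ann[[CATEGORY_COLUMNS[c] for c in CATEGORIES]].copy()
    ind.columns = list(CATEGORIES)
    ind["cell"] = ann["cell"].to_numpy()
    out = ind.groupby("cell").mean().sort_index()
    return out[list(CATEGORIES)]


def dedup_shift_report(
    pre: pd.DataFrame, post: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell and per-category change in proportions after deduplication.

    ``pre``/``post`` are :func:`category_proportions` outputs over the same
    cells; returns ``(per_cell_delta, mean_delta_per_category)``. A negative
    canonical mean indicates PCR preferentially amplified canonical
    molecules.
    """
    if set(pre.index) != set(post.index):
        raise ProcessingError("pre/post cell sets differ")
    post = post.reindex(pre.index)
    delta = (post - pre)[list(CATEGORIES)]
    return delta, delta.mean(axis=0)


# ---------------------------------------------------------------------------
# cell-cell similarity
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels for a k-cluster cut of the dendrogram."""
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.correlation.index, name="cluster")


def cell_similarity_clustering(m: CellCountMatrix) -> ClusteringResult:
    """Spearman correlation between all cell pairs + average-linkage tree.

    Counts are depth-normalized per cell (CPM; Spearman is rank-based, so the
    scale choice is immaterial) and correlated; cells are clustered on the
    distance 1 - rho. Cells with zero expression variance get correlation 0
    to every other cell (with a warning) so they end up isolated.
    """
    if len(m.df) < 2:
        raise ConfigError("clustering needs at least 2 cells")
    X = m.normalized("cpm").to_numpy(dtype=float)
    ranks = rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant-expression cell(s): correlations set to 0",
            stacklevel=2,
        )
        ranks = ranks.copy()
        ranks[flat] = np.arange(ranks.shape[1])  # placeholder, overwritten below
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=m.df.index, columns=m.df.index)

    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    order = [m.df.index[i] for i in sch.leaves_list(Z)]
    return ClusteringResult(correlation=corr_df, linkage=Z, leaf_order=order)
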