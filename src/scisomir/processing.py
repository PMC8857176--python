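"""Read preprocessing: UMI extraction, 3' adapter trimming, length filtering,
and UMI deduplication keyed on precursor alignments.

The stage order is fixed — UMI extraction first, then adapter removal, then
the minimum-length filter — because UMIs sit 5' of the insert while the
adapter is ligated 3' of it; :func:`process_cell` rejects any attempt to
reorder via configuration.

Adapter matching is substitution-only: every 3'-anchored alignment of the
read against a prefix of the adapter (full internal occurrence or
suffix-overlap) is scored as ``matches - errors`` and accepted when
``errors <= floor(max_error_rate * aligned_length)``; the best-scoring match
is removed together with everything 3' of it, ties broken by longest match,
then leftmost. Defaults (min_overlap=1, max_error_rate=0.1) are the common
small RNA trimming settings; note that min_overlap=1 will clip a single
terminal base equal to the adapter's first base.

Deduplication groups aligned reads by (cell, precursor, alignment start) and
collapses UMIs within each group — exact-match collapse by default, with an
optional "directional" mode that merges UMIs at Hamming distance 1 when the
larger count is >= 2x the smaller - 1 (the de-facto default of common
deduplicators). The kept representative per UMI cluster is the most frequent
read sequence, ties broken lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, ProcessingError

PIPELINE_ORDER = ("umi", "adapter", "length")
MIN_READ_LENGTH = 15


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ProcessingError(
                f"read {self.id}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class ProcessedRead:
    id: str
    sequence: str
    umi: str = ""
    cell_id: str = ""


@dataclass
class DropStats:
    """Per-cell preprocessing accounting."""

    cell: str
    n_input: int = 0
    umi_dropped: int = 0
    adapter_trimmed: int = 0
    length_dropped: int = 0
    survivors: int = 0

    def to_row(self) -> dict:
        return vars(self).copy()


# ---------------------------------------------------------------------------
# single-read operations
# ---------------------------------------------------------------------------

def extract_umi(read: RawRead, umi_length: int, cell_id: str = "") -> ProcessedRead | None:
    """Move the first ``umi_length`` bases into the UMI field.

    ``umi_length`` 0 is the identity (empty UMI). Reads not longer than the
    UMI are unusable and reported as None (the caller counts the drop).
    """
    if umi_length < 0:
        raise ConfigError("umi_length must be >= 0")
    if umi_length == 0:
        return ProcessedRead(id=read.id, sequence=read.sequence, umi="", cell_id=cell_id)
    if len(read.sequence) <= umi_length:
        return None
    return ProcessedRead(
        id=read.id,
        sequence=read.sequence[umi_length:],
        umi=read.sequence[:umi_length],
        cell_id=cell_id,
    )


def trim_adapter_seq(
    seq: str, adapter: str, min_overlap: int = 1, max_error_rate: float = 0.1
) -> tuple[str, bool]:
    """Trim the best 3' adapter occurrence from a sequence.

    Returns ``(trimmed_sequence, was_trimmed)``; no match is a valid outcome.
    """
    if not adapter:
        raise ConfigError("adapter must be non-empty")
    if min_overlap < 1:
        raise ConfigError("min_overlap must be >= 1")

    # fast path: an exact full occurrence always scores maximally, and
    # str.find is the leftmost such occurrence
    if len(adapter) >= min_overlap:
        j = seq.find(adapter)
        if j >= 0:
            return seq[:j], True

    n, m = len(seq), len(adapter)
    best_key = None
    best_i = None
    for i in range(0, n - min_overlap + 1):
        aln_len = min(m, n - i)
        if aln_len < min_overlap:
            continue
        allowed = int(max_error_rate * aln_len)
        errors = 0
        for a, b in zip(seq[i : i + aln_len], adapter):
            if a != b:
                errors += 1
                if errors > allowed:
                    break
        else:
            key = (aln_len - 2 * errors, aln_len, -i)  # score, longest, leftmost
            if best_key is None or key > best_key:
                best_key, best_i = key, i
    if best_i is None:
        return seq, False
    return seq[:best_i], True


def trim_adapter(
    read: ProcessedRead, adapter: str, min_overlap: int = 1, max_error_rate: float = 0.1
) -> tuple[ProcessedRead, bool]:
    seq, trimmed = trim_adapter_seq(read.sequence, adapter, min_overlap, max_error_rate)
    if not trimmed:
        return read, False
    return ProcessedRead(id=read.id, sequence=seq, umi=read.umi, cell_id=read.cell_id), True


def length_filter(reads, min_len: int = MIN_READ_LENGTH):
    """Keep exactly the reads with length >= ``min_len`` (order preserved).

    Accepts any iterable of ProcessedRead; returns ``(survivors, n_dropped)``.
    """
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    reads = list(reads)
    survivors = [r for r in reads if len(r.sequence) >= min_len]
    return survivors, len(reads) - len(survivors)


# ---------------------------------------------------------------------------
# per-cell pipeline
# ---------------------------------------------------------------------------

def process_cell(
    raw_reads: list[RawRead],
    cell_id: str,
    umi_length: int = 8,
    adapter: str | None = None,
    min_overlap: int = 1,
    max_error_rate: float = 0.1,
    min_len: int = MIN_READ_LENGTH,
    order: tuple[str, ...] = PIPELINE_ORDER,
) -> tuple[list[ProcessedRead], DropStats]:
    """UMI -> adapter -> length for one cell; the order is not configurable."""
    if tuple(order) != PIPELINE_ORDER:
        raise ConfigError(
            f"processing order is fixed to {PIPELINE_ORDER}, got {tuple(order)}"
        )
    stats = DropStats(cell=cell_id, n_input=len(raw_reads))
    out: list[ProcessedRead] = []
    for raw in raw_reads:
        read = extract_umi(raw, umi_length, cell_id=cell_id)
        if read is None:
            stats.umi_dropped += 1
            continue
        if adapter:
            read, trimmed = trim_adapter(read, adapter, min_overlap, max_error_rate)
            if trimmed:
                stats.adapter_trimmed += 1
        if len(read.sequence) < min_len:
            stats.length_dropped += 1
            continue
        out.append(read)
    stats.survivors = len(out)
    return out, stats


def processed_to_frame(processed: dict[str, list[ProcessedRead]]) -> pd.DataFrame:
    """Per-cell processed reads -> the frame consumed by the annotator."""
    rows = [
        (cell, r.id, r.sequence, r.umi)
        for cell in sorted(processed)
        for r in processed[cell]
    ]
    return pd.DataFrame(rows, columns=["cell", "read_id", "seq", "umi"])


# ---------------------------------------------------------------------------
# UMI deduplication
# ---------------------------------------------------------------------------

def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def _directional_clusters(counts: pd.Series) -> dict[str, str]:
    """umi -> cluster-representative umi, via directional adjacency merging.

    UMIs are visited by descending count (ties lexicographic); an unassigned
    neighbour at Hamming distance 1 is absorbed when the parent's count is
    >= 2 x child - 1, and absorption chains onward from the child.
    """
    order = sorted(counts.index, key=lambda u: (-counts[u], u))
    assign: dict[str, str] = {}
    for root in order:
        if root in assign:
            continue
        assign[root] = root
        frontier = [root]
        while frontier:
            parent = frontier.pop()
            for other in order:
                if other in assign:
                    continue
                if _hamming1(parent, other) and counts[parent] >= 2 * counts[other] - 1:
                    assign[other] = root
                    frontier.append(other)
    return assign


def dedup_umis(ann: pd.DataFrame, mode: str = "exact") -> pd.DataFrame:
    """Collapse PCR duplicates of annotated reads.

    Groups by (cell, precursor, alignment start on the precursor) — the
    precursor alignment stands in for genome coordinates as the positional
    key — then keeps one representative read per UMI cluster within each
    group. A no-op when all UMIs within every group are distinct and differ
    pairwise by more than one edit.
    """
    if mode not in ("exact", "directional"):
        raise ConfigError(f"unknown dedup mode {mode!r}")
    if len(ann) == 0:
        return ann.copy()
    empty = ann["umi"].astype(str) == ""
    if empty.any():
        offender = ann.loc[empty, "read_id"].iloc[0]
        raise ProcessingError(f"read {offender!r} has an empty UMI in UMI mode")

    df = ann
    if mode == "directional":
        cluster_ids = []
        for _, group in df.groupby(["cell", "precursor", "align_start"], sort=False):
            counts = group.groupby("umi").size()
            if len(counts) == 1:
                assign = {counts.index[0]: counts.index[0]}
            else:
                assign = _directional_clusters(counts)
            cluster_ids.append(group["umi"].map(assign))
        df = df.assign(_cluster=pd.concat(cluster_ids))
    else:
        df = df.assign(_cluster=df["umi"])

    key = ["cell", "precursor", "align_start", "_cluster"]
    # representative = most frequent sequence in the cluster, ties lexicographic
    seq_counts = (
        df.groupby(key + ["seq"], sort=False)
        .size()
        .rename("n")
        .reset_index()
        .sort_values(key + ["n", "seq"], ascending=[True] * len(key) + [False, True],
                     kind="mergesort")
    )
    winners = seq_counts.drop_duplicates(subset=key, keep="first")[key + ["seq"]]
    merged = df.merge(winners, on=key + ["seq"], how="inner")
    out = merged.drop_duplicates(subset=key, keep="first").drop(columns="_cluster")
    return out.reset_index(drop=True)
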