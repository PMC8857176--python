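"""Tolerance-bounded alignment of reads to precursor miRNAs.

Each read is matched against every annotated mature arm allowing a bounded
set of deviations from the canonical mature sequence: a 5' offset and a
templated 3' offset of up to +-3 nt (both still matching the precursor), a 3'
non-templated tail of up to 3 nt, and at most one internal substitution
(default bounds; all configurable). The templated 3' segment is maximal: a 3'
base matching the precursor's next base is always consumed as templated
before any base is assigned to the non-templated tail.

Among all valid decompositions the annotator returns the most parsimonious
one, ordered by: fewest substitutions, then shortest non-templated tail, then
smallest |5' offset| + |3' offset|, then smallest |5' offset|, then
lexicographically smallest (precursor, mature) name (determinism). When the
best score is achieved on more than one precursor the hit is flagged
ambiguous and assigned to the lexicographically first precursor; counts are
never fractionally split.

Category definitions (a read may belong to several at once):

* ``CANONICAL``       — perfect match to the mature sequence,
* ``FP_VARIANT``      — 5' offset != 0,
* ``TP_TEMPLATED``    — templated 3' offset != 0,
* ``TP_NONTEMPLATED`` — non-empty non-templated tail,
* ``SUBSTITUTION``    — exactly one internal mismatch.

Sign convention: positive 5' offset = extension upstream of the canonical
start; positive 3' offset = templated extension past the canonical end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .reference import ReferenceSet

CATEGORIES = (
    "CANONICAL",
    "FP_VARIANT",
    "TP_TEMPLATED",
    "TP_NONTEMPLATED",
    "SUBSTITUTION",
)

#: annotation-frame category indicator columns, in CATEGORIES order
CATEGORY_COLUMNS = {
    "CANONICAL": "is_canonical",
    "FP_VARIANT": "is_fp_variant",
    "TP_TEMPLATED": "is_tp_templated",
    "TP_NONTEMPLATED": "is_tp_nontemplated",
    "SUBSTITUTION": "is_substitution",
}


@dataclass(frozen=True)
class AlignmentParams:
    """Tolerance bounds: ``max_sub`` internal substitutions, ``max_trim`` nt of
    5'/3' templated offset, ``max_add`` nt of non-templated 3' tail."""

    max_sub: int = 1
    max_trim: int = 3
    max_add: int = 3

    def __post_init__(self) -> None:
        if min(self.max_sub, self.max_trim, self.max_add) < 0:
            raise ConfigError("alignment bounds must be >= 0")


@dataclass(frozen=True)
class IsomirAnnotation:
    """One read's best decomposition against its assigned mature arm."""

    mature_name: str
    precursor_name: str
    fp_offset: int
    tp_offset: int
    nta_tail: str
    substitutions: tuple[tuple[int, str, str], ...]
    read_length: int
    align_start: int
    ambiguous: bool = False
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.categories:
            object.__setattr__(self, "categories", frozenset(classify_fields(
                self.fp_offset, self.tp_offset, self.nta_tail, len(self.substitutions)
            )))


def classify_fields(fp_offset: int, tp_offset: int, nta_tail: str, n_sub: int) -> set[str]:
    cats = set()
    if fp_offset == 0 and tp_offset == 0 and not nta_tail and n_sub == 0:
        cats.add("CANONICAL")
    if fp_offset != 0:
        cats.add("FP_VARIANT")
    if tp_offset != 0:
        cats.add("TP_TEMPLATED")
    if nta_tail:
        cats.add("TP_NONTEMPLATED")
    if n_sub == 1:
        cats.add("SUBSTITUTION")
    return cats


def classify(ann: IsomirAnnotation) -> frozenset[str]:
    """Category memberships of an annotation (multi-membership allowed)."""
    return frozenset(
        classify_fields(ann.fp_offset, ann.tp_offset, ann.nta_tail, len(ann.substitutions))
    )


def tail_composition(ann: IsomirAnnotation) -> tuple[bool, bool]:
    """(has >=1 non-templated A, has >=1 non-templated U) for the tail."""
    return "A" in ann.nta_tail, "T" in ann.nta_tail


# ---------------------------------------------------------------------------
# scalar aligner
# ---------------------------------------------------------------------------

def align_read(
    read: str, ref: ReferenceSet, params: AlignmentParams = AlignmentParams()
) -> IsomirAnnotation | None:
    """Align one read; returns the best annotation or None (no hit).

    Reads containing N (or any non-ACGT character) never align. An empty
    reference is a configuration error.
    """
    arms = ref.arms_sorted()
    if not arms:
        raise ConfigError("reference contains no mature arms")
    if not read or set(read) - set("ACGT"):
        return None

    L = len(read)
    candidates: list[tuple] = []
    for arm_idx, (prec_name, prec_seq, mature, start, end) in enumerate(arms):
        plen = len(prec_seq)
        for fp in range(-params.max_trim, params.max_trim + 1):
            g_start = start - fp
            if not 0 <= g_start < plen:
                continue
            for tp in range(-params.max_trim, params.max_trim + 1):
                g_end = end + tp
                if g_end <= g_start or g_end > plen:
                    continue
                lt = g_end - g_start
                tail_len = L - lt
                if tail_len < 0 or tail_len > params.max_add:
                    continue
                window = prec_seq[g_start:g_end]
                mism = [i for i in range(lt) if read[i] != window[i]]
                if len(mism) > params.max_sub:
                    continue
                # substitutions may not sit on the first or last read base
                if mism and (mism[0] == 0 or (tail_len == 0 and mism[-1] == L - 1)):
                    continue
                # maximal templating: tail may not start with the next templated base
                if tail_len > 0 and g_end < plen and read[lt] == prec_seq[g_end]:
                    continue
                key = (
                    len(mism), tail_len, abs(fp) + abs(tp), abs(fp),
                    prec_name, mature, fp, tp,
                )
                subs = tuple((i, window[i], read[i]) for i in mism)
                candidates.append((key, g_start, subs, read[lt:]))

    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    key, g_start, subs, tail = candidates[0]
    best4, best_prec = key[:4], key[4]
    ambiguous = any(
        c[0][:4] == best4 and c[0][4] != best_prec for c in candidates[1:]
    )
    return IsomirAnnotation(
        mature_name=key[5],
        precursor_name=best_prec,
        fp_offset=key[6],
        tp_offset=key[7],
        nta_tail=tail,
        substitutions=subs,
        read_length=L,
        align_start=g_start,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# vectorized batch aligner
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_BIG = np.iinfo(np.int64).max


def _pack_rank(score4, n_arms, arm_idx, fp, tp):
    return (score4 * n_arms + arm_idx) * 64 + (fp + 3) * 8 + (tp + 3)


def annotate_frame(
    reads: pd.DataFrame,
    ref: ReferenceSet,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate a frame of processed reads (vectorized; same results as
    :func:`align_read` read-by-read).

    ``reads`` needs columns ``cell``, ``read_id``, ``seq`` (and optionally
    ``umi``). Returns ``(annotations, unmapped_stats)`` where annotations has
    one row per aligned read (schema below) and unmapped_stats counts
    ``mapped`` / ``no_hit`` / ``contains_n`` per cell.

    Annotation-frame columns: cell, read_id, seq, umi, mature, precursor,
    align_start, fp_offset, tp_offset, nta_tail, n_sub, sub_pos, sub_ref,
    sub_alt, ambiguous, read_len, plus boolean category indicators
    (``is_canonical`` ... ``has_nta_u``).
    """
    arms = ref.arms_sorted()
    if not arms:
        raise ConfigError("reference contains no mature arms")
    n_arms = len(arms)
    arm_codes = [_CODE[np.frombuffer(a[1].encode(), np.uint8)] for a in arms]
    prec_names = sorted({a[0] for a in arms})
    prec_id = {name: i for i, name in enumerate(prec_names)}

    seqs = reads["seq"].to_numpy(dtype=object)
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    best_rank = np.full(n, _BIG, dtype=np.int64)
    has_n_global = np.zeros(n, dtype=bool)
    ambig_global = np.zeros(n, dtype=bool)

    max_trim, max_add, max_sub = params.max_trim, params.max_add, params.max_sub
    for L in np.unique(lengths):
        L = int(L)
        sel = np.where(lengths == L)[0]
        if L == 0:
            continue
        blob = "".join(seqs[i] for i in sel).encode()
        mat = _CODE[np.frombuffer(blob, np.uint8)].reshape(len(sel), L)
        has_n = (mat > 3).any(axis=1)
        has_n_global[sel] = has_n

        l_rank = np.full(len(sel), _BIG, dtype=np.int64)
        l_best4 = np.full(len(sel), _BIG, dtype=np.int64)
        l_prec = np.full(len(sel), -1, dtype=np.int64)
        l_ambig = np.zeros(len(sel), dtype=bool)
        for arm_idx, (prec_name, prec_seq, _mature, start, end) in enumerate(arms):
            plen = len(prec_seq)
            codes = arm_codes[arm_idx]
            pid = prec_id[prec_name]
            for fp in range(-max_trim, max_trim + 1):
                g_start = start - fp
                if not 0 <= g_start < plen:
                    continue
                for tail_len in range(0, max_add + 1):
                    lt = L - tail_len
                    g_end = g_start + lt
                    tp = g_end - end
                    if lt < 1 or g_end > plen or abs(tp) > max_trim:
                        continue
                    win = codes[g_start:g_end]
                    diff = mat[:, :lt] != win
                    nm = diff.sum(axis=1).astype(np.int64)
                    bad = diff[:, 0] | (nm > max_sub) | has_n
                    if tail_len == 0:
                        bad |= diff[:, lt - 1]
                    elif g_end < plen:
                        bad |= mat[:, lt] == codes[g_end]
                    ok = ~bad
                    if not ok.any():
                        continue
                    score4 = ((nm * 4 + tail_len) * 8 + abs(fp) + abs(tp)) * 4 + abs(fp)
                    rank = _pack_rank(score4, n_arms, arm_idx, fp, tp)
                    l_ambig |= ok & (score4 == l_best4) & (l_prec != pid)
                    imp4 = ok & (score4 < l_best4)
                    l_best4[imp4] = score4[imp4]
                    l_prec[imp4] = pid
                    l_ambig[imp4] = False
                    imp = ok & (rank < l_rank)
                    l_rank[imp] = rank[imp]
        best_rank[sel] = l_rank
        ambig_global[sel] = l_ambig

    mapped = best_rank < _BIG
    # --- decode the winning candidates ---------------------------------
    arm_mature = np.array([a[2] for a in arms], dtype=object)
    arm_prec = np.array([a[0] for a in arms], dtype=object)
    arm_seq = [a[1] for a in arms]
    arm_start = np.array([a[3] for a in arms], dtype=np.int64)
    arm_end = np.array([a[4] for a in arms], dtype=np.int64)

    rank = best_rank[mapped]
    low = rank % 64
    fp = low // 8 - 3
    tp = low % 8 - 3
    arm_idx = (rank // 64) % n_arms
    score4 = rank // (64 * n_arms)
    n_sub = score4 // 128
    tail_len = (score4 // 32) % 4
    g_start = arm_start[arm_idx] - fp
    g_end = arm_end[arm_idx] + tp
    lt = g_end - g_start

    idx_mapped = np.where(mapped)[0]
    tails, sub_pos, sub_ref, sub_alt = [], [], [], []
    for j, i in enumerate(idx_mapped):
        seq = seqs[i]
        tails.append(seq[lt[j]:] if tail_len[j] else "")
        if n_sub[j]:
            win = arm_seq[arm_idx[j]][g_start[j]:g_end[j]]
            p = next(k for k in range(lt[j]) if seq[k] != win[k])
            sub_pos.append(p)
            sub_ref.append(win[p])
            sub_alt.append(seq[p])
        else:
            sub_pos.append(-1)
            sub_ref.append("")
            sub_alt.append("")

    ann = pd.DataFrame(
        {
            "cell": reads["cell"].to_numpy()[mapped],
            "read_id": reads["read_id"].to_numpy()[mapped],
            "seq": seqs[mapped],
            "umi": (
                reads["umi"].to_numpy()[mapped]
                if "umi" in reads.columns
                else np.full(mapped.sum(), "", dtype=object)
            ),
            "mature": arm_mature[arm_idx],
            "precursor": arm_prec[arm_idx],
            "align_start": g_start,
            "fp_offset": fp,
            "tp_offset": tp,
            "nta_tail": np.array(tails, dtype=object),
            "n_sub": n_sub,
            "sub_pos": np.array(sub_pos, dtype=np.int64),
            "sub_ref": np.array(sub_ref, dtype=object),
            "sub_alt": np.array(sub_alt, dtype=object),
            "ambiguous": ambig_global[mapped],
            "read_len": lengths[mapped],
        }
    )
    ann = add_category_columns(ann)

    stats = pd.DataFrame(
        {
            "cell": reads["cell"].to_numpy(),
            "mapped": mapped,
            "contains_n": has_n_global,
        }
    )
    unmapped = stats.groupby("cell", sort=True).agg(
        n_reads=("mapped", "size"),
        mapped=("mapped", "sum"),
        contains_n=("contains_n", "sum"),
    )
    unmapped["no_hit"] = unmapped["n_reads"] - unmapped["mapped"] - unmapped["contains_n"]
    return ann, unmapped.reset_index()


def add_category_columns(ann: pd.DataFrame) -> pd.DataFrame:
    """Derive boolean category/tail-composition columns from annotation fields."""
    ann = ann.copy()
    fp = ann["fp_offset"].to_numpy()
    tp = ann["tp_offset"].to_numpy()
    tail = ann["nta_tail"].fillna("").to_numpy(dtype=object)
    nsub = ann["n_sub"].to_numpy()
    has_tail = np.array([len(t) > 0 for t in tail])
    ann["is_canonical"] = (fp == 0) & (tp == 0) & ~has_tail & (nsub == 0)
    ann["is_fp_variant"] = fp != 0
    ann["is_tp_templated"] = tp != 0
    ann["is_tp_nontemplated"] = has_tail
    ann["is_substitution"] = nsub == 1
    ann["has_nta_a"] = np.array(["A" in t for t in tail])
    ann["has_nta_u"] = np.array(["T" in t for t in tail])
    return ann


def annotation_to_row(ann: IsomirAnnotation, cell: str, read_id: str, seq: str,
                      umi: str = "") -> dict:
    """Scalar annotation -> annotation-frame row (without category columns)."""
    sub = ann.substitutions[0] if ann.substitutions else (-1, "", "")
    return {
        "cell": cell, "read_id": read_id, "seq": seq, "umi": umi,
        "mature": ann.mature_name, "precursor": ann.precursor_name,
        "align_start": ann.align_start, "fp_offset": ann.fp_offset,
        "tp_offset": ann.tp_offset, "nta_tail": ann.nta_tail,
        "n_sub": len(ann.substitutions), "sub_pos": sub[0], "sub_ref": sub[1],
        "sub_alt": sub[2], "ambiguous": ann.ambiguous, "read_len": ann.read_length,
    }


def categories_string(row: pd.Series) -> str:
    return ";".join(c for c in CATEGORIES if row[CATEGORY_COLUMNS[c]])
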