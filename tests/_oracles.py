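"""Independent brute-force oracles used only by the test suite.

Each oracle enumerates the full search space with naive string operations and
applies the documented decision rule directly, staying deliberately separate
from the package's implementations.
"""

from __future__ import annotations


def oracle_align(read, ref, max_sub=1, max_trim=3, max_add=3):
    """Exhaustive enumeration of every (arm, 5' offset, templated end, tail)
    decomposition; returns a dict of the winning candidate or None."""
    if not read or set(read) - set("ACGT"):
        return None
    candidates = []
    for prec in ref.precursors:
        seq = prec.sequence
        for mature_name, canon_start, canon_end in prec.arms:
            for new_start in range(canon_start - max_trim, canon_start + max_trim + 1):
                for new_end in range(canon_end - max_trim, canon_end + max_trim + 1):
                    if new_start < 0 or new_end > len(seq) or new_start >= new_end:
                        continue
                    core = seq[new_start:new_end]
                    if len(core) > len(read):
                        continue
                    tail = read[len(core):]
                    if len(tail) > max_add:
                        continue
                    body = read[: len(core)]
                    mism = [i for i, (a, b) in enumerate(zip(body, core)) if a != b]
                    if len(mism) > max_sub:
                        continue
                    # substitutions must avoid the terminal read bases
                    if any(i == 0 for i in mism):
                        continue
                    if not tail and any(i == len(read) - 1 for i in mism):
                        continue
                    # maximal templating
                    if tail and new_end < len(seq) and tail[0] == seq[new_end]:
                        continue
                    fp = canon_start - new_start
                    tp = new_end - canon_end
                    key = (
                        len(mism), len(tail), abs(fp) + abs(tp), abs(fp),
                        prec.name, mature_name, fp, tp,
                    )
                    candidates.append((key, new_start, tuple(mism), tail))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    key, new_start, mism, tail = candidates[0]
    ambiguous = any(
        c[0][:4] == key[:4] and c[0][4] != key[4] for c in candidates[1:]
    )
    return {
        "precursor": key[4],
        "mature": key[5],
        "fp_offset": key[6],
        "tp_offset": key[7],
        "n_sub": len(mism),
        "sub_positions": mism,
        "nta_tail": tail,
        "align_start": new_start,
        "ambiguous": ambiguous,
    }


def oracle_trim(seq, adapter, min_overlap=1, max_error_rate=0.1):
    """Score every alignment offset of the adapter against the read's 3' side;
    returns (trimmed_seq, was_trimmed)."""
    best_key, best_i = None, None
    for i in range(len(seq)):
        aln = min(len(adapter), len(seq) - i)
        if aln < min_overlap:
            continue
        errors = sum(a != b for a, b in zip(seq[i : i + aln], adapter[:aln]))
        if errors > int(max_error_rate * aln):
            continue
        key = (aln - 2 * errors, aln, -i)
        if best_key is None or key > best_key:
            best_key, best_i = key, i
    if best_i is None:
        return seq, False
    return seq[:best_i], True


def oracle_ks_statistic(a, b):
    """Sup-distance between two empirical CDFs over the pooled sample points."""
    a, b = list(a), list(b)
    points = sorted(set(a) | set(b))
    return max(
        abs(
            sum(x <= t for x in a) / len(a) - sum(y <= t for y in b) / len(b)
        )
        for t in points
    )
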