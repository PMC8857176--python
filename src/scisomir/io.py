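"""File I/O: FASTQ, annotation TSV, count matrices, target tables, YAML config.

All tabular outputs are plain TSV and round-trip losslessly through the
readers in this module. FASTQ parsing uses Biopython's fast tuple iterator.
"""

from __future__ import annotations

from itertools import compress
from pathlib import Path

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import CATEGORIES, CATEGORY_COLUMNS, add_category_columns
from .errors import FormatError
from .processing import RawRead
from .targets import validate_target_table

ANNOTATION_COLUMNS = [
    "read_id", "cell", "seq", "umi", "mature", "precursor", "align_start",
    "fp_offset", "tp_offset", "nta_tail", "n_sub", "sub_pos", "sub_ref",
    "sub_alt", "categories", "ambiguous", "read_len",
]


def read_fastq(path) -> list[RawRead]:
    try:
        with open(path) as fh:
            return [
                RawRead(id=title.split()[0], sequence=seq.upper(), quality=qual)
                for title, seq, qual in FastqGeneralIterator(fh)
            ]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_fastq_dir(reads_dir) -> dict[str, list[RawRead]]:
    """One FASTQ per cell; the cell id is the file stem."""
    reads_dir = Path(reads_dir)
    paths = sorted(reads_dir.glob("*.fastq")) + sorted(reads_dir.glob("*.fq"))
    if not paths:
        raise FormatError(f"{reads_dir}: no .fastq/.fq files found")
    return {p.stem: read_fastq(p) for p in paths}


def write_fastq(path, reads) -> None:
    """Write (id, sequence, quality) triples or ProcessedRead-likes."""
    with open(path, "w") as fh:
        for r in reads:
            if isinstance(r, tuple):
                rid, seq, qual = r
            else:
                rid, seq, qual = r.id, r.sequence, "I" * len(r.sequence)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# -- annotation tables ------------------------------------------------------

def write_annotations(ann: pd.DataFrame, path) -> None:
    """Annotation frame -> TSV with a semicolon-joined ``categories`` column."""
    out = ann.copy()
    flags = ann[[CATEGORY_COLUMNS[c] for c in CATEGORIES]].to_numpy(dtype=bool)
    out["categories"] = [
        ";".join(compress(CATEGORIES, row)) for row in flags
    ]
    out[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"nta_tail": str, "sub_ref": str, "sub_alt": str, "umi": str},
        keep_default_na=False,
    )
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    df = df.drop(columns=["categories"])
    for col in ("align_start", "fp_offset", "tp_offset", "n_sub", "sub_pos", "read_len"):
        df[col] = df[col].astype(int)
    df["ambiguous"] = df["ambiguous"].astype(str).str.lower().isin(("true", "1"))
    return add_category_columns(df)


# -- matrices ---------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path, index_label: str = "cell") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_matrix_mtx(df: pd.DataFrame, prefix) -> None:
    """Optional MatrixMarket export: <prefix>.mtx + row/column name files."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(df.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, df.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, df.columns)) + "\n")


# -- target tables ----------------------------------------------------------

def read_target_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_target_table(df)


def write_target_table(df: pd.DataFrame, path) -> None:
    validate_target_table(df)
    df.to_csv(path, sep="\t", index=False)


# -- YAML config ------------------------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)
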