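"""Ground-truthed synthetic data for the whole pipeline.

Generates (1) a random precursor reference emulating a miRBase-style release,
(2) per-cell small-RNA FASTQ reads with a configurable isomiR mixture, UMIs,
PCR duplication and 3' adapter, and (3) an mRNA expression matrix in which
predicted-target genes carry a planted Pearson correlation with their miRNA's
per-cell abundance. Every molecule is recorded in a ground-truth table, so
each downstream stage can be checked against known truth without any
external download.

Study-condition defaults: per-cell depths in the 10^3-10^4 range typical of
single-cell small RNA-seq, a rank-skewed miRNA abundance vector dominated by
a few species, and the five-way isomiR mixture (canonical / 5' variant /
3' templated / non-templated addition / substitution).

Identifiability note: planted alterations are constructed so that each read
has a unique optimal decomposition under the annotation tolerance model
(|offset| <= 3, tail <= 3, <= 1 internal substitution). Concretely, the first
non-templated tail base is never the precursor's next templated base, and
substitutions are placed at read positions 1..len-4 — a substitution within 3
nt of the 3' end is indistinguishable from trimming-plus-tail and would make
ground-truth category proportions unrecoverable by any annotator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import DNA, random_dna, substream
from .errors import ConfigError
from .reference import Precursor, ReferenceSet

#: Illumina TruSeq small RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CATEGORY_NAMES = ("canonical", "fp_variant", "tp_templated", "nta", "substitution")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def make_reference(n_precursors: int, seed: int = 0) -> ReferenceSet:
    """Generate a random precursor reference with annotated mature arms.

    Precursor lengths fall in 60-110 nt, mature arms in 20-23 nt, and every
    arm keeps at least a 4 nt flank to the precursor ends so that templated
    5'/3' offsets of +-3 always remain within the precursor. The first
    precursor always carries both a 5p and a 3p arm (to exercise
    arm-assignment tie-breaking); the rest carry two arms with probability
    one half.

    Deterministic given ``seed``.
    """
    if n_precursors < 1:
        raise ValueError(f"n_precursors must be >= 1, got {n_precursors}")
    rng = substream(seed, "reference")
    margin = 4
    precursors = []
    for i in range(n_precursors):
        base = f"mir-{i + 1:03d}"
        two_arms = i == 0 or rng.random() < 0.5
        if two_arms:
            plen = int(rng.integers(80, 111))
            seq = random_dna(rng, plen)
            l5 = int(rng.integers(20, 24))
            l3 = int(rng.integers(20, 24))
            s5 = margin + int(rng.integers(0, 3))
            e3 = plen - margin - int(rng.integers(0, 3))
            arms = (
                (f"{base}-5p", s5, s5 + l5),
                (f"{base}-3p", e3 - l3, e3),
            )
        else:
            plen = int(rng.integers(60, 101))
            seq = random_dna(rng, plen)
            length = int(rng.integers(20, 24))
            start = int(rng.integers(margin, plen - margin - length + 1))
            arm_label = "5p" if rng.random() < 0.5 else "3p"
            arms = ((f"{base}-{arm_label}", start, start + length),)
        precursors.append(Precursor(name=f"pre-{base}", sequence=seq, arms=arms))
    ref = ReferenceSet(precursors=precursors)
    ref.validate()
    return ref


def skewed_abundance(ref: ReferenceSet, exponent: float = 1.1) -> dict[str, float]:
    """Rank-skewed (Zipf-like) abundance over all mature names: a handful of
    species dominate, as observed in real single-cell small RNA libraries."""
    names = sorted(ref.mature_index)
    w = np.array([(r + 1.0) ** -exponent for r in range(len(names))])
    w /= w.sum()
    return dict(zip(names, w))


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the read simulator.

    ``reads_per_cell`` counts molecules sampled per cell before PCR; with
    ``pcr_duplication_mean`` 1.0 it equals the emitted read count. Probability
    vectors must sum to 1 (within 1e-9). ``seed`` fixes all randomness
    end-to-end. ``pcr_canonical_bias`` scales the expected PCR copy number of
    canonical molecules (1.0 = unbiased), used to study how amplification
    bias distorts read-level category proportions.
    """

    n_cells: int = 12
    reads_per_cell: int = 3000
    mirna_abundance: dict[str, float] | None = None
    isomir_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.40,
            "fp_variant": 0.10,
            "tp_templated": 0.30,
            "nta": 0.15,
            "substitution": 0.05,
        }
    )
    fp_offset_probs: dict[int, float] = field(
        default_factory=lambda: {-1: 0.7, -2: 0.2, -3: 0.1}
    )
    tp_offset_probs: dict[int, float] = field(
        default_factory=lambda: {-1: 0.35, 1: 0.35, -2: 0.10, 2: 0.10, -3: 0.05, 3: 0.05}
    )
    nta_len_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    nta_a_fraction: float = 0.7
    pcr_duplication_mean: float = 2.0
    pcr_canonical_bias: float = 1.0
    umi_length: int = 8
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.reads_per_cell < 1:
            raise ConfigError("n_cells and reads_per_cell must be positive")
        if self.umi_length < 0:
            raise ConfigError("umi_length must be >= 0")
        if self.pcr_duplication_mean < 1:
            raise ConfigError("pcr_duplication_mean must be >= 1")
        for label, probs in [
            ("isomir_mixture", self.isomir_mixture),
            ("fp_offset_probs", self.fp_offset_probs),
            ("tp_offset_probs", self.tp_offset_probs),
            ("nta_len_probs", self.nta_len_probs),
        ]:
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{label} must sum to 1, got {total!r}")
            if any(v < 0 for v in probs.values()):
                raise ConfigError(f"{label} has negative weights")
        if set(self.isomir_mixture) - set(CATEGORY_NAMES):
            raise ConfigError(
                f"unknown mixture categories: {set(self.isomir_mixture) - set(CATEGORY_NAMES)}"
            )
        if any(k not in (-1, -2, -3) for k in self.fp_offset_probs):
            raise ConfigError("fp_offset_probs keys must lie in -3..-1")
        if any(k == 0 or abs(k) > 3 for k in self.tp_offset_probs):
            raise ConfigError("tp_offset_probs keys must lie in -3..3, excluding 0")
        if any(k not in (1, 2, 3) for k in self.nta_len_probs):
            raise ConfigError("nta_len_probs keys must lie in 1..3")
        if not 0.0 <= self.nta_a_fraction <= 1.0:
            raise ConfigError("nta_a_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


MOLECULE_COLUMNS = [
    "cell", "molecule", "mature", "category", "fp_offset", "tp_offset",
    "nta_tail", "sub_pos", "sub_ref", "sub_alt", "umi", "n_copies", "insert",
]


@dataclass
class GroundTruth:
    """Per-molecule simulation records plus the planted target map.

    ``molecules`` has one row per sampled molecule (columns
    ``MOLECULE_COLUMNS``); emitted reads are the molecules repeated by their
    PCR copy number. ``target_map`` is filled by :func:`simulate_mrna_coupled`
    as ``{mirna: (tuple_of_genes, effect_r)}``.
    """

    molecules: pd.DataFrame
    config: SimulationConfig
    reference: ReferenceSet
    target_map: dict[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)

    def n_molecules(self) -> int:
        return len(self.molecules)

    def n_reads(self) -> int:
        return int(self.molecules["n_copies"].sum())

    def to_annotation_frame(self, level: str = "reads") -> pd.DataFrame:
        """Truth in the annotation-frame schema (see :mod:`scisomir.annotate`).

        ``level='molecules'`` yields one row per molecule, ``'reads'`` repeats
        each molecule by its PCR copy count. Used to compare pipeline output
        against truth with the same profiling code on both sides.
        """
        m = self.molecules
        if level == "reads":
            m = m.loc[m.index.repeat(m["n_copies"])].reset_index(drop=True)
        elif level != "molecules":
            raise ValueError(f"level must be 'reads' or 'molecules', got {level!r}")
        prec = {name: t[0] for name, t in self.reference.mature_index.items()}
        start = {name: t[1] for name, t in self.reference.mature_index.items()}
        df = pd.DataFrame(
            {
                "cell": m["cell"].to_numpy(),
                "read_id": [f"truth:{i}" for i in range(len(m))],
                "seq": m["insert"].to_numpy(),
                "umi": m["umi"].to_numpy(),
                "mature": m["mature"].to_numpy(),
                "precursor": m["mature"].map(prec).to_numpy(),
                "align_start": (
                    m["mature"].map(start).to_numpy() - m["fp_offset"].to_numpy()
                ),
                "fp_offset": m["fp_offset"].to_numpy(),
                "tp_offset": m["tp_offset"].to_numpy(),
                "nta_tail": m["nta_tail"].to_numpy(),
                "n_sub": (m["sub_pos"].to_numpy() >= 0).astype(int),
                "sub_pos": m["sub_pos"].to_numpy(),
                "sub_ref": m["sub_ref"].to_numpy(),
                "sub_alt": m["sub_alt"].to_numpy(),
                "ambiguous": False,
                "read_len": m["insert"].str.len().to_numpy(),
            }
        )
        from .annotate import add_category_columns

        return add_category_columns(df)

    def category_proportions(self, level: str = "molecules") -> pd.DataFrame:
        """Per-cell true category proportions, recomputed from molecule records."""
        from .profiles import category_proportions

        return category_proportions(self.to_annotation_frame(level=level))


@dataclass
class SimulatedCells:
    """Reads per cell (full raw sequences: UMI + insert + adapter) and truth."""

    reads: dict[str, list[tuple[str, str]]]
    truth: GroundTruth

    def write_fastq_dir(self, out_dir) -> list[Path]:
        """One ``<cell>.fastq`` per cell (phred+33, constant quality 'I')."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for cell in sorted(self.reads):
            path = out_dir / f"{cell}.fastq"
            with open(path, "w") as fh:
                for read_id, seq in self.reads[cell]:
                    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths.append(path)
        return paths


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in DNA if b != base]
    return choices[int(rng.integers(0, 3))]


def simulate_cells(ref: ReferenceSet, cfg: SimulationConfig) -> SimulatedCells:
    """Draw molecules per cell and emit PCR-amplified reads.

    Each molecule is drawn as (mature ~ abundance, category ~ mixture,
    offsets/tail/substitution ~ the category's sub-distribution); its read is
    the modified mature sequence plus any non-templated tail, prefixed by a
    UMI (when ``umi_length`` > 0) and suffixed by the 3' adapter. Each
    molecule is emitted in ``1 + Poisson(pcr_duplication_mean - 1)`` copies.
    """
    cfg.validate()
    abundance = cfg.mirna_abundance or skewed_abundance(ref)
    unknown = set(abundance) - set(ref.mature_index)
    if unknown:
        raise KeyError(f"mirna_abundance names not in reference: {sorted(unknown)}")
    names = sorted(abundance)
    probs = np.array([abundance[n] for n in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError(f"mirna_abundance must sum to 1, got {probs.sum()!r}")

    prec_by_name = {p.name: p for p in ref.precursors}
    arm_info = {
        mat: (prec_by_name[prec].sequence, start, end)
        for mat, (prec, start, end) in ref.mature_index.items()
    }
    cats = sorted(cfg.isomir_mixture)
    cat_probs = np.array([cfg.isomir_mixture[c] for c in cats])
    fp_keys = sorted(cfg.fp_offset_probs)
    fp_p = np.array([cfg.fp_offset_probs[k] for k in fp_keys])
    tp_keys = sorted(cfg.tp_offset_probs)
    tp_p = np.array([cfg.tp_offset_probs[k] for k in tp_keys])
    nta_keys = sorted(cfg.nta_len_probs)
    nta_p = np.array([cfg.nta_len_probs[k] for k in nta_keys])

    reads: dict[str, list[tuple[str, str]]] = {}
    records: list[tuple] = []
    for c in range(cfg.n_cells):
        cell = f"cell_{c:03d}"
        rng = substream(cfg.seed, f"cells:{cell}")
        n = cfg.reads_per_cell
        mat_idx = rng.choice(len(names), size=n, p=probs)
        cat_idx = rng.choice(len(cats), size=n, p=cat_probs)
        cell_reads: list[tuple[str, str]] = []
        for m in range(n):
            mature = names[mat_idx[m]]
            category = cats[cat_idx[m]]
            prec_seq, start, end = arm_info[mature]
            fp = tp = 0
            tail = ""
            sub_pos, sub_ref, sub_alt = -1, "", ""
            if category == "fp_variant":
                fp = fp_keys[rng.choice(len(fp_keys), p=fp_p)]
            elif category == "tp_templated":
                tp = tp_keys[rng.choice(len(tp_keys), p=tp_p)]
            insert = prec_seq[start - fp : end + tp]
            if category == "nta":
                k = nta_keys[rng.choice(len(nta_keys), p=nta_p)]
                bases = [
                    "A" if rng.random() < cfg.nta_a_fraction else "T"
                    for _ in range(k)
                ]
                g_end = end + tp
                # the first tail base must be genuinely non-templated
                if g_end < len(prec_seq) and bases[0] == prec_seq[g_end]:
                    bases[0] = "T" if bases[0] == "A" else "A"
                tail = "".join(bases)
                insert = insert + tail
            elif category == "substitution":
                length = len(insert)
                sub_pos = int(rng.integers(1, length - 3))
                sub_ref = insert[sub_pos]
                sub_alt = _other_base(rng, sub_ref)
                insert = insert[:sub_pos] + sub_alt + insert[sub_pos + 1 :]
            umi = random_dna(rng, cfg.umi_length) if cfg.umi_length else ""
            mean = cfg.pcr_duplication_mean
            if category == "canonical":
                mean = 1.0 + (mean - 1.0) * cfg.pcr_canonical_bias
            n_copies = 1 + int(rng.poisson(mean - 1.0))
            records.append(
                (cell, m, mature, category, fp, tp, tail, sub_pos, sub_ref,
                 sub_alt, umi, n_copies, insert)
            )
            full = umi + insert + cfg.adapter
            for k in range(n_copies):
                cell_reads.append((f"{cell}|m{m}|c{k}", full))
        reads[cell] = cell_reads

    molecules = pd.DataFrame(records, columns=MOLECULE_COLUMNS)
    truth = GroundTruth(molecules=molecules, config=cfg, reference=ref)
    return SimulatedCells(reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# coupled mRNA simulation
# ---------------------------------------------------------------------------

TARGET_SOURCES = ("diana", "miranda", "pictar", "targetscan", "mirdb")


def simulate_mrna_coupled(
    truth: GroundTruth,
    n_genes: int,
    n_targets_per_mirna: int,
    effect_r: float,
    noise_sd: float = 0.5,
    seed: int = 0,
    mirnas: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an mRNA matrix whose planted targets correlate with miRNA load.

    For each regulated miRNA a disjoint block of ``n_targets_per_mirna`` genes
    gets latent log-expression ``z = effect_r * x_std + sqrt(1 - r^2) * eps``
    against the standardized per-cell molecule count of that miRNA, so the
    population Pearson correlation on the log scale equals ``effect_r``;
    non-target genes are independent noise. Expression is emitted as
    ``exp(log_mean + noise_sd * z)`` (lognormal, CPM-scale friendly).

    Also emits a target table naming 2-3 pseudo-algorithm sources per planted
    target (so the >=2-source aggregation filter passes), plus single-source
    decoy rows that the filter must drop. Returns ``(mrna, target_table)``
    with ``mrna`` genes x cells; fills ``truth.target_map``.
    """
    if not -1.0 < effect_r < 1.0:
        raise ValueError(f"effect_r must lie in (-1, 1), got {effect_r}")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_targets_per_mirna >= n_genes:
        raise ValueError("n_targets_per_mirna must be < n_genes")

    rng = substream(seed, "mrna")
    cells = sorted(truth.molecules["cell"].unique())
    counts = (
        truth.molecules.groupby(["cell", "mature"]).size().unstack(fill_value=0)
    ).reindex(cells, fill_value=0)
    if mirnas is None:
        mirnas = list(counts.sum().sort_values(ascending=False).index)
        max_fit = n_genes // max(n_targets_per_mirna, 1)
        mirnas = mirnas[:max_fit]
    if len(mirnas) * n_targets_per_mirna > n_genes:
        raise ValueError(
            f"{len(mirnas)} miRNAs x {n_targets_per_mirna} targets exceed {n_genes} genes"
        )
    unknown = set(mirnas) - set(counts.columns)
    if unknown:
        raise KeyError(f"miRNAs absent from ground truth: {sorted(unknown)}")

    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    z = rng.normal(size=(n_genes, len(cells)))
    table_rows: list[tuple[str, str, str, int]] = []
    truth.target_map = {}
    for i, mirna in enumerate(mirnas):
        x = counts[mirna].to_numpy(dtype=float)
        sd = x.std()
        x_std = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        block = slice(i * n_targets_per_mirna, (i + 1) * n_targets_per_mirna)
        z[block] = effect_r * x_std + np.sqrt(1.0 - effect_r**2) * z[block]
        block_genes = tuple(genes[block])
        truth.target_map[mirna] = (block_genes, effect_r)
        for gene in block_genes:
            n_sources = 2 + int(rng.integers(0, 2))
            chosen = rng.choice(len(TARGET_SOURCES), size=n_sources, replace=False)
            for s in sorted(chosen):
                table_rows.append(
                    (mirna, gene, TARGET_SOURCES[s], 1 + int(rng.integers(0, 500)))
                )
        # decoys: single-source predictions that the >=2-source filter drops
        n_decoys = min(20, n_genes - n_targets_per_mirna * len(mirnas))
        if n_decoys > 0:
            free = rng.choice(
                np.arange(n_targets_per_mirna * len(mirnas), n_genes),
                size=n_decoys,
                replace=False,
            )
            for g in sorted(free):
                table_rows.append(
                    (mirna, genes[g], TARGET_SOURCES[int(rng.integers(0, 5))],
                     1 + int(rng.integers(0, 500)))
                )

    log_mean = 5.0
    mrna = pd.DataFrame(
        np.exp(log_mean + noise_sd * z), index=genes, columns=cells
    )
    target_table = pd.DataFrame(
        table_rows, columns=["mirna", "gene", "source", "rank"]
    ).drop_duplicates(subset=["mirna", "gene", "source"])
    return mrna, target_table
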