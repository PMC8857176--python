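"""Precursor reference handling.

A reference is a set of precursor (hairpin) sequences plus the coordinates of
their annotated mature arms, mirroring the structure of a miRBase release:
each precursor carries one or two mature miRNAs (5p/3p), and every processed
read is interpreted relative to one of those mature intervals.

Coordinates are 0-based half-open on the precursor's 5'->3' strand
internally; GFF3 I/O converts to/from the 1-based inclusive convention.
Sequences are stored in DNA alphabet (ACGT); U<->T conversion happens only at
the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from ._util import dna_to_rna, rna_to_dna

MATURE_LEN_RANGE = (18, 26)
PRECURSOR_LEN_RANGE = (50, 120)


@dataclass(frozen=True)
class Precursor:
    """A precursor hairpin with its annotated mature arms.

    ``arms`` is a tuple of ``(mature_name, start, end)`` with 0-based
    half-open coordinates into ``sequence``.
    """

    name: str
    sequence: str
    arms: tuple[tuple[str, int, int], ...]

    def mature_sequence(self, mature_name: str) -> str:
        for name, start, end in self.arms:
            if name == mature_name:
                return self.sequence[start:end]
        raise KeyError(mature_name)


@dataclass
class ReferenceSet:
    """Precursor sequences plus a mature-name -> (precursor, start, end) index."""

    precursors: list[Precursor]
    mature_index: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    # remembered so files written back use the alphabet they arrived in
    source_alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.mature_index:
            self.mature_index = {
                name: (p.name, start, end)
                for p in self.precursors
                for name, start, end in p.arms
            }

    # -- access ---------------------------------------------------------
    def precursor(self, name: str) -> Precursor:
        for p in self.precursors:
            if p.name == name:
                return p
        raise KeyError(name)

    def mature_sequence(self, mature_name: str) -> str:
        prec_name, start, end = self.mature_index[mature_name]
        return self.precursor(prec_name).sequence[start:end]

    def arms_sorted(self) -> list[tuple[str, str, str, int, int]]:
        """All arms as (precursor_name, precursor_seq, mature_name, start, end),
        sorted lexicographically by (precursor, mature) for deterministic
        tie-breaking in the annotator."""
        out = []
        for p in self.precursors:
            for name, start, end in p.arms:
                out.append((p.name, p.sequence, name, start, end))
        out.sort(key=lambda a: (a[0], a[2]))
        return out

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        names: list[str] = []
        for p in self.precursors:
            names.append(p.name)
            lo, hi = PRECURSOR_LEN_RANGE
            if not lo <= len(p.sequence) <= hi:
                raise FormatError(
                    f"precursor {p.name}: length {len(p.sequence)} outside [{lo}, {hi}]"
                )
            if set(p.sequence) - set("ACGT"):
                raise FormatError(f"precursor {p.name}: non-ACGT characters")
            for name, start, end in p.arms:
                names.append(name)
                if not (0 <= start < end <= len(p.sequence)):
                    raise FormatError(
                        f"mature {name}: interval [{start}, {end}) outside "
                        f"precursor {p.name} (length {len(p.sequence)})"
                    )
                mlo, mhi = MATURE_LEN_RANGE
                if not mlo <= end - start <= mhi:
                    raise FormatError(
                        f"mature {name}: length {end - start} outside [{mlo}, {mhi}]"
                    )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate names in reference: {dupes}")

    # -- I/O ------------------------------------------------------------
    def write(self, fasta_path, gff3_path) -> None:
        write_reference(self, fasta_path, gff3_path)

    @classmethod
    def read(cls, fasta_path, gff3_path) -> "ReferenceSet":
        return read_reference(fasta_path, gff3_path)


def write_reference(ref: ReferenceSet, fasta_path, gff3_path) -> None:
    """Write precursors as FASTA and mature arms as GFF3 (1-based inclusive)."""
    records = []
    for p in ref.precursors:
        seq = p.sequence if ref.source_alphabet == "dna" else dna_to_rna(p.sequence)
        records.append(SeqRecord(Seq(seq), id=p.name, description=""))
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in ref.precursors:
            for name, start, end in p.arms:
                fh.write(
                    f"{p.name}\tscisomir\tmiRNA\t{start + 1}\t{end}\t.\t+\t.\t"
                    f"ID={name};Name={name}\n"
                )


def read_reference(fasta_path, gff3_path) -> ReferenceSet:
    """Read a precursor FASTA plus a mature-arm GFF3 into a ReferenceSet.

    GFF3 rows must have ``type`` == ``miRNA``, a seqid present in the FASTA and
    a ``Name=`` attribute; coordinates are converted from 1-based inclusive to
    0-based half-open. U is converted to T (and written back as U if the FASTA
    used RNA alphabet).
    """
    raw = {}
    had_u = False
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            had_u = True
            seq = rna_to_dna(seq)
        raw[rec.id] = seq
    if not raw:
        raise FormatError(f"{fasta_path}: no FASTA records")

    arms: dict[str, list[tuple[str, int, int]]] = {name: [] for name in raw}
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{gff3_path}:{lineno}: expected 9 columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, _strand, _phase, attrs = fields
            if ftype != "miRNA":
                continue
            if seqid not in raw:
                raise FormatError(f"{gff3_path}:{lineno}: unknown precursor {seqid!r}")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{gff3_path}:{lineno}: non-integer coordinates") from exc
            name = None
            for item in attrs.split(";"):
                if item.startswith("Name="):
                    name = item[len("Name="):]
            if not name:
                raise FormatError(f"{gff3_path}:{lineno}: missing Name= attribute")
            start, end = start1 - 1, end1  # to 0-based half-open
            if not (0 <= start < end <= len(raw[seqid])):
                raise FormatError(
                    f"{gff3_path}:{lineno}: mature {name} interval {start1}..{end1} "
                    f"outside precursor {seqid} (length {len(raw[seqid])})"
                )
            arms[seqid].append((name, start, end))

    precursors = [
        Precursor(name=n, sequence=s, arms=tuple(arms[n])) for n, s in raw.items()
    ]
    ref = ReferenceSet(
        precursors=precursors, source_alphabet="rna" if had_u else "dna"
    )
    ref.validate()
    return ref
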