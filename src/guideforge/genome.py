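"""Genome and annotation I/O.

A :class:`Genome` is a plain in-memory store of uppercase DNA keyed by
chromosome name, loadable from FASTA (via pyfaidx) or built directly from a
dict (the synthetic-genome generator does the latter).  Sequence access is
strand-aware: fetching a minus-strand interval returns the reverse
complement of the plus-strand slice.

On-disk conventions: FASTA for sequence, BED6 (0-based half-open) for
ranges, and a fixed-header TSV for result tables.  Internally everything is
1-based fully closed; the conversion happens here and only here.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

from .intervals import MINUS, UNSTRANDED, GenomeInterval, OutOfBoundsError

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide codes -> set of concrete bases matched.  A genome ``N``
#: is deliberately absent from every set: it matches nothing.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_VALID_GENOME_CHARS = set(IUPAC) | {"N"}


class GenomeError(ValueError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Uppercase DNA sequences keyed by chromosome name."""

    def __init__(self, sequences: Mapping[str, str], assembly_name: str = ""):
        if not sequences:
            raise GenomeError("a genome needs at least one sequence")
        self.assembly_name = assembly_name
        self.sequences: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = str(seq).upper()
            if not seq:
                raise GenomeError(f"empty sequence for {chrom!r}")
            bad = set(seq) - _VALID_GENOME_CHARS
            if bad:
                raise GenomeError(
                    f"non-IUPAC characters in {chrom!r}: {sorted(bad)}"
                )
            if chrom in self.sequences:
                raise GenomeError(f"duplicate chromosome name {chrom!r}")
            self.sequences[chrom] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def chrom_length(self, chrom: str) -> int:
        try:
            return len(self.sequences[chrom])
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def checksum(self) -> str:
        """md5 over (name, sequence) pairs; recorded in run logs."""
        h = hashlib.md5()
        for chrom, seq in sorted(self.sequences.items()):
            h.update(chrom.encode())
            h.update(b"\0")
            h.update(seq.encode())
        return h.hexdigest()

    def fetch(self, interval: GenomeInterval) -> str:
        """Sequence of an interval, 5'->3' on the interval's strand."""
        length = self.chrom_length(interval.chrom)
        if interval.start < 1 or interval.end > length:
            raise OutOfBoundsError(
                f"{interval} outside {interval.chrom} (length {length})"
            )
        s = self.sequences[interval.chrom][interval.start - 1 : interval.end]
        return revcomp(s) if interval.strand == MINUS else s

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def load_genome(fasta_path: str | Path, assembly_name: str | None = None) -> Genome:
    """Load a FASTA file eagerly into a :class:`Genome`."""
    fa = Fasta(str(fasta_path), rebuild=False)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return Genome(seqs, assembly_name or Path(fasta_path).stem)


def fetch(genome: Genome, interval: GenomeInterval) -> str:
    return genome.fetch(interval)


# ---------------------------------------------------------------------------
# BED6 (0-based half-open on disk <-> 1-based closed in memory)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, genome: Genome | None = None) -> list[GenomeInterval]:
    """Read BED3/BED6; validates against genome bounds when one is given."""
    out = []
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            try:
                chrom = fields[0]
                start = int(fields[1]) + 1  # 0-based -> 1-based
                end = int(fields[2])  # half-open end == closed end
                name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
                strand = fields[5] if len(fields) > 5 else "."
                strand = UNSTRANDED if strand in (".", "*") else strand
                iv = GenomeInterval(chrom, start, end, strand, name)
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if genome is not None:
                try:
                    if iv.end > genome.chrom_length(iv.chrom):
                        errors.append(
                            f"line {lineno}: {iv} beyond chromosome end"
                        )
                        continue
                except GenomeError as exc:
                    errors.append(f"line {lineno}: {exc}")
                    continue
            out.append(iv)
    if errors:
        raise GenomeError("malformed BED records:\n" + "\n".join(errors))
    return out


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            strand = "." if iv.strand == UNSTRANDED else iv.strand
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name or '.'}\t0\t{strand}\n"
            )


def read_targets_tsv(path: str | Path) -> list[GenomeInterval]:
    """Internal TSV (1-based closed): chrom, start, end, strand, name."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str},
                     keep_default_na=False)
    required = {"chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise GenomeError(f"targets TSV must have columns {sorted(required)}")
    return [
        GenomeInterval(str(row["chrom"]), int(row["start"]), int(row["end"]),
                       str(row["strand"]), str(row.get("name", "")))
        for row in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

#: Leading columns of every result table; mismatch-count and score columns
#: follow, their number depending on max_mm and the scorers configured.
RESULT_LEAD_COLUMNS = [
    "target_name", "target_range", "spacer_range", "spacer_seq",
    "pam_seq", "cut_after",
]


def result_columns(max_mm: int, score_names: Iterable[str] = ()) -> list[str]:
    cols = list(RESULT_LEAD_COLUMNS)
    cols += [f"T{m}" for m in range(max_mm + 1)]
    cols += [f"G{m}" for m in range(max_mm + 1)]
    cols += [f"off{m}" for m in range(max_mm + 1)]
    cols.append("off")
    cols += list(score_names)
    return cols


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV (the canonical machine-readable product)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format="%.10g")


_COUNT_COL = re.compile(r"^(?:[TG]\d+|off\d*|cut_after|nick_distance)$")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table back; count columns are restored as integers."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])
    missing = [c for c in RESULT_LEAD_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise GenomeError(f"result table header lacks columns {missing}")
    for col in df.columns:
        if _COUNT_COL.match(col):
            df[col] = df[col].astype("int64")
    return df
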