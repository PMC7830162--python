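"""Readers and writers for the external file formats the pipeline touches.

All coordinates are 1-based inclusive (protein-tool convention). Sequences are
uppercase strings over the 20 standard amino acids plus ``X`` (unknown residue).
FASTA ids are the first whitespace-delimited header token; the full header is
kept as the description.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)

_EC_RE = re.compile(r"^([1-9]\d*)\.([1-9]\d*)\.([1-9]\d*)\.(\d+|-)$")


class FormatError(ValueError):
    """Raised when an input file violates its pinned dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence of a predicted proteome."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"protein id must be a non-empty token, got {self.id!r}")
        bad = [(i, c) for i, c in enumerate(self.sequence, start=1) if c not in _ALPHABET_SET]
        if bad:
            pos, c = bad[0]
            raise FormatError(
                f"protein {self.id}: illegal residue {c!r} at position {pos} "
                f"(alphabet is {ALPHABET})"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignalPeptideCall:
    """Secretion verdict for one protein, from SignalP or the toy fallback.

    ``cleavage_site`` is the 1-based position of the first mature residue.
    """

    protein_id: str
    is_secreted: bool
    cleavage_site: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cleavage_site is not None:
            if not self.is_secreted:
                raise FormatError(
                    f"{self.protein_id}: cleavage_site given for a non-secreted call"
                )
            if self.cleavage_site < 2:
                raise FormatError(
                    f"{self.protein_id}: cleavage_site must be >= 2, got {self.cleavage_site}"
                )


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain annotation row (InterProScan dialect)."""

    protein_id: str
    analysis: str
    signature_id: str
    description: str
    start: int
    end: int
    evalue: Optional[float] = None
    interpro_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"{self.protein_id}/{self.signature_id}: bad coordinates "
                f"{self.start}..{self.end}"
            )


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotated gene: id, free-text function, EC numbers."""

    genome_id: str
    feature_id: str
    function_text: str
    ec_numbers: tuple[str, ...] = ()
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        for ec in self.ec_numbers:
            if not _EC_RE.match(ec):
                raise FormatError(f"feature {self.feature_id}: bad EC number {ec!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    Sequences are uppercased and ``*`` stop characters are stripped from the
    ends. Duplicate ids and residues outside the alphabet are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().strip("*")
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Signal-peptide tables

#: Column layout of SignalP 4.1 "short" output (whitespace-separated).
_SIGNALP4_NCOL = 12


def read_signalp(path: str | Path, dialect: str = "generic") -> list[SignalPeptideCall]:
    """Read a signal-peptide table.

    ``signalp4``: the 12-column SignalP 4.1 short format (name, Cmax, pos,
    Ymax, pos, Smax, pos, Smean, D, ?, Dmaxcut, Networks-used); the secretion
    decision comes from the ``?`` column and the cleavage site from the Ymax
    position column. ``generic``: TSV with protein_id, Y/N and an optional
    cleavage position.
    """
    if dialect not in ("signalp4", "generic"):
        raise ValueError(f"unknown signal-peptide dialect {dialect!r}")
    calls: list[SignalPeptideCall] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "signalp4":
                cols = line.split()
                if len(cols) < _SIGNALP4_NCOL:
                    raise FormatError(
                        f"{path}:{lineno}: expected {_SIGNALP4_NCOL} columns, got {len(cols)}"
                    )
                name, decision = cols[0], cols[9]
                if decision not in ("Y", "N"):
                    raise FormatError(
                        f"{path}:{lineno}: malformed decision token {decision!r}"
                    )
                secreted = decision == "Y"
                calls.append(
                    SignalPeptideCall(
                        protein_id=name,
                        is_secreted=secreted,
                        cleavage_site=int(cols[4]) if secreted else None,
                        score=float(cols[8]),
                    )
                )
            else:
                cols = line.split("\t")
                if len(cols) < 2:
                    raise FormatError(f"{path}:{lineno}: expected >=2 columns")
                decision = cols[1].strip()
                if decision not in ("Y", "N"):
                    raise FormatError(
                        f"{path}:{lineno}: malformed decision token {decision!r}"
                    )
                secreted = decision == "Y"
                site = None
                if secreted and len(cols) >= 3 and cols[2].strip():
                    site = int(cols[2])
                calls.append(
                    SignalPeptideCall(protein_id=cols[0], is_secreted=secreted, cleavage_site=site)
                )
    return calls


def write_signalp_generic(calls: Iterable[SignalPeptideCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in calls:
            site = str(c.cleavage_site) if c.cleavage_site is not None else ""
            fh.write(f"{c.protein_id}\t{'Y' if c.is_secreted else 'N'}\t{site}\n")


# ---------------------------------------------------------------------------
# InterProScan TSV


def read_interproscan(path: str | Path) -> list[DomainHit]:
    """Read an InterProScan TSV (>=9 tab-separated columns).

    Columns used (1-based): 1 protein accession, 4 analysis, 5 signature
    accession, 6 description, 7 start, 8 stop, 9 e-value, 12 InterPro
    accession. ``-`` maps to absent.
    """
    hits: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected >=9 columns, got {len(cols)}")
            try:
                start, end = int(cols[6]), int(cols[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > stop {end}")
            evalue = None if cols[8].strip() in ("-", "") else float(cols[8])
            interpro = None
            if len(cols) >= 12 and cols[11].strip() not in ("-", ""):
                interpro = cols[11].strip()
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    analysis=cols[3],
                    signature_id=cols[4],
                    description=cols[5],
                    start=start,
                    end=end,
                    evalue=evalue,
                    interpro_id=interpro,
                )
            )
    return hits


def write_interproscan(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write domain hits in the 12-column InterProScan TSV dialect.

    Columns 2 (MD5) and 3 (length) and 10-11 (status/date) are filled with
    ``-`` placeholders; they are not consumed by :func:`read_interproscan`.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            ev = format(h.evalue, "g") if h.evalue is not None else "-"
            ipr = h.interpro_id if h.interpro_id is not None else "-"
            fh.write(
                "\t".join(
                    [
                        h.protein_id, "-", "-", h.analysis, h.signature_id,
                        h.description, str(h.start), str(h.end), ev, "-", "-", ipr,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation feature tables

FEATURE_TABLE_HEADER = ["genome_id", "feature_id", "function_text", "ec_numbers", "protein_id"]


def read_feature_table(path: str | Path) -> list[AnnotationFeature]:
    """Read the bespoke annotation TSV (header pinned to FEATURE_TABLE_HEADER).

    EC numbers are semicolon-separated and validated; empty cells map to an
    empty list / absent protein id.
    """
    feats: list[AnnotationFeature] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
        if header != FEATURE_TABLE_HEADER:
            raise FormatError(
                f"{path}: bad header {header!r}, expected {FEATURE_TABLE_HEADER!r}"
            )
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            cols += [""] * (len(FEATURE_TABLE_HEADER) - len(cols))
            ecs = tuple(e.strip() for e in cols[3].split(";") if e.strip())
            try:
                feats.append(
                    AnnotationFeature(
                        genome_id=cols[0],
                        feature_id=cols[1],
                        function_text=cols[2],
                        ec_numbers=ecs,
                        protein_id=cols[4].strip() or None,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: {exc}") from exc
    return feats


def write_feature_table(feats: Iterable[AnnotationFeature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FEATURE_TABLE_HEADER) + "\n")
        for f in feats:
            fh.write(
                "\t".join(
                    [
                        f.genome_id,
                        f.feature_id,
                        f.function_text,
                        ";".join(f.ec_numbers),
                        f.protein_id or "",
                    ]
                )
                + "\n"
            )
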