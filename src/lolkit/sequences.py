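"""Lipobox detection and maturation-state sequence derivation.

Bacterial lipoproteins are identified by a conserved four-residue "lipobox"
motif, ``[LVI][ASTVI][GAS][C]``, whose cysteine sits at the +1 position
relative to the signal-peptide (SP) cleavage site and receives the lipid
modification.  This module scans sequences for the motif and derives the
residue content of each of the four maturation states:

* ``SP`` — unlipidated preprolipoprotein (full sequence, SP helix intact),
* ``SP_DI`` — diacylated prolipoprotein (full sequence, diacyl anchor),
* ``DI`` — apolipoprotein (SP cleaved; sequence starts at the cysteine),
* ``TRI`` — mature triacylated lipoprotein (same suffix, triacyl anchor),

plus ``UNTETHERED``, the folded core with neither protein nor lipid tether.

All residue numbering in this module is 1-based, matching PDB author
numbering so positions can be cross-referenced with structures.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STANDARD_AA",
    "LIPOBOX_PATTERN",
    "ProteinSequence",
    "LipoboxMatch",
    "MaturationState",
    "scan_lipobox",
    "select_match",
    "derive_state_sequence",
    "read_fasta",
    "write_fasta",
    "write_match_report",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Conserved lipobox motif; the final cysteine is the lipidation site.
LIPOBOX_PATTERN = re.compile(r"(?=([LVI][ASTVI][GAS]C))")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20 standard codes."""

    def __init__(self, seq_id: str, position: int, char: str):
        self.seq_id = seq_id
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"sequence {seq_id!r}: invalid residue {char!r} at position {position} "
            "(only the 20 standard one-letter codes are accepted)"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence (one-letter codes, length >= 1)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in STANDARD_AA:
                raise InvalidResidueError(self.id, i, ch)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class LipoboxMatch:
    """One lipobox occurrence.

    ``cys_position`` is the 1-based index of the conserved cysteine;
    ``sp_length`` is the number of residues N-terminal of it (the putative
    signal peptide, ``cys_position - 1``).
    """

    cys_position: int
    motif: str

    def __post_init__(self):
        if len(self.motif) != 4 or self.motif[3] != "C":
            raise ValueError(f"motif {self.motif!r} is not a 4-mer ending in C")
        if not LIPOBOX_PATTERN.match(self.motif):
            raise ValueError(f"motif {self.motif!r} does not match the lipobox pattern")
        if self.cys_position < 4:
            raise ValueError("cys_position must be >= 4 (three motif residues precede it)")

    @property
    def sp_length(self) -> int:
        return self.cys_position - 1


class MaturationState(str, Enum):
    """The four maturation stages plus the tether-free control."""

    SP = "SP"
    SP_DI = "SP_DI"
    DI = "DI"
    TRI = "TRI"
    UNTETHERED = "UNTETHERED"

    @property
    def retains_signal_peptide(self) -> bool:
        return self in (MaturationState.SP, MaturationState.SP_DI)

    @property
    def anchor(self) -> str:
        """Lipid attachment implied by the state: none | diacyl | triacyl."""
        if self in (MaturationState.SP_DI, MaturationState.DI):
            return "diacyl"
        if self is MaturationState.TRI:
            return "triacyl"
        return "none"


def scan_lipobox(seq: ProteinSequence) -> list[LipoboxMatch]:
    """Return all (possibly overlapping) lipobox matches, ordered by position.

    Every 4-residue window matching ``[LVI][ASTVI][GAS][C]`` is reported; the
    caller chooses among multiple sites (see :func:`select_match`).
    """
    matches = []
    for m in LIPOBOX_PATTERN.finditer(seq.residues):
        window = m.group(1)
        matches.append(LipoboxMatch(cys_position=m.start() + 4, motif=window))
    return matches


def select_match(matches: Iterable[LipoboxMatch]) -> LipoboxMatch:
    """Default site selection among multiple lipobox hits.

    Prefers a match whose implied signal peptide is of plausible length
    (15-40 residues); otherwise falls back to the first match.
    """
    matches = list(matches)
    if not matches:
        raise ValueError("no lipobox matches to select from")
    for m in matches:
        if 15 <= m.sp_length <= 40:
            return m
    return matches[0]


def derive_state_sequence(
    seq: ProteinSequence,
    match: LipoboxMatch,
    state: MaturationState,
    core_range: tuple[int, int] | None = None,
) -> ProteinSequence:
    """Residue content of ``seq`` in a given maturation state.

    SP and SP_DI retain the full precursor.  DI and TRI start at the lipobox
    cysteine (the SP has been cleaved by signal peptidase).  UNTETHERED
    returns the user-designated core-domain range (1-based, inclusive).
    """
    cys = match.cys_position
    if cys > len(seq) or seq[cys] != "C":
        raise ValueError(
            f"match (cys at {cys}) is inconsistent with sequence {seq.id!r}"
        )
    if state.retains_signal_peptide:
        return seq
    if state in (MaturationState.DI, MaturationState.TRI):
        return ProteinSequence(
            id=f"{seq.id}|{state.value}", residues=seq.residues[cys - 1 :]
        )
    if state is MaturationState.UNTETHERED:
        if core_range is None:
            raise ValueError("UNTETHERED requires an explicit core_range (start, end)")
        lo, hi = core_range
        if not (1 <= lo <= hi <= len(seq)):
            raise ValueError(f"core_range {core_range} outside sequence of length {len(seq)}")
        return ProteinSequence(
            id=f"{seq.id}|core", residues=seq.residues[lo - 1 : hi]
        )
    raise ValueError(f"unknown maturation state {state!r}")


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file (validates residue alphabet)."""
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_match_report(
    results: Iterable[tuple[ProteinSequence, list[LipoboxMatch]]],
    path: str | Path,
) -> None:
    """TSV report: one row per match (id, cys_position, motif, sp_length)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "cys_position", "motif", "sp_length"])
        for seq, matches in results:
            for m in matches:
                w.writerow([seq.id, m.cys_position, m.motif, m.sp_length])
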