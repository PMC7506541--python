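"""Coding-microsatellite discovery and frameshift-peptide construction.

A deletion inside a coding mononucleotide run shifts the downstream
reading frame, so the ribosome translates a novel ("neo") amino-acid
sequence from the shifted frame until it hits a stop codon.  One-base
deletions (m1) produce frame M1, two-base deletions (m2) frame M2; the
corresponding insertions (p2, p1) give the same downstream peptides up to
one extra residue at the junction, so only the deletion forms are
emitted by default.

Each peptide carries up to eight wild-type residues immediately upstream
of the first diverging codon so that epitopes spanning the wild-type /
neo-sequence junction are represented.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from .reframe import CmsLocus

WT_CONTEXT_RESIDUES = 8
#: indel sizes handled, keyed by the frame they induce
_FRAME_DELETIONS = {"M1": 1, "M2": 2}
_FRAME_INSERTIONS = {"M1": 2, "M2": 1}  # p2 / p1, behind the insertions flag


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame protein-coding DNA sequence for one gene."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        bad = re.search("[^ACGT]", self.sequence)
        if bad:
            raise ValueError(
                f"non-ACGT character {self.sequence[bad.start()]!r} at position {bad.start()} in {self.gene}"
            )

    def translate(self) -> str:
        """Standard-code translation of the longest complete-codon prefix."""
        n = len(self.sequence) - len(self.sequence) % 3
        return str(Seq(self.sequence[:n]).translate())


@dataclass(frozen=True)
class FrameshiftPeptide:
    """A frameshift neoantigen candidate.

    ``sequence`` = wild-type prefix (≤ 8 residues upstream of the first
    diverging codon) followed by the neo-sequence up to, not including,
    the first stop.  ``no_stop`` marks run-off translation (the shifted
    frame reached the end of the CDS without a stop); ``empty_neo`` marks
    an immediate stop at the divergence codon.
    """

    gene: str
    frame: str  # M1 | M2
    sequence: str
    wt_prefix: str
    neo_sequence: str
    no_stop: bool = False

    @property
    def neo_length(self) -> int:
        return len(self.neo_sequence)

    @property
    def empty_neo(self) -> bool:
        return self.neo_length == 0

    @property
    def peptide_id(self) -> str:
        return f"{self.gene}|{self.frame}"


def find_coding_microsatellites(
    cds: CodingSequence,
    min_length: int = 8,
    wt_fragment_length: int | None = None,
) -> list[CmsLocus]:
    """Locate maximal mononucleotide runs of at least ``min_length`` bases.

    Returns one :class:`CmsLocus` per qualifying run, with ``cds_offset``
    the 0-based start of the run in the coding sequence.  Loci are named
    ``gene`` (single run) or ``gene@offset``.
    """
    seq = cds.sequence
    runs = [(m.start(), m.group(0)[0], len(m.group(0))) for m in re.finditer(r"(.)\1*", seq)]
    hits = [(start, base, length) for start, base, length in runs if length >= min_length]
    loci = []
    for start, base, length in hits:
        locus_id = cds.gene if len(hits) == 1 else f"{cds.gene}@{start}"
        loci.append(
            CmsLocus(
                locus_id=locus_id,
                gene=cds.gene,
                repeat_base=base,
                repeat_length=length,
                wt_fragment_length=wt_fragment_length or len(seq),
                cds_offset=start,
            )
        )
    return loci


def _translate_codons(seq: str) -> list[str]:
    n = len(seq) - len(seq) % 3
    return [str(Seq(seq[i : i + 3]).translate()) for i in range(0, n, 3)]


def _build_peptide(cds: CodingSequence, locus: CmsLocus, frame: str, indel: int) -> FrameshiftPeptide:
    """Apply a signed indel (negative = deletion) at the 3′ end of the run."""
    if locus.cds_offset is None:
        raise ValueError(f"locus {locus.locus_id} has no cds_offset")
    start, length = locus.cds_offset, locus.repeat_length
    end = start + length
    if end > len(cds.sequence):
        raise ValueError(f"locus {locus.locus_id} extends beyond the coding sequence")
    run = cds.sequence[start:end]
    if run != locus.repeat_base * length:
        raise ValueError(
            f"coding sequence does not carry a {locus.repeat_base}×{length} run at offset {start}"
        )
    if indel < 0:
        mutant = cds.sequence[: end + indel] + cds.sequence[end:]
    else:
        mutant = cds.sequence[:end] + locus.repeat_base * indel + cds.sequence[end:]

    wt_aa = _translate_codons(cds.sequence)
    mut_aa = _translate_codons(mutant)

    # first diverging codon (amino-acid level divergence point)
    div = next(
        (i for i, (w, m) in enumerate(zip(wt_aa, mut_aa)) if w != m),
        min(len(wt_aa), len(mut_aa)),
    )

    prefix = "".join(wt_aa[max(0, div - WT_CONTEXT_RESIDUES) : div])
    neo_codons = mut_aa[div:]
    no_stop = "*" not in neo_codons
    if not no_stop:
        neo_codons = neo_codons[: neo_codons.index("*")]
    neo = "".join(neo_codons)
    return FrameshiftPeptide(
        gene=cds.gene,
        frame=frame,
        sequence=prefix + neo,
        wt_prefix=prefix,
        neo_sequence=neo,
        no_stop=no_stop,
    )


def generate_frameshift_peptides(
    cds: CodingSequence,
    locus: CmsLocus,
    insertions: bool = False,
) -> list[FrameshiftPeptide]:
    """Build the M1 (m1 deletion) and M2 (m2 deletion) frameshift peptides.

    The indel is placed at the 3′ end of the run — within a homopolymer
    the position is unobservable and every placement yields the same
    mutant sequence.  With ``insertions=True`` the p2/p1 insertion forms
    are emitted as well (frames M1/M2 respectively).
    """
    peptides = [
        _build_peptide(cds, locus, frame, -size) for frame, size in _FRAME_DELETIONS.items()
    ]
    if insertions:
        peptides += [
            _build_peptide(cds, locus, frame, size) for frame, size in _FRAME_INSERTIONS.items()
        ]
    return peptides


# ---------------------------------------------------------------------------
# FASTA round trip
# ---------------------------------------------------------------------------


def write_peptides_fasta(peptides: Sequence[FrameshiftPeptide], path: str | Path) -> None:
    """Write peptides as FASTA; headers encode gene|frame|neo_length[|flags]."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for pep in peptides:
            flags = []
            if pep.no_stop:
                flags.append("no_stop")
            header = f"{pep.gene}|{pep.frame}|{pep.neo_length}|wt={len(pep.wt_prefix)}" + (
                f"|{','.join(flags)}" if flags else ""
            )
            if header in seen:
                raise ValueError(f"duplicate peptide header {header!r}")
            seen.add(header)
            fh.write(f">{header}\n")
            for i in range(0, len(pep.sequence), 60):
                fh.write(pep.sequence[i : i + 60] + "\n")
            if not pep.sequence:
                fh.write("\n")


def read_peptides_fasta(path: str | Path) -> list[FrameshiftPeptide]:
    """Inverse of :func:`write_peptides_fasta` (round-trip identity)."""
    peptides: list[FrameshiftPeptide] = []
    header: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        if header in seen:
            raise ValueError(f"duplicate peptide header {header!r}")
        seen.add(header)
        parts = header.split("|")
        if len(parts) < 4:
            raise ValueError(f"malformed peptide header {header!r}")
        gene, frame, neo_length = parts[0], parts[1], int(parts[2])
        wt_len = int(parts[3].removeprefix("wt="))
        flags = parts[4].split(",") if len(parts) > 4 else []
        seq = "".join(chunks)
        peptides.append(
            FrameshiftPeptide(
                gene=gene,
                frame=frame,
                sequence=seq,
                wt_prefix=seq[:wt_len],
                neo_sequence=seq[wt_len:],
                no_stop="no_stop" in flags,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return peptides
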