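"""Sequence records, FASTA I/O, translation and ORF arithmetic.

Nucleotide sequences are stored uppercase over the full IUPAC DNA alphabet
(ACGT plus the ambiguity codes RYSWKMBDHVN) so that assembled metagenomic
contigs containing Ns, and degenerate primer patterns, share one
representation.  Internally all coordinates are 0-based half-open on the
forward strand; the gene-table convention (1-based inclusive, start > end
meaning reverse strand) is produced/consumed only by explicit converters at
the I/O boundary.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("swfscreen")

# --- alphabets -------------------------------------------------------------

#: expansion of each IUPAC DNA letter into the concrete bases it stands for
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: inverse map: set of bases -> the single IUPAC letter covering exactly it
IUPAC_FROM_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

IUPAC_DNA = frozenset(IUPAC_EXPANSION)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
# '-'/'.' admit aligned sequences; '*' stop; 'X' unknown
PROTEIN_ALPHABET = AMINO_ACIDS | frozenset("*X-.")

#: standard genetic code (NCBI table 1), codon -> amino acid, '*' for stop
STANDARD_CODE: dict[str, str] = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    STANDARD_CODE[_stop] = "*"


# --- record types ----------------------------------------------------------

@dataclass
class NucSequence:
    """A DNA sequence over the IUPAC alphabet, stored uppercase."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinSequence:
    """An amino-acid sequence ('*' = stop, 'X' = unknown), stored uppercase."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal protein characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OrfRecord:
    """An open reading frame in the gene-table coordinate convention.

    ``start``/``end`` are 1-based inclusive nucleotide positions on the
    forward strand; ``start > end`` marks a reverse-strand ORF.  ``aa_length``
    counts encoded amino acids excluding the stop codon, which lies inside
    the span.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    aa_length: int
    protein: ProteinSequence | None = field(default=None, repr=False)


# --- FASTA I/O -------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "dna") -> list[NucSequence] | list[ProteinSequence]:
    """Read a multi-record FASTA file.

    ``alphabet`` is ``"dna"`` or ``"protein"``.  Residues are uppercased.
    Raises ``ValueError`` on an empty file, duplicate record ids, or illegal
    characters (the error names the offending record).
    """
    path = Path(path)
    cls = NucSequence if alphabet == "dna" else ProteinSequence
    records: list = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r} (record {i})")
        seen.add(rec.id)
        try:
            records.append(cls(id=rec.id, residues=str(rec.seq), description=rec.description))
        except ValueError as exc:
            raise ValueError(f"{path}: record {i}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[NucSequence | ProteinSequence], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# --- elementary operations -------------------------------------------------

def complement_str(residues: str) -> str:
    return residues.translate(_COMPLEMENT)


def reverse_complement(seq: NucSequence) -> NucSequence:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, N<->N)."""
    return NucSequence(
        id=seq.id,
        residues=complement_str(seq.residues)[::-1],
        description=seq.description,
    )


def translate_codon(codon: str) -> str:
    """Translate one (possibly ambiguous) codon under the standard code.

    If every concrete expansion of the codon encodes the same residue, that
    residue is returned ('*' if all expansions are stops); otherwise 'X'.
    """
    try:
        products = {
            STANDARD_CODE[a + b + c]
            for a in IUPAC_EXPANSION[codon[0]]
            for b in IUPAC_EXPANSION[codon[1]]
            for c in IUPAC_EXPANSION[codon[2]]
        }
    except KeyError as exc:
        raise ValueError(f"illegal base in codon {codon!r}") from exc
    return products.pop() if len(products) == 1 else "X"


def translate(seq: NucSequence, frame: int = 1, strand: str = "+") -> ProteinSequence:
    """Translate in ``frame`` (1..3) on ``strand`` ('+'/'-'); trailing partial
    codon dropped, stops rendered '*', unresolvable ambiguity rendered 'X'."""
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1..3, got {frame}")
    residues = seq.residues if strand == "+" else complement_str(seq.residues)[::-1]
    aa = [
        translate_codon(residues[i : i + 3])
        for i in range(frame - 1, len(residues) - 2, 3)
    ]
    if not aa:
        raise ValueError(f"sequence {seq.id!r} too short to translate in frame {frame}")
    return ProteinSequence(id=seq.id, residues="".join(aa), description=f"frame={frame} strand={strand}")


def orf_aa_length(start: int, end: int) -> int:
    """Amino-acid count of an ORF given gene-table coordinates.

    ``start``/``end`` are 1-based inclusive; ``start > end`` marks a
    reverse-strand gene.  The span includes the stop codon, which is excluded
    from the count: aa = span/3 - 1.
    """
    span = abs(end - start) + 1
    if span % 3 != 0:
        raise ValueError(f"span {start}..{end} ({span} nt) not divisible by 3")
    return span // 3 - 1


def table_coords(start0: int, end0: int, strand: str) -> tuple[int, int]:
    """Convert internal 0-based half-open forward-strand coordinates to the
    gene-table convention (1-based inclusive; start>end on the reverse strand)."""
    if strand == "+":
        return start0 + 1, end0
    return end0, start0 + 1


def from_table_coords(start: int, end: int) -> tuple[int, int, str]:
    """Inverse of :func:`table_coords`: returns (start0, end0, strand)."""
    if start <= end:
        return start - 1, end, "+"
    return end - 1, start, "-"


def find_orfs(
    seq: NucSequence,
    min_aa: int,
    start_codons: Sequence[str] = ("ATG",),
) -> list[OrfRecord]:
    """Maximal start-codon-to-stop ORFs on both strands with >= min_aa residues.

    Maximal means the first start codon after the previous in-frame stop.
    Coordinates follow the gene-table convention.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    results: list[OrfRecord] = []
    L = len(seq)
    for strand in "+-":
        residues = seq.residues if strand == "+" else complement_str(seq.residues)[::-1]
        for offset in range(3):
            start_pos: int | None = None
            for i in range(offset, L - 2, 3):
                codon = residues[i : i + 3]
                if codon in STANDARD_CODE and STANDARD_CODE[codon] == "*":
                    if start_pos is not None:
                        aa_len = (i + 3 - start_pos) // 3 - 1
                        if aa_len >= min_aa:
                            results.append(
                                _make_orf(seq, residues, strand, start_pos, i + 3, L)
                            )
                        start_pos = None
                elif start_pos is None and codon in start_codons:
                    start_pos = i
    results.sort(key=lambda o: (min(o.start, o.end), o.strand))
    return results


def _make_orf(seq: NucSequence, oriented: str, strand: str, s0: int, e0: int, L: int) -> OrfRecord:
    prot = "".join(translate_codon(oriented[i : i + 3]) for i in range(s0, e0 - 3, 3))
    if strand == "+":
        start, end = table_coords(s0, e0, "+")
    else:
        # map coordinates on the reverse-complement back to the forward strand
        start, end = L - s0, L - e0 + 1
    return OrfRecord(
        contig_id=seq.id,
        start=start,
        end=end,
        strand=strand,
        aa_length=(e0 - s0) // 3 - 1,
        protein=ProteinSequence(id=f"{seq.id}|{start}-{end}", residues=prot),
    )


def write_orf_report(orfs: Iterable[OrfRecord], path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """TSV report: contig_id, start, end, strand, aa_length (table convention)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig_id\tstart\tend\tstrand\taa_length\n")
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\t{o.aa_length}\n")


def expand_iupac(pattern: str) -> Iterable[str]:
    """All concrete DNA sequences matched by an IUPAC pattern (use on short
    patterns only; the count is the pattern's degeneracy)."""
    pools = [sorted(IUPAC_EXPANSION[c]) for c in pattern]
    for combo in itertools.product(*pools):
        yield "".join(combo)
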