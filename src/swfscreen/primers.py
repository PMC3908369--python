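"""Degenerate-primer design by minimal-degeneracy reverse translation.

A conserved protein motif is converted position by position into the IUPAC
triplet whose per-position base set is the smallest cover of the bases used
by the residue's codons.  For "rectangular" residues (codon set equal to the
product of its per-position base sets — all residues except Leu, Arg and Ser)
the triplet matches exactly the residue's codons; for Leu/Arg/Ser the minimal
single-triplet cover necessarily also matches a few foreign codons.

Lowercase motif letters mark low-confidence positions and become NNN.
Reverse primers are the reverse complement of the coding-strand pattern, as
they anneal to the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .seq import (
    AMINO_ACIDS,
    IUPAC_EXPANSION,
    IUPAC_FROM_SET,
    STANDARD_CODE,
    complement_str,
)

#: residue -> tuple of codons (standard code, stops excluded)
CODONS_BY_RESIDUE: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(STANDARD_CODE.items()):
    if _aa != "*":
        CODONS_BY_RESIDUE.setdefault(_aa, ())
        CODONS_BY_RESIDUE[_aa] += (_codon,)


def _minimal_cover_triplet(residue: str) -> str:
    codons = CODONS_BY_RESIDUE[residue]
    triplet = []
    for pos in range(3):
        bases = frozenset(c[pos] for c in codons)
        triplet.append(IUPAC_FROM_SET[bases])
    return "".join(triplet)


#: residue -> minimal-cover IUPAC triplet, precomputed
MINIMAL_TRIPLET: dict[str, str] = {aa: _minimal_cover_triplet(aa) for aa in CODONS_BY_RESIDUE}


def pattern_degeneracy(pattern: str) -> int:
    """Product over positions of IUPAC expansion-set sizes."""
    d = 1
    for c in pattern:
        d *= len(IUPAC_EXPANSION[c])
    return d


def reverse_translate_motif(motif: str) -> str:
    """IUPAC DNA pattern for a protein motif; lowercase positions become NNN."""
    parts = []
    for ch in motif:
        if ch.islower():
            parts.append("NNN")
        elif ch in AMINO_ACIDS:
            parts.append(MINIMAL_TRIPLET[ch])
        else:
            raise ValueError(f"illegal residue {ch!r} in motif {motif!r}")
    if not parts:
        raise ValueError("empty motif")
    return "".join(parts)


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate primer, pattern written 5'->3'."""

    name: str
    pattern: str
    source_motif: str
    orientation: str  # "forward" | "reverse"
    degeneracy: int

    def __len__(self) -> int:
        return len(self.pattern)


def make_primer(name: str, motif: str, orientation: str) -> DegeneratePrimer:
    """Build a primer from a motif.

    Forward primers equal the reverse translation of the motif; reverse
    primers are its reverse complement (5'->3' on the template's complement).
    Degeneracy is invariant under complementation.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    pattern = reverse_translate_motif(motif)
    if orientation == "reverse":
        pattern = complement_str(pattern)[::-1]
    return DegeneratePrimer(
        name=name,
        pattern=pattern,
        source_motif=motif,
        orientation=orientation,
        degeneracy=pattern_degeneracy(pattern),
    )


# The two primer pairs used for the metagenome screens: AT1F/AT3R2 target the
# acyltransferase regions FPGQGsQW / QGEIAAA of generic type I PKS (~290 bp
# products); SWF_ATF/SWF_ATR target FSGQGTQW / QCALVEL of SwfA (~220 bp).
BUILTIN_PRIMERS: dict[str, tuple[str, str]] = {
    "AT1F": ("FPGQGsQW", "forward"),
    "AT3R2": ("QGEIAAA", "reverse"),
    "SWF_ATF": ("FSGQGTQW", "forward"),
    "SWF_ATR": ("QCALVEL", "reverse"),
}

#: named primer pairs (forward, reverse) for the two screening workflows
BUILTIN_PAIRS: dict[str, tuple[str, str]] = {
    "AT": ("AT1F", "AT3R2"),
    "SWF": ("SWF_ATF", "SWF_ATR"),
}


def builtin_primer(name: str) -> DegeneratePrimer:
    motif, orientation = BUILTIN_PRIMERS[name]
    return make_primer(name, motif, orientation)


def write_primer_tsv(primers: Iterable[DegeneratePrimer], path: str | Path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("name\tmotif\torientation\tpattern\tdegeneracy\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.source_motif}\t{p.orientation}\t{p.pattern}\t{p.degeneracy}\n")


def read_primer_tsv(path: str | Path) -> list[DegeneratePrimer]:
    primers = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("name\t") or not line.strip():
                continue
            name, motif, orientation, pattern, degeneracy = line.rstrip("\n").split("\t")
            primers.append(
                DegeneratePrimer(name, pattern, motif, orientation, int(degeneracy))
            )
    return primers
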