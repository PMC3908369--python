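"""In-silico PCR: degenerate-primer site finding and amplicon extraction.

Matching semantics: a template base matches a pattern position iff its IUPAC
expansion set is a subset of the pattern letter's expansion set, so an
ambiguous template base (e.g. N in an assembly gap) counts as a mismatch
unless the pattern is at least as ambiguous.  A site qualifies when its total
mismatches are within the limit AND its 3'-terminal clamp positions are
mismatch-free, mimicking the polymerase's requirement for a matched 3' end.

The scan is vectorized: bases are encoded as 4-bit masks and windows are
compared with ``sliding_window_view``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .primers import DegeneratePrimer
from .seq import IUPAC_EXPANSION, NucSequence, complement_str, table_coords

logger = logging.getLogger("swfscreen")

# defaults used by the screening workflows (annealing stringency is not a
# measured quantity; these pass the two in-scope product classes with margin).
# max_mismatch stays below 2 because the generic and swf AT forward patterns
# differ at exactly two constrained positions, so a 2-mismatch tolerance makes
# each primer set cross-anneal to the other's site and double-report products.
DEFAULT_MAX_MISMATCH = 1
DEFAULT_CLAMP_LEN = 3
DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 2000

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE = np.zeros(256, dtype=np.uint8)
for _letter, _bases in IUPAC_EXPANSION.items():
    _CODE[ord(_letter)] = sum(_BIT[b] for b in _bases)


def _encode(residues: str) -> np.ndarray:
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PrimerMatch:
    """A primer annealing window.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    contig.  ``strand`` '+' means the primer pattern matches the forward
    strand directly; '-' means it matches the reverse complement of the
    window (i.e. the primer anneals to the forward strand).
    """

    contig_id: str
    primer: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A primer-pair product.

    ``start``/``end`` span both primer sites, 0-based half-open on the
    forward strand of the contig; ``strand`` is the strand of the product's
    coding orientation (forward primer's strand); ``sequence`` is the product
    read 5'->3' so it always begins with the forward-primer window.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    length: int
    sequence: NucSequence
    fwd_match: PrimerMatch
    rev_match: PrimerMatch


def iupac_mismatches(pattern: str, window: str) -> int:
    """Mismatch count of a concrete/ambiguous window against an IUPAC pattern."""
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    pat = _encode(pattern)
    win = _encode(window.upper())
    return int(np.count_nonzero(win & ~pat))


def _scan(template_bits: np.ndarray, pattern: str, max_mismatch: int, clamp_len: int,
          clamp_at_end: bool) -> list[tuple[int, int]]:
    """Offsets and mismatch counts of qualifying windows of ``pattern`` on an
    encoded template.  ``clamp_at_end``: True when the primer's 3' end is the
    window's right end (pattern in primer orientation), False when reversed."""
    m = len(pattern)
    if m > len(template_bits):
        return []
    pat = _encode(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, m)
    mismatch_matrix = (windows & ~pat) != 0
    totals = mismatch_matrix.sum(axis=1)
    ok = totals <= max_mismatch
    if clamp_len > 0:
        c = min(clamp_len, m)
        clamp = mismatch_matrix[:, -c:] if clamp_at_end else mismatch_matrix[:, :c]
        ok &= ~clamp.any(axis=1)
    offsets = np.nonzero(ok)[0]
    return [(int(o), int(totals[o])) for o in offsets]


def find_primer_sites(
    contig: NucSequence,
    primer: DegeneratePrimer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    clamp_len: int = DEFAULT_CLAMP_LEN,
) -> list[PrimerMatch]:
    """All qualifying annealing windows of ``primer`` on both strands of
    ``contig``, in ascending coordinate order."""
    if max_mismatch < 0 or clamp_len < 0:
        raise ValueError("max_mismatch and clamp_len must be >= 0")
    if len(primer) > len(contig):
        logger.warning(
            "primer %s (%d nt) longer than contig %s (%d nt)",
            primer.name, len(primer), contig.id, len(contig),
        )
        return []
    bits = _encode(contig.residues)
    sites = [
        PrimerMatch(contig.id, primer.name, "+", off, off + len(primer), mm)
        for off, mm in _scan(bits, primer.pattern, max_mismatch, clamp_len, clamp_at_end=True)
    ]
    # a '-' site: the pattern matches the window's reverse complement, i.e.
    # the reverse-complemented pattern matches the forward strand; the
    # primer's 3' end then sits at the window's LEFT end.
    rc_pattern = complement_str(primer.pattern)[::-1]
    sites += [
        PrimerMatch(contig.id, primer.name, "-", off, off + len(primer), mm)
        for off, mm in _scan(bits, rc_pattern, max_mismatch, clamp_len, clamp_at_end=False)
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    contig: NucSequence,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    clamp_len: int = DEFAULT_CLAMP_LEN,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Amplicon]:
    """All products of the primer pair on either template orientation.

    A product pairs a forward-primer site with a downstream reverse-primer
    site on the opposite strand; its length runs from the 5' end of the
    forward site to the 5' end of the reverse site, inclusive.  Every
    qualifying pairing within [min_len, max_len] is reported (screening
    favours sensitivity over a shortest-product rule).
    """
    fwd_sites = find_primer_sites(contig, fwd, max_mismatch, clamp_len)
    rev_sites = find_primer_sites(contig, rev, max_mismatch, clamp_len)
    products: list[Amplicon] = []
    # '+' products: fwd anneals on '-' template => fwd pattern matches '+'
    # strand ('+' site); rev primer anneals to the '+' strand => rev pattern
    # matches the '-' strand ('-' site) downstream.
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            if r.start < f.start:
                continue
            length = r.end - f.start
            if min_len <= length <= max_len and r.start >= f.end:
                seq = NucSequence(
                    id=f"{contig.id}|{f.start + 1}-{r.end}|+",
                    residues=contig.residues[f.start : r.end],
                    description=f"amplicon {fwd.name}/{rev.name}",
                )
                products.append(
                    Amplicon(contig.id, f.start, r.end, "+", length, seq, f, r)
                )
    # '-' products: the gene sits on the reverse strand.
    for f in (s for s in fwd_sites if s.strand == "-"):
        for r in (s for s in rev_sites if s.strand == "+"):
            if f.end < r.end:
                continue
            length = f.end - r.start
            if min_len <= length <= max_len and r.end <= f.start:
                raw = contig.residues[r.start : f.end]
                seq = NucSequence(
                    id=f"{contig.id}|{r.start + 1}-{f.end}|-",
                    residues=complement_str(raw)[::-1],
                    description=f"amplicon {fwd.name}/{rev.name}",
                )
                products.append(
                    Amplicon(contig.id, r.start, f.end, "-", length, seq, f, r)
                )
    products.sort(key=lambda a: (a.start, a.end, a.strand))
    return products


def write_site_report(
    amplicons_or_sites: Sequence[Amplicon] | Sequence[PrimerMatch],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    """TSV report; coordinates in the 1-based inclusive convention."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if amplicons_or_sites and isinstance(amplicons_or_sites[0], Amplicon):
            fh.write("contig_id\tstrand\tstart\tend\tlength\tfwd_mismatches\trev_mismatches\n")
            for a in amplicons_or_sites:
                s, e = table_coords(a.start, a.end, "+")
                fh.write(
                    f"{a.contig_id}\t{a.strand}\t{s}\t{e}\t{a.length}\t"
                    f"{a.fwd_match.mismatches}\t{a.rev_match.mismatches}\n"
                )
        else:
            fh.write("contig_id\tprimer\tstrand\tstart\tend\tmismatches\n")
            for m in amplicons_or_sites:
                s, e = table_coords(m.start, m.end, "+")
                fh.write(f"{m.contig_id}\t{m.primer}\t{m.strand}\t{s}\t{e}\t{m.mismatches}\n")
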