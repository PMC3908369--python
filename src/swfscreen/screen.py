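"""Signature-motif scanning, PKS-family classification and percent identity.

The classifier separates swf-type mono-modular PKS/FAS proteins from
canonical cis-AT PKS and radical-SAM proteins using the diagnostic motif
contrasts of the swf family:

* ketosynthase DPQQR motif: the second Q is replaced by I or V in swf
  (animal-FAS-like), intact DPQQR in cis-AT PKS;
* ketosynthase HGTGT motif: changed to HATGT in swf;
* acyltransferase QCALVEL (aa ~591-597 of SwfA): unique to the swf AT
  domain, tolerating substitution of its first and last residue;
* acyltransferase IAFH (malonyl-CoA substrate) and GHSxGE (the fourth
  residue is recorded verbatim; an unusual Ser in swf) are reported as
  evidence but do not drive the family call;
* the radical-SAM cysteine triad C-x(3)-C-x(2)-C.

Percent identity between protein fragments (the quantity behind screening
claims like "64-97% identity to the SwfA homologues") comes from a global
Needleman-Wunsch alignment with linear gap costs.  Among equal-score
alignments the traceback prefers more matched columns, then more aligned
pairs (fewer columns), so the reported identity is a deterministic, total
function of the inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seq import AMINO_ACIDS, ProteinSequence

# evidence status values
ABSENT = "absent"
CANONICAL = "canonical"
SWF_VARIANT = "swf-variant"

# family labels
SWF = "swf"
CIS_AT = "cis-AT-like"
RADICAL_SAM = "radical-SAM"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MotifSpec:
    """A diagnostic motif.

    ``canonical``/``variant`` are simple amino-acid patterns: letters,
    ``[ABC]`` alternatives and ``.`` wildcards.  ``edge_tolerance`` > 0
    additionally admits, as the variant class, canonical-pattern matches with
    substitutions confined to that many leading/trailing positions.
    """

    name: str
    canonical: str
    variant: str | None = None
    edge_tolerance: int = 0
    diagnostic_for: str = ""

    def _regex(self, pattern: str) -> re.Pattern:
        return re.compile(pattern.replace(".", "[A-Z]"))

    def scan(self, protein: str) -> tuple[str, int | None, str | None]:
        """Return (status, 1-based position, matched text)."""
        m = self._regex(self.canonical).search(protein)
        if m:
            return CANONICAL, m.start() + 1, m.group()
        if self.variant is not None:
            m = self._regex(self.variant).search(protein)
            if m:
                return SWF_VARIANT, m.start() + 1, m.group()
        if self.edge_tolerance > 0:
            k = self.edge_tolerance
            core = self.canonical[k:-k]
            relaxed = "." * k + core + "." * k
            m = self._regex(relaxed).search(protein)
            if m:
                return SWF_VARIANT, m.start() + 1, m.group()
        return ABSENT, None, None


#: the default motif set used throughout the screening workflows
DEFAULT_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("KS_DPQQR", canonical="DPQQR", variant="DPQ[IV]R", diagnostic_for="KS"),
    MotifSpec("KS_HGTGT", canonical="HGTGT", variant="HATGT", diagnostic_for="KS"),
    MotifSpec("AT_QCALVEL", canonical="QCALVEL", edge_tolerance=1, diagnostic_for="AT"),
    MotifSpec("AT_IAFH", canonical="IAFH", diagnostic_for="AT"),
    MotifSpec("AT_GHSxGE", canonical="GHS.GE", diagnostic_for="AT"),
    MotifSpec("radSAM_CxxxCxxC", canonical="C...C..C", diagnostic_for="radSAM"),
)


@dataclass(frozen=True)
class MotifHit:
    status: str
    position: int | None = None
    matched: str | None = None


@dataclass
class FamilyCall:
    sequence_id: str
    evidence: Mapping[str, MotifHit]
    label: str = UNCLASSIFIED
    rationale: str = ""


def scan_motifs(
    protein: ProteinSequence,
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS,
) -> dict[str, MotifHit]:
    """Evidence map: motif name -> (status, position, matched text)."""
    return {
        spec.name: MotifHit(*spec.scan(protein.residues)) for spec in motifs
    }


def classify_family(sequence_id: str, evidence: Mapping[str, MotifHit]) -> FamilyCall:
    """Deterministic rule-table family call from a motif evidence map.

    Rules, applied in order (the unique swf AT signature wins conflicts):

    1. QCALVEL present (exact or edge-varied)            -> swf
    2. DPQ[IV]R and HATGT both present                   -> swf
    3. intact DPQQR and HGTGT present, QCALVEL absent    -> cis-AT-like
    4. Cys triad present with no KS/AT evidence          -> radical-SAM
    5. otherwise                                         -> unclassified
    """
    def status(name: str) -> str:
        hit = evidence.get(name)
        return hit.status if hit is not None else ABSENT

    qc = status("AT_QCALVEL")
    dpq = status("KS_DPQQR")
    hgtgt = status("KS_HGTGT")
    triad = status("radSAM_CxxxCxxC")
    ks_at_evidence = any(
        status(n) != ABSENT
        for n in ("KS_DPQQR", "KS_HGTGT", "AT_QCALVEL", "AT_IAFH", "AT_GHSxGE")
    )

    if qc != ABSENT:
        label, why = SWF, "rule 1: swf AT signature QCALVEL present"
    elif dpq == SWF_VARIANT and hgtgt == SWF_VARIANT:
        label, why = SWF, "rule 2: swf KS variants DPQ[IV]R and HATGT present"
    elif dpq == CANONICAL and hgtgt == CANONICAL and qc == ABSENT:
        label, why = CIS_AT, "rule 3: intact DPQQR and HGTGT, no QCALVEL"
    elif triad != ABSENT and not ks_at_evidence:
        label, why = RADICAL_SAM, "rule 4: Cys triad without KS/AT evidence"
    else:
        label, why = UNCLASSIFIED, "rule 5: no firing rule"
    return FamilyCall(sequence_id, dict(evidence), label, why)


def classify_protein(
    protein: ProteinSequence, motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS
) -> FamilyCall:
    """Convenience: scan then classify."""
    return classify_family(protein.id, scan_motifs(protein, motifs))


# --- global alignment and percent identity ---------------------------------

@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: int
    matches: int
    length: int
    percent_identity: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent_identity = 100.0 * self.matches / self.length


def global_align(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> AlignmentResult:
    """Optimal global alignment under linear-gap scoring.

    Maximizes (score, matches, aligned pairs) lexicographically, which is
    well-defined because tuple addition is monotone for lexicographic order;
    percent identity = 100 * matches / alignment columns (gaps count as
    columns).
    """
    sa = a.residues if isinstance(a, ProteinSequence) else a
    sb = b.residues if isinstance(b, ProteinSequence) else b
    if not sa or not sb:
        raise ValueError("global_align requires non-empty sequences")
    n, m = len(sa), len(sb)
    NEG = (-(1 << 30), 0, 0)
    # dp[j] = best (score, matches, pairs) for current row prefix
    dp = [(j * gap, 0, 0) for j in range(m + 1)]
    back = [[0] * (m + 1) for _ in range(n + 1)]  # 0=diag 1=up 2=left
    for j in range(1, m + 1):
        back[0][j] = 2
    for i in range(1, n + 1):
        prev_diag = dp[0]
        dp[0] = (i * gap, 0, 0)
        back[i][0] = 1
        for j in range(1, m + 1):
            is_match = sa[i - 1] == sb[j - 1]
            diag = (
                prev_diag[0] + (match if is_match else mismatch),
                prev_diag[1] + (1 if is_match else 0),
                prev_diag[2] + 1,
            )
            up = (dp[j][0] + gap, dp[j][1], dp[j][2])
            left = (dp[j - 1][0] + gap, dp[j - 1][1], dp[j - 1][2])
            best, move = diag, 0
            if up > best:
                best, move = up, 1
            if left > best:
                best, move = left, 2
            prev_diag = dp[j]
            dp[j] = best
            back[i][j] = move
    score, matches, pairs = dp[m]
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = back[i][j]
        if move == 0 and i > 0 and j > 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif move == 1 and i > 0:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return AlignmentResult(aligned_a, aligned_b, score, matches, len(aligned_a))


def percent_identity(a: ProteinSequence | str, b: ProteinSequence | str) -> float:
    return global_align(a, b).percent_identity


def write_classification_report(
    calls: Iterable[FamilyCall],
    path: str | Path,
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS,
    header_lines: Iterable[str] = (),
) -> None:
    """TSV: sequence_id, per-motif status, label, rationale."""
    names = [m.name for m in motifs]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sequence_id\t" + "\t".join(names) + "\tlabel\trationale\n")
        for call in calls:
            cols = [call.sequence_id]
            for name in names:
                hit = call.evidence.get(name, MotifHit(ABSENT))
                cols.append(
                    hit.status if hit.position is None
                    else f"{hit.status}@{hit.position}:{hit.matched}"
                )
            cols += [call.label, call.rationale]
            fh.write("\t".join(cols) + "\n")
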