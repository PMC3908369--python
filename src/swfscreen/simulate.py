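"""Synthetic metagenome generator with ground-truth manifests.

Emulates the screening substrate: contigs carrying planted PKS genes whose
encoded proteins carry configurable motif bundles, with primer-binding sites
realized at an exact requested substitution count against the degenerate
primers, decoy genes carrying the canonical (non-swf) motif variants, and a
radical-SAM decoy.  Every quantity needed to score a pipeline stage (gene
coordinates, family labels, primer-site coordinates and mismatch counts,
expected amplicon lengths) is recorded in a JSON-serializable manifest that
is re-verified against the emitted sequence on creation.

Default motif layout of a planted swf gene (1-based aa start positions):
DPQIR at 160 and HATGT at 300 (the KS domain occupies roughly the first 420
aa), FPGQGsQW at 425 and QGEIAAA at 515 (the generic AT primer pair, product
3*(515-425)+21 = 291 bp), IAFH at 480 and GHSSGE at 495, FSGQGTQW at 525 and
QCALVEL at 591 (the swf AT primer pair, 66 codons apart, product
3*66+21 = 219 bp; QCALVEL sits at aa 591-597 as in SwfA).  Decoy cis-AT
genes carry DPQQR/HGTGT and the generic primer motifs but no swf signatures;
radical-SAM decoys carry only the Cys triad.

Background residues are uniform over the 20 amino acids; back-translation
uses uniform synonymous codon choice.  Backgrounds are rejection-sampled so
no diagnostic motif occurs outside its planted position, making family
labels structural properties of the data rather than probabilistic ones.
All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pcr import iupac_mismatches
from .primers import CODONS_BY_RESIDUE, DegeneratePrimer, builtin_primer
from .seq import (
    IUPAC_EXPANSION,
    NucSequence,
    ProteinSequence,
    complement_str,
    table_coords,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# patterns that must not occur by chance anywhere in a generated protein
_DIAGNOSTIC_RE = re.compile(
    "|".join([
        "DPQ[QIV]R", "H[GA]TGT", "[A-Z]CALVE[A-Z]", "IAFH", "GHS[A-Z]GE",
        "FPGQG[A-Z]QW", "QGEIAAA", "FSGQGTQW", "C[A-Z]{3}C[A-Z]{2}C",
    ])
)

#: family -> ((motif text, 1-based aa start), ...); lowercase letters are
#: positions filled with a random residue (variable positions)
FAMILY_LAYOUTS: dict[str, tuple[tuple[str, int], ...]] = {
    "swf": (
        ("DPQIR", 160), ("HATGT", 300), ("FPGQGSQW", 425), ("IAFH", 480),
        ("GHSSGE", 495), ("QGEIAAA", 515), ("FSGQGTQW", 525), ("QCALVEL", 591),
    ),
    "cisAT_decoy": (
        ("DPQQR", 160), ("HGTGT", 300), ("FPGQGSQW", 425), ("QGEIAAA", 515),
    ),
    "radicalSAM_decoy": (
        ("CGAVCSRC", 100),
    ),
}

FAMILY_LENGTHS = {"swf": 700, "cisAT_decoy": 620, "radicalSAM_decoy": 400}

#: motif -> primer name whose binding site the motif's codons form
PRIMER_SITE_MOTIFS = {
    "FPGQGSQW": "AT1F", "QGEIAAA": "AT3R2",
    "FSGQGTQW": "SWF_ATF", "QCALVEL": "SWF_ATR",
}


@dataclass
class PlantSpec:
    """One gene to embed in a contig."""

    family: str = "swf"
    strand: str = "+"
    fwd_substitutions: int = 0
    rev_substitutions: int = 0
    motifs: tuple[tuple[str, int], ...] | None = None
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LAYOUTS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.fwd_substitutions < 0 or self.rev_substitutions < 0:
            raise ValueError("substitution counts must be >= 0")
        if self.motifs is None:
            self.motifs = FAMILY_LAYOUTS[self.family]
        if self.protein_length is None:
            self.protein_length = FAMILY_LENGTHS[self.family]
        last_end = 0
        for motif, pos in self.motifs:
            if pos <= last_end:
                raise ValueError("motif positions must be ordered and non-overlapping")
            last_end = pos + len(motif) - 1
        if last_end > self.protein_length:
            raise ValueError("motif positions exceed protein length")


def make_protein(spec: PlantSpec, seed: int, protein_id: str = "plant") -> ProteinSequence:
    """Random-background protein with the spec's motif bundle planted.

    The background is redrawn until no diagnostic motif occurs outside its
    planted window (rejection sampling; the acceptance probability is close
    to 1).  Residue 1 is always M so the gene is an ATG-start ORF.
    """
    rng = np.random.default_rng(seed)
    L = spec.protein_length
    for _ in range(1000):
        residues = list(rng.choice(list(AA20), size=L))
        residues[0] = "M"
        planted_spans = []
        for motif, pos in spec.motifs:
            for k, ch in enumerate(motif):
                residues[pos - 1 + k] = ch if not ch.islower() else rng.choice(list(AA20))
            planted_spans.append((pos - 1, pos - 1 + len(motif)))
        text = "".join(residues)
        # widen spans: a diagnostic hit is fine if it overlaps a planted window
        clean = True
        for m in _DIAGNOSTIC_RE.finditer(text):
            if not any(m.start() < e and m.end() > s for s, e in planted_spans):
                clean = False
                break
        if clean:
            return ProteinSequence(id=protein_id, residues=text)
    raise RuntimeError("failed to generate a clean background protein")


def make_swf_protein(seed: int, protein_id: str = "swf_plant",
                     spec: PlantSpec | None = None) -> ProteinSequence:
    """Convenience wrapper: a swf-family protein under the default layout."""
    return make_protein(spec or PlantSpec(family="swf"), seed, protein_id)


def _back_translate(protein: str, rng: np.random.Generator) -> list[str]:
    """Uniform random synonymous codon per residue."""
    return [
        rng.choice(CODONS_BY_RESIDUE[aa]) if aa in CODONS_BY_RESIDUE else "NNN"
        for aa in protein
    ]


def _apply_site_substitutions(
    codons: list[str], aa_start: int, motif: str, primer: DegeneratePrimer,
    n_subs: int, rng: np.random.Generator,
) -> int:
    """Mutate the primer-binding window to exactly ``n_subs`` mismatches.

    The window is the motif's codons on the coding strand.  Substituted
    positions are taken from the primer's 5' side (coding-strand left end for
    a forward primer, right end for a reverse primer) so the 3' clamp region
    stays intact; each substituted base is drawn outside the pattern's
    expansion set at that position.  Returns the realized mismatch count.
    """
    window = list("".join(codons[aa_start - 1 : aa_start - 1 + len(motif)]))
    # pattern in coding-strand orientation
    pattern = primer.pattern if primer.orientation == "forward" else (
        complement_str(primer.pattern)[::-1]
    )
    assert len(window) == len(pattern)
    order = (range(len(window)) if primer.orientation == "forward"
             else range(len(window) - 1, -1, -1))
    usable = [i for i in order if len(IUPAC_EXPANSION[pattern[i]]) < 4]
    if n_subs > len(usable):
        raise ValueError(
            f"cannot realize {n_subs} substitutions against {primer.name}: "
            f"only {len(usable)} non-N pattern positions"
        )
    for i in usable[:n_subs]:
        choices = sorted(set("ACGT") - IUPAC_EXPANSION[pattern[i]])
        window[i] = rng.choice(choices)
    for k in range(len(motif)):
        codons[aa_start - 1 + k] = "".join(window[3 * k : 3 * k + 3])
    return iupac_mismatches(pattern, "".join(window))


@dataclass
class PlantedGene:
    """Manifest entry for one planted gene (coordinates in the gene-table
    convention: 1-based inclusive, start > end on the reverse strand)."""

    gene_id: str
    family: str
    start: int
    end: int
    strand: str
    protein: str
    primer_sites: list[dict] = field(default_factory=list)
    expected_amplicons: list[dict] = field(default_factory=list)


@dataclass
class TruthManifest:
    contig_id: str
    seed: int
    genes: list[PlantedGene] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "contig_id": self.contig_id,
            "seed": self.seed,
            "genes": [
                {**vars(g)} for g in self.genes
            ],
        }


def make_contig(
    plants: Sequence[PlantSpec],
    seed: int,
    contig_id: str = "contig",
    flank_len: int = 300,
    spacer_len: int = 200,
    gc_content: float = 0.5,
) -> tuple[NucSequence, TruthManifest]:
    """Assemble one contig with the given plants and its truth manifest.

    Each plant's protein is generated, back-translated with uniform synonymous
    codons, primer-site codons adjusted to the requested substitution counts,
    a TAA stop appended, and the gene embedded on the requested strand between
    random flanks of the requested GC content.  The draw is rejected and
    retried if any screening primer finds a binding site (at the default
    stringency) outside the planted windows, so amplicon counts are exact
    structural properties of the output.  The manifest is verified against
    the emitted sequence before returning.
    """
    for attempt in range(50):
        contig, manifest = _assemble_contig(
            plants, np.random.default_rng([seed, attempt]), seed,
            contig_id, flank_len, spacer_len, gc_content,
        )
        if not _spurious_sites(contig, manifest):
            _verify_manifest(contig, manifest)
            return contig, manifest
    raise RuntimeError("could not assemble a contig free of chance primer sites")


def _spurious_sites(contig: NucSequence, manifest: TruthManifest) -> list:
    """Primer sites found at default stringency that were not planted."""
    from .pcr import find_primer_sites  # local import to avoid cycle

    # keyed by coordinates only: a cross-primer hit on a planted window (the
    # generic and swf AT patterns are two mismatches apart) is not spurious
    planted = {
        (site["start"] - 1, site["end"])
        for gene in manifest.genes
        for site in gene.primer_sites
    }
    spurious = []
    for pname in PRIMER_SITE_MOTIFS.values():
        for m in find_primer_sites(contig, builtin_primer(pname)):
            if (m.start, m.end) not in planted:
                spurious.append(m)
    return spurious


def _assemble_contig(
    plants: Sequence[PlantSpec],
    rng: np.random.Generator,
    seed: int,
    contig_id: str,
    flank_len: int,
    spacer_len: int,
    gc_content: float,
) -> tuple[NucSequence, TruthManifest]:
    manifest = TruthManifest(contig_id=contig_id, seed=seed)

    def random_dna(n: int) -> str:
        p_gc = gc_content / 2
        p_at = (1 - gc_content) / 2
        return "".join(rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at]))

    parts = [random_dna(flank_len)]
    offset = flank_len
    for gi, spec in enumerate(plants):
        gene_id = f"{contig_id}_g{gi + 1}_{spec.family}"
        protein = make_protein(spec, seed=int(rng.integers(0, 2**31 - 1)), protein_id=gene_id)
        codons = _back_translate(protein.residues, rng)
        site_records = []
        for motif, pos in spec.motifs:
            pname = PRIMER_SITE_MOTIFS.get(motif)
            if pname is None:
                continue
            primer = builtin_primer(pname)
            n_subs = (spec.fwd_substitutions if primer.orientation == "forward"
                      else spec.rev_substitutions)
            realized = _apply_site_substitutions(codons, pos, motif, primer, n_subs, rng)
            if realized != n_subs:
                raise ValueError(
                    f"{gene_id}: requested {n_subs} substitutions at {pname}, realized {realized}"
                )
            site_records.append((pname, pos, n_subs, len(motif)))
        gene_dna = "".join(codons) + "TAA"
        gene_len = len(gene_dna)
        if spec.strand == "-":
            gene_dna = complement_str(gene_dna)[::-1]
        gene_start0 = offset
        parts.append(gene_dna)
        offset += gene_len
        parts.append(random_dna(spacer_len))
        offset += spacer_len

        start, end = table_coords(gene_start0, gene_start0 + gene_len, spec.strand)
        entry = PlantedGene(
            gene_id=gene_id, family=spec.family, start=start, end=end,
            strand=spec.strand, protein=protein.residues,
        )
        # primer-site coordinates on the contig's forward strand
        for pname, pos, n_subs, motif_len in site_records:
            s_in_gene = 3 * (pos - 1)
            e_in_gene = s_in_gene + 3 * motif_len
            if spec.strand == "+":
                s0, e0 = gene_start0 + s_in_gene, gene_start0 + e_in_gene
            else:
                s0 = gene_start0 + gene_len - e_in_gene
                e0 = gene_start0 + gene_len - s_in_gene
            entry.primer_sites.append({
                "primer": pname, "start": s0 + 1, "end": e0,
                "mismatches": n_subs, "strand": spec.strand,
            })
        # expected amplicon lengths from motif spacing: 5' fwd to 5' rev
        by_name = {r[0]: r for r in site_records}
        for fwd_name, rev_name, pair in (("AT1F", "AT3R2", "AT"), ("SWF_ATF", "SWF_ATR", "SWF")):
            if fwd_name in by_name and rev_name in by_name:
                fpos = by_name[fwd_name][1]
                rpos, rlen = by_name[rev_name][1], by_name[rev_name][3]
                entry.expected_amplicons.append({
                    "pair": pair,
                    "length": 3 * (rpos - fpos) + 3 * rlen,
                })
        manifest.genes.append(entry)

    contig = NucSequence(id=contig_id, residues="".join(parts))
    return contig, manifest


def _verify_manifest(contig: NucSequence, manifest: TruthManifest) -> None:
    """Independent re-scan: every manifest entry must hold on the sequence."""
    from .seq import translate  # local import to avoid cycle at module load

    for gene in manifest.genes:
        if gene.strand == "+":
            s0, e0 = gene.start - 1, gene.end
            sub = NucSequence("check", contig.residues[s0:e0])
        else:
            s0, e0 = gene.end - 1, gene.start
            sub = NucSequence("check", complement_str(contig.residues[s0:e0])[::-1])
        prot = translate(sub, frame=1, strand="+")
        observed = prot.residues.rstrip("*")
        # primer-site substitutions may alter encoded residues; compare
        # outside the primer-site codons only
        masked = set()
        for site in gene.primer_sites:
            if site["mismatches"] == 0:
                continue
            # map contig window back to aa indices
            if gene.strand == "+":
                aa_from = (site["start"] - gene.start) // 3
            else:
                aa_from = (gene.start - site["end"]) // 3
            aa_to = aa_from + (site["end"] - site["start"] + 1) // 3
            masked.update(range(aa_from, aa_to))
        if len(observed) != len(gene.protein):
            raise AssertionError(f"{gene.gene_id}: length mismatch on re-scan")
        for i, (a, b) in enumerate(zip(observed, gene.protein)):
            if i not in masked and a != b:
                raise AssertionError(f"{gene.gene_id}: residue mismatch at aa {i + 1}")
        for site in gene.primer_sites:
            primer = builtin_primer(site["primer"])
            pattern = primer.pattern if primer.orientation == "forward" else (
                complement_str(primer.pattern)[::-1]
            )
            window = contig.residues[site["start"] - 1 : site["end"]]
            if gene.strand == "-":
                window = complement_str(window)[::-1]
            mm = iupac_mismatches(pattern, window)
            if mm != site["mismatches"]:
                raise AssertionError(
                    f"{gene.gene_id}/{site['primer']}: manifest says "
                    f"{site['mismatches']} mismatches, re-scan finds {mm}"
                )


def make_metagenome(
    n_swf: int = 4,
    n_cis_decoy: int = 8,
    n_radsam_decoy: int = 0,
    seed: int = 0,
    fwd_substitutions: int = 0,
    rev_substitutions: int = 0,
) -> tuple[list[NucSequence], list[TruthManifest]]:
    """One contig per plant, alternating strands; default 4 swf + 8 decoys
    (the composition of the original 12-amplicon screen)."""
    specs = (
        [PlantSpec("swf", "+" if i % 2 == 0 else "-", fwd_substitutions, rev_substitutions)
         for i in range(n_swf)]
        + [PlantSpec("cisAT_decoy", "+" if i % 2 == 0 else "-", fwd_substitutions, rev_substitutions)
           for i in range(n_cis_decoy)]
        + [PlantSpec("radicalSAM_decoy", "+") for _ in range(n_radsam_decoy)]
    )
    contigs, manifests = [], []
    rng = np.random.default_rng(seed)
    for i, spec in enumerate(specs):
        c, m = make_contig([spec], seed=int(rng.integers(0, 2**31 - 1)),
                           contig_id=f"ctg{i + 1:03d}")
        contigs.append(c)
        manifests.append(m)
    return contigs, manifests


def write_manifest(manifests: Sequence[TruthManifest], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_json() for m in manifests], fh, indent=1)
        fh.write("\n")


# --- alignment simulation for phylogeny tests --------------------------------

def simulate_alignment(
    tree, length: int, seed: int = 0,
) -> list[ProteinSequence]:
    """Evolve i.i.d. sites down a tree under the 20-state uniform-exchange
    model (branch lengths in expected substitutions per site).

    Along a branch of length t each site is redrawn uniformly over the 20
    residues with probability 1 - exp(-(20/19) t), so the expected p-distance
    between two leaves at path length T is 0.95 (1 - exp(-(20/19) T)),
    saturating at 0.95.
    """
    from .phylo import PhyloTree

    if length < 1:
        raise ValueError("length must be >= 1")
    root = tree.root if isinstance(tree, PhyloTree) else tree
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AA20.encode(), dtype=np.uint8)
    out: list[ProteinSequence] = []

    def evolve(node, state: np.ndarray) -> None:
        if node.is_leaf():
            out.append(ProteinSequence(id=node.name, residues=state.tobytes().decode()))
            return
        for child in node.children:
            p_redraw = 1.0 - np.exp(-(20.0 / 19.0) * child.length)
            mask = rng.random(length) < p_redraw
            child_state = state.copy()
            child_state[mask] = rng.choice(alphabet, size=int(mask.sum()))
            evolve(child, child_state)

    evolve(root, rng.choice(alphabet, size=length))
    return out
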