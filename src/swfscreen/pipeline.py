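"""End-to-end workflows chaining the pipeline stages.

``run_screen`` reproduces the metagenome screening workflow: degenerate
primers -> in-silico PCR -> translation of each amplicon in the frame
anchored by the forward primer motif -> signature-motif family
classification -> summary.  ``run_phylo`` is the distance/NJ/bootstrap
workflow and ``run_mass`` the apo/holo ACP mass-verification workflow.

Every report starts with a header echoing the tool version, the full
configuration and the seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .massspec import (
    ISOTOPE_TABLE_VERSION,
    disulfide_dimer,
    formula_subtract,
    isotope_pattern,
    match_peaks,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
    peak_mz,
    ppant_adduct,
)
from .pcr import (
    DEFAULT_CLAMP_LEN,
    DEFAULT_MAX_LEN,
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MIN_LEN,
    Amplicon,
    amplify,
    write_site_report,
)
from .phylo import (
    bootstrap_support,
    condense,
    p_distance,
    root_with_outgroup,
    write_distance_tsv,
    write_newick,
)
from .primers import BUILTIN_PAIRS, builtin_primer
from .screen import DEFAULT_MOTIFS, FamilyCall, classify_protein, write_classification_report
from .seq import NucSequence, read_fasta, translate, write_fasta

# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Workflow parameters; defaults are the module defaults."""

    primer_pairs: tuple[str, ...] = ("AT", "SWF")
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    clamp_len: int = DEFAULT_CLAMP_LEN
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    bootstrap_replicates: int = 100
    condense_cutoff: float | None = None
    outgroup: str | None = None
    poisson_correction: bool = False
    prune_threshold: float = 1e-10
    charges: tuple[int, ...] = tuple(range(1, 11))
    seed: int = 0

    def echo(self) -> list[str]:
        items = sorted(vars(self).items())
        return (
            [f"swfscreen {__version__}"]
            + [f"{k} = {v}" for k, v in items]
            + [f"isotope_table = {ISOTOPE_TABLE_VERSION}"]
        )


@dataclass
class ScreenResult:
    amplicons: list[Amplicon]
    calls: list[FamilyCall]
    family_counts: Counter = field(default_factory=Counter)
    length_counts: Counter = field(default_factory=Counter)


def _translate_amplicon(amplicon: Amplicon):
    # the product starts at the forward primer's 5' end, which is a codon
    # boundary of the source motif, so frame 1 is anchored by construction
    return translate(amplicon.sequence, frame=1, strand="+")


def screen_contigs(
    contigs: Sequence[NucSequence],
    config: RunConfig = RunConfig(),
) -> ScreenResult:
    """In-silico PCR with the configured primer pairs, then classify each
    amplicon's translation."""
    amplicons: list[Amplicon] = []
    for pair_name in config.primer_pairs:
        fwd_name, rev_name = BUILTIN_PAIRS[pair_name]
        fwd, rev = builtin_primer(fwd_name), builtin_primer(rev_name)
        for contig in contigs:
            amplicons.extend(
                amplify(contig, fwd, rev, config.max_mismatch, config.clamp_len,
                        config.min_len, config.max_len)
            )
    calls = [classify_protein(_translate_amplicon(a)) for a in amplicons]
    result = ScreenResult(amplicons=amplicons, calls=calls)
    result.family_counts = Counter(c.label for c in calls)
    result.length_counts = Counter(a.length for a in amplicons)
    return result


def run_screen(
    contig_fasta: str | Path,
    outdir: str | Path,
    config: RunConfig = RunConfig(),
) -> ScreenResult:
    """File-level screening workflow.

    Writes ``amplicons.fasta``, ``amplicons.tsv``, ``classification.tsv`` and
    ``summary.tsv`` under ``outdir``.  Input problems are reported before any
    output file is created.
    """
    contig_fasta = Path(contig_fasta)
    if not contig_fasta.exists():
        raise FileNotFoundError(f"contig FASTA not found: {contig_fasta}")
    contigs = read_fasta(contig_fasta, alphabet="dna")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = screen_contigs(contigs, config)
    header = config.echo()
    write_fasta([a.sequence for a in result.amplicons], outdir / "amplicons.fasta")
    write_site_report(result.amplicons, outdir / "amplicons.tsv", header)
    write_classification_report(result.calls, outdir / "classification.tsv",
                                DEFAULT_MOTIFS, header)
    with open(outdir / "summary.tsv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("metric\tvalue\tcount\n")
        fh.write(f"amplicons\t-\t{len(result.amplicons)}\n")
        for label in sorted(result.family_counts):
            fh.write(f"family\t{label}\t{result.family_counts[label]}\n")
        for length in sorted(result.length_counts):
            fh.write(f"amplicon_length\t{length}\t{result.length_counts[length]}\n")
    return result


def run_phylo(
    alignment_fasta: str | Path,
    outdir: str | Path,
    config: RunConfig = RunConfig(),
) -> "PhyloTree":
    """Distance matrix -> NJ -> bootstrap -> optional rooting/condensation.

    Writes ``distances.tsv``, ``tree.nwk`` and ``phylo_report.tsv``.
    """
    alignment = read_fasta(alignment_fasta, alphabet="protein")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.echo()
    dm = p_distance(alignment, config.poisson_correction)
    tree = bootstrap_support(alignment, config.bootstrap_replicates, config.seed,
                             config.poisson_correction)
    if config.outgroup is not None:
        tree = root_with_outgroup(tree, config.outgroup)
    if config.condense_cutoff is not None:
        tree = condense(tree, config.condense_cutoff)
    write_distance_tsv(dm, outdir / "distances.tsv", header)
    write_newick(tree, outdir / "tree.nwk")
    with open(outdir / "phylo_report.tsv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("key\tvalue\n")
        fh.write(f"taxa\t{len(dm.taxa)}\n")
        fh.write(f"distance_model\t{'poisson' if config.poisson_correction else 'p-distance'}\n")
        fh.write(f"bootstrap_replicates\t{config.bootstrap_replicates}\n")
        fh.write(f"bootstrap_seed\t{config.seed}\n")
        if config.outgroup is not None:
            fh.write(f"outgroup\t{config.outgroup}\n")
        if config.condense_cutoff is not None:
            fh.write(f"condense_cutoff\t{config.condense_cutoff}\n")
    return tree


def run_mass(
    apo_formula: str,
    out_path: str | Path,
    peaks: Sequence[float] = (),
    config: RunConfig = RunConfig(),
) -> dict:
    """Apo/holo proteoform report.

    Emits, for the apo formula and both phosphopantetheinylation adduct
    variants: formulas, monoisotopic and nominal masses, the adduct mass
    shifts, a charge ladder of monoisotopic and most-intense-peak m/z, the
    disulfide dimer, and (optionally) nearest-peak ppm matches for a supplied
    m/z list.  Returns the computed quantities as a dict.
    """
    apo = parse_formula(apo_formula)
    holo_rad = ppant_adduct(apo, "radical")
    holo_even = ppant_adduct(apo, "even_electron")
    dimer = disulfide_dimer(holo_rad)
    forms = {
        "apo": apo,
        "holo_radical": holo_rad,
        "holo_even_electron": holo_even,
        "holo_radical_dimer": dimer,
    }
    out: dict = {"formulas": {k: str(v) for k, v in forms.items()}}
    out["monoisotopic"] = {k: monoisotopic_mass(v) for k, v in forms.items()}
    out["nominal"] = {k: nominal_mass(v) for k, v in forms.items()}
    out["adduct_shift"] = {
        "radical": monoisotopic_mass(holo_rad) - monoisotopic_mass(apo),
        "even_electron": monoisotopic_mass(holo_even) - monoisotopic_mass(apo),
        "radical_nominal": nominal_mass(holo_rad) - nominal_mass(apo),
        "even_electron_nominal": nominal_mass(holo_even) - nominal_mass(apo),
    }
    ladder: dict[str, dict] = {}
    candidates: dict[str, float] = {}
    for name, f in forms.items():
        ladder[name] = {}
        for z in config.charges:
            mono = peak_mz(f, z, "monoisotopic", config.prune_threshold)
            top = peak_mz(f, z, "most_intense", config.prune_threshold)
            ladder[name][z] = {"monoisotopic": mono.mz, "most_intense": top.mz}
            candidates[f"{name}_z{z}_most_intense"] = top.mz
    out["charge_ladder"] = ladder
    if peaks:
        out["peak_matches"] = match_peaks(peaks, candidates)

    with open(out_path, "w") as fh:
        for line in config.echo():
            fh.write(f"# {line}\n")
        fh.write("section\tkey\tvalue\n")
        for k, v in out["formulas"].items():
            fh.write(f"formula\t{k}\t{v}\n")
        for k, v in out["monoisotopic"].items():
            fh.write(f"monoisotopic_amu\t{k}\t{v:.4f}\n")
        for k, v in out["nominal"].items():
            fh.write(f"nominal_amu\t{k}\t{v}\n")
        for k, v in out["adduct_shift"].items():
            fh.write(f"adduct_shift\t{k}\t{v:.4f}\n" if isinstance(v, float)
                     else f"adduct_shift\t{k}\t{v}\n")
        for name, per_z in ladder.items():
            for z, vals in per_z.items():
                fh.write(f"mz\t{name}_z{z}_monoisotopic\t{vals['monoisotopic']:.4f}\n")
                fh.write(f"mz\t{name}_z{z}_most_intense\t{vals['most_intense']:.4f}\n")
        for mz, name, calc, ppm in out.get("peak_matches", []):
            fh.write(f"peak_match\t{mz}\t{name}={calc:.4f} ({ppm:+.2f} ppm)\n")
    return out
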