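"""Chemical-formula arithmetic, isotope patterns and charge-state m/z.

Implements the apo/holo acyl-carrier-protein verification arithmetic: parse
element-count formulas, compute monoisotopic and nominal masses, build the
aggregated (unit-mass-binned) isotope pattern by per-element convolution,
predict the m/z of the monoisotopic or most intense isotopic peak of a
protonated z+ ion, and form the phosphopantetheinylation adducts:

* radical adduct  +C11H20N2O6PS (nominal +339), the experimentally observed
  mass shift for phosphopantetheinylation of an ACP serine;
* even-electron adduct +C11H21N2O6PS (nominal +340), phosphopantetheine in
  the neutral dihydrogenphosphate form minus one water.

For a ~10 kDa protein the most intense isotopic peak lies several unit-mass
bins above the monoisotopic one, so the two peak choices are exposed
explicitly.

Isotope masses and abundances are an embedded snapshot of the NIST/CIAAW
compilation (version string in :data:`ISOTOPE_TABLE_VERSION`, echoed in every
report).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

ISOTOPE_TABLE_VERSION = "nist-2018"

#: charge carrier: proton mass in amu (positive-mode ESI)
PROTON_MASS = 1.007276

#: element -> ((mass, abundance), ...) lightest isotope first
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177812, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088989, 0.00364)),
    "O": ((15.99491461956, 0.99757), (16.99913170, 0.00038), (17.99915961, 0.00205)),
    "P": ((30.97376163, 1.0),),
    "S": ((31.97207100, 0.9499), (32.97145876, 0.0075),
          (33.96786690, 0.0425), (35.96708076, 0.0001)),
    "Na": ((22.9897692809, 1.0),),
    "Cl": ((34.96885268, 0.7576), (36.96590259, 0.2424)),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """Immutable element-count map."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ISOTOPES:
                raise ValueError(f"unknown element {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula(merged)

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style element-count string, e.g. ``C449H704N134O140S3``
    (implicit count 1 allowed, as in the P of ``...O146PS4``)."""
    if not text or not text.strip():
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text.strip()):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ChemicalFormula(counts)


def format_formula(f: ChemicalFormula) -> str:
    """Hill order: C, H, then remaining elements alphabetically; count 1 implicit."""
    parts = []
    rest = sorted(el for el in f.counts if el not in ("C", "H"))
    for el in [e for e in ("C", "H") if e in f.counts] + rest:
        n = f.counts[el]
        parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def formula_subtract(a: ChemicalFormula, b: ChemicalFormula) -> ChemicalFormula:
    """Elementwise a - b; raises if any count would go negative."""
    out: dict[str, int] = dict(a.counts)
    for el, n in b.counts.items():
        out[el] = out.get(el, 0) - n
        if out[el] < 0:
            raise ValueError(f"negative count for {el} in subtraction")
    return ChemicalFormula(out)


def monoisotopic_mass(f: ChemicalFormula) -> float:
    """Sum of counts times lightest-isotope masses."""
    return sum(n * ISOTOPES[el][0][0] for el, n in f.counts.items())


def nominal_mass(f: ChemicalFormula) -> int:
    """Sum of counts times lightest-isotope nucleon numbers."""
    return sum(n * round(ISOTOPES[el][0][0]) for el, n in f.counts.items())


# --- isotope pattern ---------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Unit-mass-binned isotope distribution.

    ``peaks``: (neutral mass, relative abundance) with abundances normalized
    to max = 1; bin masses are abundance-weighted means of the isotopologues
    aggregated in the bin.  ``raw_total`` is the un-normalized abundance sum
    (1 minus pruning loss).
    """

    peaks: tuple[tuple[float, float], ...]
    raw_total: float

    def monoisotopic(self) -> tuple[float, float]:
        return self.peaks[0]

    def most_intense(self) -> tuple[float, float]:
        return max(self.peaks, key=lambda p: (p[1], -p[0]))


def isotope_pattern(f: ChemicalFormula, prune_threshold: float = 1e-10) -> IsotopePattern:
    """Aggregated isotope distribution by per-element convolution.

    Each element's single-atom distribution (keyed by nucleon shift above its
    lightest isotope) is raised to its count by binary exponentiation; element
    results are then convolved together.  Bins below ``prune_threshold``
    (relative abundance per convolution step) are dropped.
    """
    if not (0 < prune_threshold <= 1e-3):
        raise ValueError("prune_threshold must be in (0, 1e-3]")

    def single(el: str) -> dict[int, tuple[float, float]]:
        base_nucleons = round(ISOTOPES[el][0][0])
        d: dict[int, tuple[float, float]] = {}
        for mass, ab in ISOTOPES[el]:
            if ab > 0:
                d[round(mass) - base_nucleons] = (ab, mass)
        return d

    def conv(a: dict[int, tuple[float, float]],
             b: dict[int, tuple[float, float]]) -> dict[int, tuple[float, float]]:
        out: dict[int, list[float]] = {}
        for ka, (pa, ma) in a.items():
            for kb, (pb, mb) in b.items():
                p = pa * pb
                k = ka + kb
                cell = out.setdefault(k, [0.0, 0.0])
                cell[0] += p
                cell[1] += p * (ma + mb)
        return {
            k: (p, msum / p)
            for k, (p, msum) in out.items()
            if p >= prune_threshold
        }

    def power(d: dict[int, tuple[float, float]], n: int) -> dict[int, tuple[float, float]]:
        result = {0: (1.0, 0.0)}
        base = d
        while n > 0:
            if n & 1:
                result = conv(result, base)
            n >>= 1
            if n:
                base = conv(base, base)
        return result

    total = {0: (1.0, 0.0)}
    for el, n in sorted(f.counts.items()):
        total = conv(total, power(single(el), n))
    keys = sorted(total)
    raw_total = sum(total[k][0] for k in keys)
    max_ab = max(total[k][0] for k in keys)
    peaks = tuple((total[k][1], total[k][0] / max_ab) for k in keys)
    return IsotopePattern(peaks=peaks, raw_total=raw_total)


@dataclass(frozen=True)
class ChargeStatePeak:
    charge: int
    mz: float
    which: str
    neutral_mass: float


def peak_mz(f: ChemicalFormula, z: int, which: str = "most_intense",
            prune_threshold: float = 1e-10) -> ChargeStatePeak:
    """m/z of the requested isotopologue peak of the protonated z+ ion:
    (peak neutral mass + z * proton mass) / z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    pattern = isotope_pattern(f, prune_threshold)
    if which == "monoisotopic":
        mass, _ = pattern.monoisotopic()
    elif which == "most_intense":
        mass, _ = pattern.most_intense()
    else:
        raise ValueError(f"unknown peak choice {which!r}")
    return ChargeStatePeak(z, (mass + z * PROTON_MASS) / z, which, mass)


def ppm_error(measured: float, calculated: float) -> float:
    """Signed relative error: 1e6 * (calculated - measured) / calculated."""
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return 1e6 * (calculated - measured) / calculated


# --- phosphopantetheinylation arithmetic -------------------------------------

#: neutral fragment added on phosphopantetheinylation, radical (odd-electron)
#: form: nominal +339, as established experimentally
PPANT_RADICAL = ChemicalFormula({"C": 11, "H": 20, "N": 2, "O": 6, "P": 1, "S": 1})
#: even-electron form (phosphopantetheine - H2O): nominal +340
PPANT_EVEN_ELECTRON = ChemicalFormula({"C": 11, "H": 21, "N": 2, "O": 6, "P": 1, "S": 1})


def ppant_adduct(apo: ChemicalFormula, variant: str = "radical") -> ChemicalFormula:
    """Holo-form formula from an apo-form formula under either adduct model."""
    if variant == "radical":
        return apo + PPANT_RADICAL
    if variant == "even_electron":
        return apo + PPANT_EVEN_ELECTRON
    raise ValueError(f"unknown adduct variant {variant!r}")


def disulfide_dimer(f: ChemicalFormula) -> ChemicalFormula:
    """2f - H2: oxidative dimerization of the terminal thiol."""
    doubled = ChemicalFormula({el: 2 * n for el, n in f.counts.items()})
    return formula_subtract(doubled, ChemicalFormula({"H": 2}))


def match_peaks(
    observed: Iterable[float],
    candidates: Mapping[str, float],
) -> list[tuple[float, str, float, float]]:
    """Match observed m/z values to named calculated peaks.

    Returns (observed, best candidate name, calculated, ppm error) per
    observation, nearest candidate by |ppm|.
    """
    out = []
    for mz in observed:
        name, calc = min(candidates.items(), key=lambda kv: abs(ppm_error(mz, kv[1])))
        out.append((mz, name, calc, ppm_error(mz, calc)))
    return out
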