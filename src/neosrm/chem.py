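"""Peptide physical chemistry for SRM assay design.

Monoisotopic masses, precursor and b/y fragment m/z, Kyte-Doolittle
hydropathy (GRAVY), heavy-isotope label bookkeeping, and the
size-exclusion (SEC) mass-window gate used to decide which candidate
peptides survive the chromatographic collection step.

All masses are monoisotopic: SRM quadrupole Q1/Q3 set points target the
monoisotopic species, so average masses are never used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "AA_MONO_MASS",
    "KYTE_DOOLITTLE",
    "HEAVY_LABEL_SHIFTS",
    "isotope_label_shift",
    "Peptide",
    "FragmentIon",
    "SecWindow",
    "PeptideError",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_ions",
    "gravy",
    "sec_filter",
    "heavy_peptide",
]

#: Mass of a proton (Da); added once per charge when converting mass to m/z.
PROTON_MASS = 1.007276
#: Mass of one water molecule (Da); the condensation term of the peptide bond.
WATER_MASS = 18.010565

# Standard heavy-label shifts for fully 13C/15N-labelled lysine and
# arginine ("K+8"/"R+10"), the usual chemistry of synthetic SRM standards.
HEAVY_LABEL_SHIFTS: Mapping[str, float] = {"K": 8.014199, "R": 10.008269}

# Isotope mass differences (Da) used to derive full 13C/15N label shifts.
_C13_MINUS_C12 = 1.0033548378
_N15_MINUS_N14 = 0.9970349
# Carbon/nitrogen atom counts of each residue (side chain + backbone).
_AA_CN_COUNTS: Mapping[str, tuple[int, int]] = {
    "A": (3, 1), "R": (6, 4), "N": (4, 2), "D": (4, 1), "C": (3, 1),
    "E": (5, 1), "Q": (5, 2), "G": (2, 1), "H": (6, 3), "I": (6, 1),
    "L": (6, 1), "K": (6, 2), "M": (5, 1), "F": (9, 1), "P": (5, 1),
    "S": (3, 1), "T": (4, 1), "W": (11, 2), "Y": (9, 1), "V": (5, 1),
}


def isotope_label_shift(aa: str) -> float:
    """Mass shift (Da) of a residue with every C as 13C and every N as 15N.

    Reproduces the conventional K+8.014199 / R+10.008269 shifts and
    generalizes them to the other residues, which matters for HLA
    peptides whose C terminus is not tryptic.
    """
    if aa not in _AA_CN_COUNTS:
        raise PeptideError(f"unknown residue {aa!r}")
    n_c, n_n = _AA_CN_COUNTS[aa]
    return n_c * _C13_MINUS_C12 + n_n * _N15_MINUS_N14


def _load_table(name: str) -> dict[str, float]:
    text = resources.files("neosrm.data").joinpath(name).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    return table


#: Monoisotopic residue masses (Da), loaded from the versioned data table.
AA_MONO_MASS: Mapping[str, float] = _load_table("aa_monoisotopic.tsv")
#: Kyte-Doolittle hydropathy values per residue.
KYTE_DOOLITTLE: Mapping[str, float] = _load_table("kyte_doolittle.tsv")


class PeptideError(ValueError):
    """Invalid peptide sequence or label specification."""


@dataclass(frozen=True)
class Peptide:
    """An amino-acid sequence with an optional heavy-isotope label.

    Parameters
    ----------
    sequence:
        Upper-case string over the 20 standard one-letter codes.
    label:
        Mapping from 1-based residue position to a positive mass shift
        in Da. Empty for a light (unlabelled) peptide.
    """

    sequence: str
    label: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise PeptideError("peptide sequence must contain at least one residue")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AA_MONO_MASS:
                raise PeptideError(
                    f"unknown residue {aa!r} at position {i} in {self.sequence!r}"
                )
        for pos, shift in self.label.items():
            if not 1 <= pos <= len(self.sequence):
                raise PeptideError(
                    f"label position {pos} outside sequence of length {len(self.sequence)}"
                )
            if shift <= 0:
                raise PeptideError(f"label shift at position {pos} must be > 0 Da")
        # freeze the mapping so Peptide stays hashable-by-value in practice
        object.__setattr__(self, "label", dict(self.label))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_heavy(self) -> bool:
        return bool(self.label)


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series product ion of a peptide."""

    series: str  # "b" or "y"
    ordinal: int  # 1 .. len(peptide) - 1
    charge: int
    mz: float

    @property
    def key(self) -> str:
        """Stable identifier, e.g. ``y7^1``."""
        return f"{self.series}{self.ordinal}^{self.charge}"


@dataclass(frozen=True)
class SecWindow:
    """SEC collection window in Da.

    The collection of the peptide fraction starts after the 2000 Da
    ladder peak elutes and stops before the 800 Da peak, so only masses
    strictly inside (low_da, high_da) are retained.
    """

    low_da: float = 800.0
    high_da: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 < self.low_da < self.high_da:
            raise ValueError("SEC window requires 0 < low_da < high_da")

    def contains(self, mass_da: float) -> bool:
        return self.low_da < mass_da < self.high_da


def _as_peptide(p: Peptide | str) -> Peptide:
    return p if isinstance(p, Peptide) else Peptide(p)


def monoisotopic_mass(p: Peptide | str) -> float:
    """Monoisotopic mass in Da: residue masses + one water + label shifts."""
    p = _as_peptide(p)
    mass = sum(AA_MONO_MASS[aa] for aa in p.sequence) + WATER_MASS
    return mass + sum(p.label.values())


def precursor_mz(p: Peptide | str, z: int) -> float:
    """Precursor m/z (Th) of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"precursor charge must be >= 1, got {z}")
    return (monoisotopic_mass(p) + z * PROTON_MASS) / z


def fragment_ions(
    p: Peptide | str,
    series_set: Iterable[str] = ("b", "y"),
    product_charges: Iterable[int] = (1,),
) -> list[FragmentIon]:
    """All b/y fragment ions at the requested product charges.

    For a peptide of length n the ordinals run 1..n-1.  b_i carries the
    N-terminal i residues (plus protons); y_j the C-terminal j residues
    plus water.  Heavy-label shifts are applied to whichever fragment
    contains the labelled residue.
    """
    p = _as_peptide(p)
    series_set = tuple(series_set)
    for s in series_set:
        if s not in ("b", "y"):
            raise ValueError(f"unsupported fragment series {s!r}; only b/y")
    charges = tuple(product_charges)
    if any(z < 1 for z in charges):
        raise ValueError("product charges must be >= 1")

    n = len(p)
    residue = [AA_MONO_MASS[aa] for aa in p.sequence]
    for pos, shift in p.label.items():
        residue[pos - 1] += shift

    prefix = [0.0]
    for m in residue:
        prefix.append(prefix[-1] + m)
    total = prefix[n]

    ions: list[FragmentIon] = []
    for series in series_set:
        for ordinal in range(1, n):
            if series == "b":
                neutral = prefix[ordinal]
            else:  # y: C-terminal `ordinal` residues + water
                neutral = total - prefix[n - ordinal] + WATER_MASS
            for z in charges:
                ions.append(
                    FragmentIon(series, ordinal, z, (neutral + z * PROTON_MASS) / z)
                )
    return ions


def gravy(p: Peptide | str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    p = _as_peptide(p)
    return sum(KYTE_DOOLITTLE[aa] for aa in p.sequence) / len(p)


def sec_filter(
    peptides: Iterable[Peptide | str], window: SecWindow | None = None
) -> list[Peptide]:
    """Peptides whose monoisotopic mass lies strictly inside the SEC window."""
    window = window or SecWindow()
    kept = []
    for p in peptides:
        p = _as_peptide(p)
        if window.contains(monoisotopic_mass(p)):
            kept.append(p)
    return kept


def heavy_peptide(
    sequence: str, label: Mapping[int, float] | None = None
) -> Peptide:
    """Heavy-standard version of a peptide.

    When no explicit label is given, a C-terminal K or R receives the
    standard +8.014199 / +10.008269 Da shift.  Any other C-terminal
    residue (common for HLA-eluted peptides, which are not tryptic)
    requires an explicit label: silently guessing a label position would
    corrupt every Q1/Q3 value downstream.
    """
    if label is not None:
        return Peptide(sequence, dict(label))
    cterm = sequence[-1:]
    if cterm in HEAVY_LABEL_SHIFTS:
        return Peptide(sequence, {len(sequence): HEAVY_LABEL_SHIFTS[cterm]})
    raise PeptideError(
        f"no default heavy label for C-terminal residue {cterm!r}; "
        "specify the label position and mass shift explicitly"
    )
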