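"""MaxRec carrier-peptide design.

Before each run the liquid path is pre-conditioned with carrier
("MaxRec") peptides: near-copies of every target, 1-2 substitutions
away, spiked far above endogenous levels so that they occupy the
nonspecific binding surfaces the real neoantigens would otherwise be
lost to.  The carriers must mimic the target physically (same length,
matched hydrophobicity) while remaining invisible to the mass
spectrometer: either their precursor m/z clears every monitored Q1
window, or — when a Q1 clash is unavoidable — every one of their b/y
product ions clears the clashing Q3 windows.

Blindness here is evaluated on theoretical m/z alone; the selectivity
claim rests on the quadrupole mass filters, not on retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .chem import AA_MONO_MASS, Peptide, fragment_ions, gravy, monoisotopic_mass, precursor_mz
from .srm import AssayPanel

__all__ = [
    "MaxRecConstraints",
    "MaxRecPeptide",
    "BlindnessResult",
    "DesignError",
    "candidate_substitutions",
    "verify_blindness",
    "design_maxrec",
    "maxrec_cocktail_report",
    "read_cocktail_report",
]

_AA = sorted(AA_MONO_MASS)

# Coarse residue classes used by the optional "detectability" filter:
# substitutions within a class keep ionization/fragmentation behaviour
# roughly comparable.
_RESIDUE_CLASS = {
    **{aa: "hydrophobic" for aa in "AVLIMFWC"},
    **{aa: "polar" for aa in "STNQYG"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    "P": "special",
}


class DesignError(ValueError):
    """No carrier peptide satisfies the constraints."""


@dataclass(frozen=True)
class MaxRecConstraints:
    """Design constraints for carrier peptides.

    ``q1_min_separation`` / ``q3_min_separation`` default to 2.0 / 1.0 Th,
    reflecting unit-resolution quadrupole isolation windows.  A
    substitution is forbidden when it is in ``forbidden_swaps`` or when
    the residue mass difference is below ``min_residue_delta_da`` (near-
    isobaric swaps such as L<->I or K<->Q would defeat blindness).
    """

    max_substitutions: int = 2
    gravy_tolerance: float = 0.5
    q1_min_separation: float = 2.0
    q3_min_separation: float = 1.0
    forbidden_swaps: frozenset[frozenset[str]] = frozenset(
        {frozenset("LI"), frozenset("KQ")}
    )
    min_residue_delta_da: float = 0.5
    class_preserving_only: bool = False

    def __post_init__(self) -> None:
        if self.max_substitutions not in (1, 2):
            raise ValueError("max_substitutions must be 1 or 2")
        if self.q1_min_separation <= 0 or self.q3_min_separation <= 0:
            raise ValueError("m/z separations must be > 0")


@dataclass(frozen=True)
class BlindnessResult:
    passed: bool
    q1_margin: float  # smallest precursor-m/z distance to any monitored Q1
    q3_margin: float | None  # smallest product distance over Q1 clashes (None: no clash)

    @property
    def margin(self) -> float:
        """Certificate margin: Q1 distance when no clash, else the Q3 one."""
        return self.q1_margin if self.q3_margin is None else self.q3_margin


@dataclass(frozen=True)
class MaxRecPeptide:
    sequence: str
    parent_id: str
    substitution_positions: tuple[int, ...]  # 1-based
    gravy_delta: float
    blindness: BlindnessResult


def _allowed_swap(ref: str, alt: str, c: MaxRecConstraints) -> bool:
    if alt == ref:
        return False
    if frozenset((ref, alt)) in c.forbidden_swaps:
        return False
    if abs(AA_MONO_MASS[alt] - AA_MONO_MASS[ref]) < c.min_residue_delta_da:
        return False
    if c.class_preserving_only and _RESIDUE_CLASS[alt] != _RESIDUE_CLASS[ref]:
        return False
    return True


def candidate_substitutions(
    target: Peptide | str, c: MaxRecConstraints | None = None
) -> Iterator[tuple[str, tuple[int, ...]]]:
    """All sequences at Hamming distance 1, then 2, from the target.

    Yields ``(sequence, substituted_positions)`` with positions 1-based.
    Forbidden and near-isobaric swaps are never emitted.
    """
    c = c or MaxRecConstraints()
    seq = target.sequence if isinstance(target, Peptide) else target
    n = len(seq)
    options = {
        i: [aa for aa in _AA if _allowed_swap(seq[i], aa, c)] for i in range(n)
    }
    for i in range(n):
        for aa in options[i]:
            yield seq[:i] + aa + seq[i + 1 :], (i + 1,)
    if c.max_substitutions >= 2:
        for i, j in combinations(range(n), 2):
            for aa_i in options[i]:
                for aa_j in options[j]:
                    s = seq[:i] + aa_i + seq[i + 1 : j] + aa_j + seq[j + 1 :]
                    yield s, (i + 1, j + 1)


def verify_blindness(
    candidate: Peptide | str,
    panels: Sequence[AssayPanel],
    c: MaxRecConstraints | None = None,
) -> BlindnessResult:
    """Check that the candidate cannot light up any monitored transition.

    For every precursor charge monitored across the panels, the
    candidate's precursor m/z must clear every panel precursor m/z by at
    least ``q1_min_separation``; where it does not (a Q1 clash), every
    b/y product ion of the candidate must clear every product m/z of the
    clashing panel transitions by ``q3_min_separation``.
    """
    c = c or MaxRecConstraints()
    if not panels:
        raise ValueError("at least one assay panel is required")
    candidate = candidate if isinstance(candidate, Peptide) else Peptide(candidate)

    monitored_charges = sorted({z for p in panels for z in p.precursor_charges})
    product_charges = sorted(
        {e.transition.product.charge for p in panels for e in p.entries}
    )

    q1_margin = float("inf")
    q3_margin: float | None = None
    passed = True
    for z in monitored_charges:
        cand_pre = precursor_mz(candidate, z)
        for panel in panels:
            clashing = [
                e
                for e in panel.entries
                if abs(cand_pre - e.transition.precursor_mz) < c.q1_min_separation
            ]
            for e in panel.entries:
                q1_margin = min(q1_margin, abs(cand_pre - e.transition.precursor_mz))
            if not clashing:
                continue
            cand_products = fragment_ions(candidate, ("b", "y"), product_charges)
            for e in clashing:
                for ion in cand_products:
                    d = abs(ion.mz - e.transition.product.mz)
                    q3_margin = d if q3_margin is None else min(q3_margin, d)
                    if d < c.q3_min_separation:
                        passed = False
    return BlindnessResult(passed, q1_margin, q3_margin)


def design_maxrec(
    target: Peptide | str,
    panels: Sequence[AssayPanel],
    c: MaxRecConstraints | None = None,
    k: int = 3,
    parent_id: str | None = None,
) -> list[MaxRecPeptide]:
    """The k best blind carrier peptides for a target.

    Candidates at Hamming distance <= 2 are screened for matched
    hydrophobicity (|dGRAVY| <= tolerance) and MS blindness against
    *all* supplied panels (a carrier must not interfere with any target
    in the run), then ranked by |dGRAVY| ascending, blindness margin
    descending, and finally sequence order — a total order, so the
    design is deterministic.
    """
    c = c or MaxRecConstraints()
    target = target if isinstance(target, Peptide) else Peptide(target)
    parent_id = parent_id or target.sequence
    target_gravy = gravy(target)

    survivors: list[MaxRecPeptide] = []
    for seq, positions in candidate_substitutions(target, c):
        dg = gravy(seq) - target_gravy
        if abs(dg) > c.gravy_tolerance:
            continue
        blind = verify_blindness(seq, panels, c)
        if not blind.passed:
            continue
        survivors.append(MaxRecPeptide(seq, parent_id, positions, dg, blind))
    if not survivors:
        raise DesignError(
            f"no carrier peptide found for {parent_id}; consider loosening "
            "gravy_tolerance or the m/z separations"
        )
    survivors.sort(key=lambda m: (abs(m.gravy_delta), -m.blindness.margin, m.sequence))
    return survivors[:k]


def maxrec_cocktail_report(
    maxrecs: Sequence[MaxRecPeptide],
    concentration_fmol_per_ul: float = 10.0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate a carrier cocktail; working concentration 10 fmol/uL."""
    if not maxrecs:
        raise ValueError("empty carrier set")
    rows = []
    for m in maxrecs:
        rows.append(
            {
                "parent": m.parent_id,
                "sequence": m.sequence,
                "positions": ";".join(str(p) for p in m.substitution_positions),
                "monoisotopic_mass": round(monoisotopic_mass(m.sequence), 5),
                "dgravy": round(m.gravy_delta, 4),
                "q1_margin": round(m.blindness.q1_margin, 5),
                "q3_margin": (
                    round(m.blindness.q3_margin, 5)
                    if m.blindness.q3_margin is not None
                    else ""
                ),
                "concentration_fmol_per_ul": concentration_fmol_per_ul,
            }
        )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def read_cocktail_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, dtype={"positions": str, "q3_margin": str})
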