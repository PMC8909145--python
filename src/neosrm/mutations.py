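"""Missense-mutation parsing and candidate neoantigen enumeration.

HLA class I presents peptides of 8-12 residues, so every window of
those lengths that covers a mutated residue is a candidate neoantigen.
An interior missense site therefore yields at most 8+9+10+11+12 = 50
candidates; sites near a protein terminus yield fewer.  Enumeration is
exhaustive and prediction-free: no binding-affinity model is consulted.

Coordinates are 1-based protein positions throughout, matching the
clinical ``GENE_RefPosAlt`` notation (e.g. ``KRAS_G12V``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .chem import Peptide, SecWindow, monoisotopic_mass

__all__ = [
    "MutationError",
    "ProteinContext",
    "MissenseMutation",
    "Candidate",
    "CandidateSet",
    "DEFAULT_LENGTHS",
    "load_contexts",
    "parse_mutation",
    "apply_mutation",
    "enumerate_candidates",
    "candidate_count",
    "candidates_table",
]

DEFAULT_LENGTHS: tuple[int, ...] = (8, 9, 10, 11, 12)

_MUTATION_RE = re.compile(r"^(?P<gene>[A-Za-z0-9][A-Za-z0-9.-]*)_(?P<ref>[A-Z])(?P<pos>[1-9]\d*)(?P<alt>[A-Z])$")


class MutationError(ValueError):
    """Malformed mutation token or context mismatch."""


@dataclass(frozen=True)
class ProteinContext:
    """A protein sequence (or excerpt) in canonical coordinates.

    ``offset`` is the canonical 1-based position of the first residue of
    ``sequence``, so excerpts of long proteins can keep hotspot
    numbering (e.g. TP53 R248 inside a 66-residue excerpt).
    """

    gene: str
    sequence: str
    offset: int = 1

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        Peptide(self.sequence)  # validates the alphabet

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        return self.offset + len(self.sequence) - 1

    def residue(self, position: int) -> str:
        """Residue at canonical 1-based ``position``."""
        if not self.start <= position <= self.end:
            raise MutationError(
                f"position {position} outside {self.gene} context "
                f"[{self.start}, {self.end}]"
            )
        return self.sequence[position - self.offset]


@dataclass(frozen=True)
class MissenseMutation:
    gene: str
    position: int  # 1-based protein coordinate
    ref_aa: str
    alt_aa: str
    context: ProteinContext

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise MutationError(
                f"{self.token}: reference and alternate residues are identical"
            )
        observed = self.context.residue(self.position)
        if observed != self.ref_aa:
            raise MutationError(
                f"{self.token}: context has {observed!r} at position "
                f"{self.position}, expected reference residue {self.ref_aa!r}"
            )

    @property
    def token(self) -> str:
        return f"{self.gene}_{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class Candidate:
    """One enumerated window on the mutated sequence."""

    sequence: str
    start: int  # canonical 1-based, inclusive
    length: int
    wildtype_sequence: str


@dataclass(frozen=True)
class CandidateSet:
    mutation: MissenseMutation
    candidates: tuple[Candidate, ...]

    def __len__(self) -> int:
        return len(self.candidates)


def load_contexts(fasta_path: str | Path) -> dict[str, ProteinContext]:
    """Read context proteins from FASTA.

    The record id is the gene name; an optional ``offset=N`` token in
    the description declares the canonical position of the excerpt's
    first residue (defaults to 1 for full-length entries).
    """
    contexts: dict[str, ProteinContext] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        offset = 1
        m = re.search(r"offset=(\d+)", record.description)
        if m:
            offset = int(m.group(1))
        contexts[record.id] = ProteinContext(record.id, str(record.seq).upper(), offset)
    return contexts


def parse_mutation(
    token: str, context_lookup: Mapping[str, ProteinContext]
) -> MissenseMutation:
    """Parse ``GENE_RefPosAlt`` and validate it against the gene's context."""
    m = _MUTATION_RE.match(token)
    if m is None:
        raise MutationError(
            f"cannot parse mutation token {token!r}; expected GENE_RefPosAlt, "
            "e.g. KRAS_G12V"
        )
    gene = m.group("gene")
    if gene not in context_lookup:
        raise MutationError(f"no protein context available for gene {gene!r}")
    return MissenseMutation(
        gene=gene,
        position=int(m.group("pos")),
        ref_aa=m.group("ref"),
        alt_aa=m.group("alt"),
        context=context_lookup[gene],
    )


def apply_mutation(m: MissenseMutation) -> str:
    """The context sequence with the alternate residue substituted in."""
    i = m.position - m.context.offset
    seq = m.context.sequence
    return seq[:i] + m.alt_aa + seq[i + 1 :]


def enumerate_candidates(
    m: MissenseMutation, lengths: Sequence[int] = DEFAULT_LENGTHS
) -> CandidateSet:
    """Every window of each requested length that covers the mutated site.

    Windows are clipped to the available context; candidates are keyed
    by (start, length), so repetitive contexts may legitimately yield
    duplicate sequences at distinct positions.
    """
    mutated = apply_mutation(m)
    wildtype = m.context.sequence
    lo, hi = m.context.start, m.context.end
    pos = m.position
    out: list[Candidate] = []
    for L in sorted(lengths):
        first = max(lo, pos - L + 1)
        last = min(pos, hi - L + 1)
        for s in range(first, last + 1):
            i = s - m.context.offset
            out.append(
                Candidate(
                    sequence=mutated[i : i + L],
                    start=s,
                    length=L,
                    wildtype_sequence=wildtype[i : i + L],
                )
            )
    return CandidateSet(mutation=m, candidates=tuple(out))


def candidate_count(context_len: int, position: int, lengths: Sequence[int] = DEFAULT_LENGTHS) -> int:
    """Closed-form window count for a site at ``position`` of a
    full-length protein of ``context_len`` residues (offset 1)."""
    total = 0
    for L in lengths:
        n = min(position, context_len - L + 1) - max(1, position - L + 1) + 1
        if n > 0:
            total += n
    return total


def candidates_table(
    cs: CandidateSet,
    sec_window: SecWindow | None = None,
    include_wildtype: bool = False,
) -> pd.DataFrame:
    """Candidate set as a tidy table with mass and SEC-gate annotation."""
    window = sec_window or SecWindow()
    rows = []
    for c in cs.candidates:
        mass = monoisotopic_mass(c.sequence)
        rows.append(
            {
                "gene": cs.mutation.gene,
                "mutation": cs.mutation.token,
                "start": c.start,
                "length": c.length,
                "sequence": c.sequence,
                "monoisotopic_mass": round(mass, 5),
                "in_sec_window": window.contains(mass),
            }
        )
        if include_wildtype:
            wt_mass = monoisotopic_mass(c.wildtype_sequence)
            rows.append(
                {
                    "gene": cs.mutation.gene,
                    "mutation": cs.mutation.token + "_WT",
                    "start": c.start,
                    "length": c.length,
                    "sequence": c.wildtype_sequence,
                    "monoisotopic_mass": round(wt_mass, 5),
                    "in_sec_window": window.contains(wt_mass),
                }
            )
    return pd.DataFrame(rows)
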