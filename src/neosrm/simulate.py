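"""Synthetic acquisition data and packaged example targets.

The simulators emulate the statistical structure the design and
quantification stages assume, so the whole pipeline can be exercised
offline:

* per-transition collision-energy response curves are unimodal
  (Gaussian in CE) with multiplicative log-normal noise;
* transition peak intensities follow a decaying rank structure, as real
  fragment-ion spectra do;
* blank tumor-matrix runs show interference on a chosen subset of
  transitions, at a stated fraction of the standard's signal;
* light/heavy area tables carry replicate-level log-normal noise on the
  detected ratio.

``fixtures()`` bundles short context excerpts around the KRAS G12/Q61,
TP53 Y220/R248/R213 and IDH2 R140 hotspots plus an 11-entry benchmark
assay table (detected ratios with and without the carrier cocktail,
500 amol heavy spike, 5e7 tumor cells) whose area tables round-trip
through the quantification stage.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import Peptide, isotope_label_shift
from .mutations import MissenseMutation, ProteinContext, enumerate_candidates, parse_mutation
from .quant import AVOGADRO
from .srm import CeGrid, Transition

__all__ = [
    "ResponseModel",
    "TransitionResponse",
    "simulate_ce_response",
    "simulate_blank_matrix",
    "simulate_quant_areas",
    "random_response_model",
    "fixtures",
    "Fixtures",
    "FixtureTarget",
    "fixture_heavy_peptide",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class TransitionResponse:
    """True (simulated) CE response of one transition."""

    optimal_ce: float
    peak_intensity: float
    width_ev: float

    def __post_init__(self) -> None:
        if self.width_ev <= 0:
            raise ValueError("response width must be > 0")
        if self.peak_intensity <= 0:
            raise ValueError("peak intensity must be > 0")

    def intensity_at(self, ce: float) -> float:
        d = ce - self.optimal_ce
        return self.peak_intensity * math.exp(-(d * d) / (2.0 * self.width_ev**2))


@dataclass(frozen=True)
class ResponseModel:
    """Per-transition response curves plus acquisition noise settings."""

    responses: Mapping[str, TransitionResponse]  # keyed by transition key
    noise_cv: float = 0.0
    blank_interference: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")


def random_response_model(
    transitions: Sequence[Transition],
    seed: int,
    noise_cv: float = 0.0,
    ce_jitter_ev: float = 3.0,
    width_range_ev: tuple[float, float] = (4.0, 8.0),
    base_intensity: float = 1e6,
    rank_decay: float = 4.0,
    n_interfering: int = 0,
    interference_fraction: float = 0.5,
) -> ResponseModel:
    """A plausible response model for a transition set.

    True optima sit within ``ce_jitter_ev`` of the theoretical CE; peak
    intensities decay geometrically with a shuffled rank so that a
    realistic intensity hierarchy exists; optionally ``n_interfering``
    transitions also show blank-matrix signal.
    """
    rng = np.random.default_rng(seed)
    keys = [t.key for t in transitions]
    ranks = rng.permutation(len(keys))
    responses = {}
    for t, rank in zip(transitions, ranks):
        responses[t.key] = TransitionResponse(
            optimal_ce=max(2.0, t.ce + rng.uniform(-ce_jitter_ev, ce_jitter_ev)),
            peak_intensity=base_intensity * math.exp(-rank / rank_decay),
            width_ev=rng.uniform(*width_range_ev),
        )
    interference = {}
    if n_interfering:
        for key in rng.choice(keys, size=min(n_interfering, len(keys)), replace=False):
            interference[str(key)] = interference_fraction
    return ResponseModel(responses, noise_cv, interference, seed)


def simulate_ce_response(
    model: ResponseModel, grids: Iterable[CeGrid], replicate: int = 1
) -> pd.DataFrame:
    """Measured intensities for every (transition, CE) of a schedule.

    intensity(ce) = peak * exp(-(ce - opt)^2 / (2 width^2)) * noise,
    with unit-mean log-normal noise; bit-reproducible under the model's
    seed.
    """
    rng = np.random.default_rng(model.seed)
    rows = []
    for grid in grids:
        t = grid.base
        response = model.responses[t.key]
        noise = _lognormal_factors(rng, model.noise_cv, len(grid.ce_values))
        for ce, f in zip(grid.ce_values, noise):
            rows.append(
                {
                    "target_id": t.target_id,
                    "transition_key": t.key,
                    "ce": ce,
                    "intensity": response.intensity_at(ce) * f,
                    "is_blank": False,
                    "replicate": replicate,
                }
            )
    return pd.DataFrame(rows)


def simulate_blank_matrix(
    model: ResponseModel, transitions: Sequence[Transition]
) -> pd.DataFrame:
    """Blank-matrix run: interfering transitions carry the configured
    fraction of their standard's peak signal, all others read zero."""
    rows = []
    for t in transitions:
        fraction = model.blank_interference.get(t.key, 0.0)
        response = model.responses[t.key]
        rows.append(
            {
                "target_id": t.target_id,
                "transition_key": t.key,
                "ce": response.optimal_ce,
                "intensity": fraction * response.peak_intensity,
                "is_blank": True,
                "replicate": 1,
            }
        )
    return pd.DataFrame(rows)


def simulate_quant_areas(
    truth_copies_per_cell: float,
    cell_count: float,
    spike_amol: float,
    cv: float,
    n_replicates: int,
    seed: int,
    target_id: str = "target",
    n_transitions: int = 8,
    heavy_base_area: float = 1e6,
) -> pd.DataFrame:
    """Light/heavy area table implied by a true copy number.

    The implied true detected ratio is
    ``(copies * cells / N_A / 1e-18) / spike``; each replicate's light
    areas are the heavy areas scaled by that ratio times one unit-mean
    log-normal factor (so the replicate-to-replicate ratio CV is
    ``cv``).  Heavy areas decay across transitions to mimic a fragment
    intensity hierarchy.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    true_amol = truth_copies_per_cell * cell_count / AVOGADRO / 1e-18
    true_ratio = true_amol / spike_amol
    heavy = heavy_base_area * np.exp(-np.arange(n_transitions) / 3.0)
    factors = _lognormal_factors(rng, cv, n_replicates)
    rows = []
    for rep in range(1, n_replicates + 1):
        ratio = true_ratio * factors[rep - 1]
        for i in range(n_transitions):
            rows.append(
                {
                    "target_id": target_id,
                    "replicate": rep,
                    "transition_key": f"t{i + 1}",
                    "light_area": heavy[i] * ratio,
                    "heavy_area": heavy[i],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Packaged example set: hotspot contexts and the 11-entry benchmark table.
# --------------------------------------------------------------------------

# Short excerpts of the canonical human proteins around the assayed
# hotspots, in canonical UniProt coordinates (KRAS P01116, TP53 P04637,
# IDH2 P48735).  Entered once and frozen; _CONTEXT_SHA256 guards against
# accidental edits.
_CONTEXT_SEQS = {
    "KRAS": ("MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAGQEEYSAMRDQYMR", 1),
    "TP53": ("EGNLRVEYLDDRNTFRHSVVVPYEPPEVGSDCTTIHYNYMCNSSCMGGMNRRPILTIITLEDSSGN", 198),
    "IDH2": ("LVSGWVKPIIIGRHAYGDQYRATDF", 128),
}
_CONTEXT_SHA256 = {
    "KRAS": "bed3c8543208255a",
    "TP53": "c660c2d1ae4e4b2e",
    "IDH2": "74d75ec28260aef1",
}


@dataclass(frozen=True)
class FixtureTarget:
    """One benchmark assay entry: a mutant peptide with its measured
    detected ratios (mean, sample sd over three replicates)."""

    name: str
    mutation: str  # GENE_RefPosAlt token
    site: str  # mutation-site label for site-level summaries
    start: int  # 1-based window start in protein coordinates
    length: int
    ratio_with_carrier: tuple[float, float]
    ratio_without_carrier: tuple[float, float]


# Benchmark detected ratios from a nine-patient frozen-tumor study of
# KRAS/TP53/IDH2 hotspot neoantigens: three replicates per assay, a
# 500 amol heavy-standard spike, and a 5e7 tumor-cell assumption.
_FIXTURE_TARGETS = (
    FixtureTarget("KRAS_Q61H", "KRAS_Q61H", "KRAS_Q61", 55, 9, (1.045, 0.058), (0.022, 0.006)),
    FixtureTarget("KRAS_Q61L", "KRAS_Q61L", "KRAS_Q61", 55, 9, (0.729, 0.037), (0.053, 0.004)),
    FixtureTarget("KRAS_Q61R", "KRAS_Q61R", "KRAS_Q61", 55, 9, (1.495, 0.156), (0.04, 0.004)),
    FixtureTarget("IDH2_R140Q", "IDH2_R140Q", "IDH2_R140", 136, 9, (1.019, 0.057), (0.015, 0.003)),
    FixtureTarget("TP53_Y220C", "TP53_Y220C", "TP53_Y220", 217, 9, (1.354, 0.014), (0.054, 0.002)),
    FixtureTarget("TP53_R248W", "TP53_R248W", "TP53_R248", 245, 9, (0.173, 0.031), (0.086, 0.034)),
    FixtureTarget("TP53_R213L", "TP53_R213L", "TP53_R213", 210, 9, (0.662, 0.03), (0.373, 0.057)),
    FixtureTarget("KRAS_G12V_9mer", "KRAS_G12V", "KRAS_G12", 8, 9, (5.458, 1.206), (0.146, 0.022)),
    FixtureTarget("KRAS_G12V_10mer", "KRAS_G12V", "KRAS_G12", 7, 10, (6.381, 1.693), (0.141, 0.024)),
    FixtureTarget("KRAS_G12D_9mer", "KRAS_G12D", "KRAS_G12", 8, 9, (2.933, 1.227), (0.145, 0.067)),
    FixtureTarget("KRAS_G12D_10mer", "KRAS_G12D", "KRAS_G12", 7, 10, (6.518, 3.748), (0.244, 0.104)),
)

FIXTURE_SPIKE_AMOL = 500.0
FIXTURE_CELL_COUNT = 5e7


@dataclass(frozen=True)
class Fixtures:
    contexts: Mapping[str, ProteinContext]
    targets: tuple[FixtureTarget, ...]
    spike_amol: float
    cell_count: float

    def mutation(self, target: FixtureTarget) -> MissenseMutation:
        return parse_mutation(target.mutation, self.contexts)

    def peptide_sequence(self, target: FixtureTarget) -> str:
        """The mutant peptide of a benchmark entry, recovered by
        enumeration (never stored, so it always matches the context)."""
        cs = enumerate_candidates(self.mutation(target), lengths=(target.length,))
        for cand in cs.candidates:
            if cand.start == target.start:
                return cand.sequence
        raise LookupError(f"window start {target.start} not available for {target.name}")

    def site_of(self) -> dict[str, str]:
        return {t.name: t.site for t in self.targets}

    def quant_areas(
        self,
        arm: str = "with_carrier",
        n_transitions: int = 8,
        heavy_base_area: float = 1e6,
    ) -> pd.DataFrame:
        """Replicate-resolved area table reproducing the benchmark
        detected-ratio column of the chosen arm.

        Three replicate ratios are placed at mean - sd, mean, mean + sd,
        whose sample mean and sd equal the tabulated values exactly.
        """
        if arm not in ("with_carrier", "without_carrier"):
            raise ValueError("arm must be 'with_carrier' or 'without_carrier'")
        heavy = heavy_base_area * np.exp(-np.arange(n_transitions) / 3.0)
        rows = []
        for t in self.targets:
            mean, sd = (
                t.ratio_with_carrier if arm == "with_carrier" else t.ratio_without_carrier
            )
            for rep, delta in enumerate((-1.0, 0.0, 1.0), start=1):
                ratio = mean + delta * sd
                for i in range(n_transitions):
                    rows.append(
                        {
                            "target_id": t.name,
                            "replicate": rep,
                            "transition_key": f"t{i + 1}",
                            "light_area": heavy[i] * ratio,
                            "heavy_area": heavy[i],
                        }
                    )
        return pd.DataFrame(rows)

    def reference_table(self) -> pd.DataFrame:
        rows = []
        for t in self.targets:
            rows.append(
                {
                    "target_id": t.name,
                    "site": t.site,
                    "ratio_with_carrier": t.ratio_with_carrier[0],
                    "ratio_sd_with_carrier": t.ratio_with_carrier[1],
                    "ratio_without_carrier": t.ratio_without_carrier[0],
                    "ratio_sd_without_carrier": t.ratio_without_carrier[1],
                }
            )
        return pd.DataFrame(rows)


def fixtures() -> Fixtures:
    """The packaged 11-target benchmark set with its hotspot contexts."""
    contexts = {}
    for gene, (seq, offset) in _CONTEXT_SEQS.items():
        digest = hashlib.sha256(seq.encode()).hexdigest()[:16]
        if digest != _CONTEXT_SHA256[gene]:
            raise RuntimeError(f"context excerpt for {gene} was modified (checksum mismatch)")
        contexts[gene] = ProteinContext(gene, seq, offset)
    return Fixtures(
        contexts=contexts,
        targets=_FIXTURE_TARGETS,
        spike_amol=FIXTURE_SPIKE_AMOL,
        cell_count=FIXTURE_CELL_COUNT,
    )


def fixture_heavy_peptide(sequence: str) -> Peptide:
    """Heavy standard of a fixture target: the C-terminal residue fully
    13C/15N-labelled (the K+8/R+10 convention, generalized to
    non-tryptic C termini)."""
    return Peptide(sequence, {len(sequence): isotope_label_shift(sequence[-1])})
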