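"""End-to-end orchestration: enumerate -> schedule -> acquire (simulated)
-> optimize -> curate -> panel -> carrier design -> quantify.

These helpers wire the stage modules together in the order the assay
runs; every stage remains individually usable with real measurement
tables in place of the simulator's.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .carrier import DesignError, MaxRecConstraints, MaxRecPeptide, design_maxrec
from .chem import Peptide
from .quant import fold_improvement, quantify, site_summary
from .simulate import (
    Fixtures,
    fixture_heavy_peptide,
    fixtures,
    random_response_model,
    simulate_blank_matrix,
    simulate_ce_response,
)
from .srm import (
    AssayPanel,
    Transition,
    build_panel,
    curate_matrix,
    make_transitions,
    optimize_stage2,
    rank_stage1,
    stage1_grid,
    stage2_grid,
)

__all__ = ["DesignRun", "design_target", "run_fixture_pipeline", "FixtureRun"]


@dataclass(frozen=True)
class DesignRun:
    """Artifacts of one target's two-stage design."""

    panel: AssayPanel
    transitions: tuple[Transition, ...]
    stage1_measurements: pd.DataFrame
    stage2_measurements: pd.DataFrame
    dropped: pd.DataFrame  # transitions removed by blank-matrix curation


def design_target(
    target_id: str,
    peptide: Peptide | str,
    seed: int,
    noise_cv: float = 0.1,
    n_interfering: int = 2,
    precursor_charges: Sequence[int] = (2, 3),
) -> DesignRun:
    """Run the full two-stage CE optimization for one target against the
    bundled acquisition simulator."""
    transitions = make_transitions(target_id, peptide, precursor_charges)
    model = random_response_model(
        transitions, seed=seed, noise_cv=noise_cv, n_interfering=n_interfering
    )

    stage1 = simulate_ce_response(model, [stage1_grid(t) for t in transitions])
    advancing = set(rank_stage1(stage1, transitions)["transition_key"])
    survivors = [t for t in transitions if t.key in advancing]

    grids2 = {t.key: stage2_grid(t) for t in survivors}
    stage2 = simulate_ce_response(model, grids2.values())
    optimized = optimize_stage2(stage2, grids2)

    blank = simulate_blank_matrix(model, survivors)
    kept, dropped = curate_matrix(optimized, blank)
    panel = build_panel(kept, survivors)
    return DesignRun(panel, tuple(transitions), stage1, stage2, dropped)


def design_cocktail(
    targets: Mapping[str, Peptide | str],
    panels: Sequence[AssayPanel],
    constraints: MaxRecConstraints | None = None,
    k: int = 1,
) -> dict[str, list[MaxRecPeptide]]:
    """Carrier peptides for every target, blind to *all* panels.

    Single substitutions are tried first (maximal physical similarity);
    only when none survives does the search widen to two.
    """
    base = constraints or MaxRecConstraints()
    out = {}
    for target_id, peptide in targets.items():
        seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
        light = Peptide(seq)
        try:
            narrow = replace(base, max_substitutions=1)
            out[target_id] = design_maxrec(light, panels, narrow, k=k, parent_id=target_id)
        except DesignError:
            out[target_id] = design_maxrec(light, panels, base, k=k, parent_id=target_id)
    return out


@dataclass(frozen=True)
class FixtureRun:
    """Everything the 11-target benchmark run produces."""

    fixtures: Fixtures
    panels: dict[str, AssayPanel]
    cocktail: dict[str, list[MaxRecPeptide]]
    quant_with: pd.DataFrame
    quant_without: pd.DataFrame
    sites: pd.DataFrame
    folds: pd.DataFrame


def run_fixture_pipeline(
    seed: int, design_cocktails: bool = True, noise_cv: float = 0.1
) -> FixtureRun:
    """The whole pipeline over the packaged 11-target benchmark set."""
    fx = fixtures()
    panels: dict[str, AssayPanel] = {}
    sequences: dict[str, str] = {}
    for i, target in enumerate(fx.targets):
        seq = fx.peptide_sequence(target)
        sequences[target.name] = seq
        heavy = fixture_heavy_peptide(seq)
        run = design_target(target.name, heavy, seed=seed + i, noise_cv=noise_cv)
        panels[target.name] = run.panel

    cocktail: dict[str, list[MaxRecPeptide]] = {}
    if design_cocktails:
        cocktail = design_cocktail(sequences, list(panels.values()))

    quant_with = quantify(
        fx.quant_areas("with_carrier"), fx.spike_amol, fx.cell_count
    )
    quant_without = quantify(
        fx.quant_areas("without_carrier"), fx.spike_amol, fx.cell_count
    )
    copies = dict(zip(quant_with["target_id"], quant_with["copies_per_cell"]))
    sites = site_summary(copies, fx.site_of())
    folds = fold_improvement(
        dict(zip(quant_with["target_id"], quant_with["ratio_mean"])),
        dict(zip(quant_without["target_id"], quant_without["ratio_mean"])),
    )
    return FixtureRun(fx, panels, cocktail, quant_with, quant_without, sites, folds)
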