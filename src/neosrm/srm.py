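"""Two-stage collision-energy optimization and signature-transition selection.

The acquisition schedule follows triple-quadrupole SRM practice:

* stage 1 screens every b/y transition of each precursor charge state at
  the theoretical collision energy (CE) and at +/-5 eV (3 points), and
  advances the most intense transitions per charge state (at least 20
  when available);
* stage 2 refines each surviving transition on a 9-point grid spanning
  +/-8 eV around the theoretical CE in 2 eV steps;
* transitions whose signal is also present in a blank tumor-matrix run
  are curated away, and the 8-10 most intense survivors become the
  target's signature panel.

Every ranking uses an explicit total order, so identical measurement
tables always produce byte-identical panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import FragmentIon, Peptide, fragment_ions, precursor_mz

__all__ = [
    "CE_FLOOR",
    "DEFAULT_CE_PARAMS",
    "Transition",
    "CeGrid",
    "AssayPanel",
    "PanelEntry",
    "SrmError",
    "theoretical_ce",
    "make_transitions",
    "stage1_grid",
    "stage2_grid",
    "schedule_table",
    "rank_stage1",
    "optimize_stage2",
    "curate_matrix",
    "build_panel",
    "write_transition_list",
    "read_transition_list",
    "read_measurements",
]

#: Lowest collision energy the instrument is asked for (eV).
CE_FLOOR = 2.0

#: Linear CE model per precursor charge: ce = slope * precursor_mz + intercept.
#: Editable defaults in the style of vendor CE equations; override via config.
DEFAULT_CE_PARAMS: Mapping[int, tuple[float, float]] = {
    2: (0.031, 1.0),
    3: (0.036, -4.8),
}


class SrmError(ValueError):
    """Unusable measurement table or empty panel."""


def theoretical_ce(
    precursor_mz_th: float,
    charge: int,
    params: Mapping[int, tuple[float, float]] | None = None,
) -> float:
    """Theoretical collision energy from the per-charge linear model."""
    params = params or DEFAULT_CE_PARAMS
    if charge not in params:
        raise SrmError(
            f"no collision-energy coefficients configured for charge {charge}+"
        )
    slope, intercept = params[charge]
    return max(CE_FLOOR, slope * precursor_mz_th + intercept)


@dataclass(frozen=True)
class Transition:
    """One precursor -> product ion pair with a collision energy."""

    target_id: str
    peptide: Peptide
    precursor_mz: float
    precursor_charge: int
    product: FragmentIon
    ce: float

    def __post_init__(self) -> None:
        if self.ce <= 0:
            raise ValueError("collision energy must be > 0")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")

    @property
    def key(self) -> str:
        """Stable identifier, e.g. ``z2/y7^1``."""
        return f"z{self.precursor_charge}/{self.product.key}"


@dataclass(frozen=True)
class CeGrid:
    base: Transition
    stage: int  # 1 or 2
    ce_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if any(v <= 0 for v in self.ce_values):
            raise ValueError("all grid CE values must be > 0")


@dataclass(frozen=True)
class PanelEntry:
    transition: Transition
    optimal_ce: float
    best_intensity: float


@dataclass(frozen=True)
class AssayPanel:
    """A target's final signature transitions with optimized CEs."""

    target_id: str
    peptide: Peptide
    entries: tuple[PanelEntry, ...]
    degraded: bool = False  # fewer survivors than the k_min floor

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def precursor_charges(self) -> tuple[int, ...]:
        return tuple(sorted({e.transition.precursor_charge for e in self.entries}))


def make_transitions(
    target_id: str,
    peptide: Peptide | str,
    precursor_charges: Sequence[int] = (2, 3),
    series_set: Sequence[str] = ("b", "y"),
    product_charges: Sequence[int] = (1,),
    ce_params: Mapping[int, tuple[float, float]] | None = None,
) -> list[Transition]:
    """All candidate transitions of a target at its theoretical CEs.

    Precursor charges default to 2+/3+, the usual states of 8-12-mers
    under electrospray; 1+ can be requested explicitly.
    """
    peptide = peptide if isinstance(peptide, Peptide) else Peptide(peptide)
    out = []
    for z in precursor_charges:
        pre_mz = precursor_mz(peptide, z)
        ce = theoretical_ce(pre_mz, z, ce_params)
        for product in fragment_ions(peptide, series_set, product_charges):
            out.append(Transition(target_id, peptide, pre_mz, z, product, ce))
    return out


def _clamped_grid(center: float, offsets: Iterable[float]) -> tuple[float, ...]:
    values = sorted({max(CE_FLOOR, center + d) for d in offsets})
    return tuple(values)


def stage1_grid(t: Transition) -> CeGrid:
    """Theoretical CE plus 5 eV below/above (3 values, clamped at the floor)."""
    return CeGrid(t, 1, _clamped_grid(t.ce, (-5.0, 0.0, 5.0)))


def stage2_grid(t: Transition) -> CeGrid:
    """Nine CE values: theoretical plus 4 steps of 2 eV on either side."""
    return CeGrid(t, 2, _clamped_grid(t.ce, tuple(2.0 * k for k in range(-4, 5))))


def schedule_table(grids: Iterable[CeGrid]) -> pd.DataFrame:
    """One row per (transition, CE) of an acquisition schedule."""
    rows = []
    for grid in grids:
        t = grid.base
        for ce in grid.ce_values:
            rows.append(_transition_row(t, ce, stage=str(grid.stage)))
    return pd.DataFrame(rows)


def _transition_row(t: Transition, ce: float, stage: str) -> dict:
    return {
        "target_id": t.target_id,
        "sequence": t.peptide.sequence,
        "label": "heavy" if t.peptide.is_heavy else "light",
        "precursor_mz": round(t.precursor_mz, 5),
        "precursor_charge": t.precursor_charge,
        "product": t.product.key,
        "product_mz": round(t.product.mz, 5),
        "ce": round(ce, 1),
        "stage": stage,
    }


def _transition_meta(transitions: Iterable[Transition]) -> pd.DataFrame:
    rows = []
    for t in transitions:
        rows.append(
            {
                "transition_key": t.key,
                "precursor_charge": t.precursor_charge,
                "series": t.product.series,
                "ordinal": t.product.ordinal,
                "product_mz": t.product.mz,
            }
        )
    return pd.DataFrame(rows)


def rank_stage1(
    measurements: pd.DataFrame,
    transitions: Sequence[Transition],
    n_per_charge: int = 20,
    score: str = "max",
) -> pd.DataFrame:
    """Score stage-1 measurements and pick the transitions that advance.

    Each transition is scored by its maximum intensity across its own
    CE grid (``score="auc"`` uses the trapezoidal area under the
    intensity-vs-CE curve instead); per precursor charge state the top
    max(20, n_per_charge) advance (all of them when fewer were
    measured).  Ties break by higher product m/z, then y before b, then
    lower ordinal — a total order, so the outcome is deterministic.
    """
    signal = measurements[~measurements["is_blank"].astype(bool)]
    if signal.empty:
        raise SrmError("no non-blank stage-1 measurements supplied")
    if score == "max":
        scores = (
            signal.groupby("transition_key", as_index=False)["intensity"].max()
            .rename(columns={"intensity": "score"})
        )
    elif score == "auc":
        scores = (
            signal.sort_values("ce")
            .groupby("transition_key")
            .apply(
                lambda g: float(np.trapezoid(g["intensity"], g["ce"])),
                include_groups=False,
            )
            .rename("score")
            .reset_index()
        )
    else:
        raise SrmError(f"unknown stage-1 score {score!r}")
    meta = _transition_meta(transitions)
    scored = scores.merge(meta, on="transition_key", how="inner")
    scored["series_rank"] = (scored["series"] != "y").astype(int)  # y first
    scored = scored.sort_values(
        by=["score", "product_mz", "series_rank", "ordinal"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    n_advance = max(20, n_per_charge)
    out = (
        scored.groupby("precursor_charge", group_keys=False, sort=True)
        .head(n_advance)
        .drop(columns="series_rank")
        .reset_index(drop=True)
    )
    return out


def optimize_stage2(
    measurements: pd.DataFrame,
    grids: Mapping[str, CeGrid] | None = None,
) -> pd.DataFrame:
    """Per transition, the CE that maximized intensity on the 9-point grid.

    Ties go to the lower CE.  If ``grids`` are supplied and some grid
    points were never measured, a warning is raised and the optimum is
    taken over the observed points only.
    """
    signal = measurements[~measurements["is_blank"].astype(bool)]
    if signal.empty:
        raise SrmError("no non-blank stage-2 measurements supplied")
    if grids is not None:
        for key, grid in grids.items():
            observed = set(signal.loc[signal["transition_key"] == key, "ce"])
            missing = [v for v in grid.ce_values if v not in observed]
            if missing:
                warnings.warn(
                    f"transition {key}: {len(missing)} stage-2 grid points "
                    "unmeasured; optimizing over observed CEs only",
                    stacklevel=2,
                )
    best = (
        signal.sort_values(by=["intensity", "ce"], ascending=[False, True], kind="mergesort")
        .groupby("transition_key", as_index=False)
        .first()[["transition_key", "ce", "intensity"]]
        .rename(columns={"ce": "optimal_ce", "intensity": "best_intensity"})
    )
    return best.sort_values(
        by=["best_intensity", "transition_key"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def curate_matrix(
    optimized: pd.DataFrame,
    blank_measurements: pd.DataFrame,
    ratio_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop transitions with appreciable signal in the blank tumor matrix.

    A transition is rejected when its maximum blank-matrix intensity is
    at least ``ratio_threshold`` times its best standard intensity (5%
    by default).  Returns (kept, dropped-with-reason).
    """
    blanks = blank_measurements[blank_measurements["is_blank"].astype(bool)]
    blank_max = blanks.groupby("transition_key")["intensity"].max()
    result = optimized.copy()
    result["blank_intensity"] = (
        result["transition_key"].map(blank_max).fillna(0.0)
    )
    result["blank_ratio"] = result["blank_intensity"] / result["best_intensity"]
    drop = result["blank_intensity"] >= ratio_threshold * result["best_intensity"]
    dropped = result[drop].copy()
    dropped["reason"] = [
        f"blank/signal ratio {r:.3f} >= threshold {ratio_threshold:g}"
        for r in dropped["blank_ratio"]
    ]
    return result[~drop].reset_index(drop=True), dropped.reset_index(drop=True)


def build_panel(
    optimized: pd.DataFrame,
    transitions: Sequence[Transition],
    k_min: int = 8,
    k_max: int = 10,
) -> AssayPanel:
    """Assemble the signature-transition panel from curated survivors.

    Takes the top min(k_max, survivors) transitions by optimized
    intensity; warns when fewer than k_min survive (degraded panel) and
    fails hard when none do.
    """
    if optimized.empty:
        raise SrmError("no curated transitions survive; target is unmeasurable")
    index = {t.key: t for t in transitions}
    target_ids = {t.target_id for t in transitions}
    if len(target_ids) != 1:
        raise SrmError("build_panel expects transitions of a single target")
    entries = []
    for row in optimized.head(k_max).itertuples(index=False):
        t = index[row.transition_key]
        entries.append(
            PanelEntry(
                transition=t,
                optimal_ce=float(row.optimal_ce),
                best_intensity=float(row.best_intensity),
            )
        )
    degraded = len(entries) < k_min
    if degraded:
        warnings.warn(
            f"only {len(entries)} signature transitions survived curation "
            f"(floor is {k_min}); panel is degraded",
            stacklevel=2,
        )
    t0 = entries[0].transition
    return AssayPanel(t0.target_id, t0.peptide, tuple(entries), degraded)


def write_transition_list(
    obj: AssayPanel | Iterable[CeGrid] | pd.DataFrame, path: str | Path
) -> pd.DataFrame:
    """Write a vendor-neutral transition-list CSV; returns the frame written."""
    if isinstance(obj, AssayPanel):
        frame = pd.DataFrame(
            [_transition_row(e.transition, e.optimal_ce, stage="final") for e in obj.entries]
        )
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        frame = schedule_table(obj)
    frame.to_csv(path, index=False)
    return frame


def read_transition_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"stage": str})


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV: target_id, transition_key, ce, intensity,
    is_blank, replicate."""
    df = pd.read_csv(path)
    required = {"target_id", "transition_key", "ce", "intensity", "is_blank", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise SrmError(f"measurement table missing columns: {sorted(missing)}")
    df["is_blank"] = df["is_blank"].astype(bool)
    return df
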