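"""Absolute quantification from light/heavy transition areas.

A known amount of heavy-isotope-labelled standard (in attomoles) is
spiked into each sample.  Per replicate, the detected ratio is the sum
of light (endogenous) transition areas divided by the sum of heavy
(standard) areas over the signature transitions; the mean ratio times
the spike amount gives the endogenous abundance in attomoles, and

    copies/cell = amol x 1e-18 mol x N_A / cell count

converts to copy number per tumor cell (N_A = 6.02214076e23, SI exact).
Assays are run in replicate (typically three); dispersion is reported
as the sample standard deviation and as percent CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "DEFAULT_CELL_COUNT",
    "QuantError",
    "RatioResult",
    "QuantResult",
    "detected_ratio",
    "abundance_amol",
    "copies_per_cell",
    "quantify",
    "site_summary",
    "fold_improvement",
    "replicate_cv",
]

AVOGADRO = 6.02214076e23
#: Default tumor cellularity assumption: 50 million cells.
DEFAULT_CELL_COUNT = 5e7
#: Light signal must exceed this multiple of the blank signal to count
#: as detected.
SIGNAL_TO_BLANK_MIN = 3.0


class QuantError(ValueError):
    """Quantification impossible (e.g. heavy standard not detected)."""


@dataclass(frozen=True)
class RatioResult:
    mean: float
    sd: float  # sample sd over replicates; 0.0 when n == 1
    n_replicates: int
    non_detectable: bool = False


@dataclass(frozen=True)
class QuantResult:
    target_id: str
    ratio: RatioResult
    spike_amol: float
    cell_count: float

    @property
    def abundance_amol(self) -> float:
        return abundance_amol(self.ratio.mean, self.spike_amol)

    @property
    def copies_per_cell(self) -> float:
        return copies_per_cell(self.abundance_amol, self.cell_count)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def detected_ratio(
    areas: pd.DataFrame,
    signal_to_blank_min: float = SIGNAL_TO_BLANK_MIN,
    aggregation: str = "sum",
) -> RatioResult:
    """Light/heavy detected ratio for one target.

    ``areas`` holds one row per (replicate, transition) with columns
    ``replicate``, ``light_area``, ``heavy_area`` and optionally
    ``blank_area``.  Per replicate the ratio is the summed light area
    over the summed heavy area (robust to weak transitions); with
    ``aggregation="median"`` it is instead the median of per-transition
    light/heavy ratios.  Mean and sample sd are taken over replicates.
    A target is flagged non-detectable when the total light signal is
    zero or fails the ``signal_to_blank_min`` : 1 signal-to-blank rule.
    """
    if areas.empty:
        raise QuantError("no area measurements supplied")
    if aggregation not in ("sum", "median"):
        raise QuantError(f"unknown ratio aggregation {aggregation!r}")
    if (areas["light_area"] < 0).any() or (areas["heavy_area"] < 0).any():
        raise QuantError("peak areas must be >= 0")
    ratios = []
    for rep, group in areas.groupby("replicate"):
        heavy = group["heavy_area"].sum()
        if heavy <= 0:
            raise QuantError(
                f"replicate {rep}: heavy-standard signal is zero; "
                "quantification impossible"
            )
        if aggregation == "sum":
            ratios.append(group["light_area"].sum() / heavy)
        else:
            per_transition = group["light_area"] / group["heavy_area"]
            ratios.append(float(per_transition.median()))
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0

    light_total = float(areas["light_area"].sum())
    non_detectable = light_total == 0.0
    if "blank_area" in areas.columns:
        blank_total = float(areas["blank_area"].sum())
        if light_total < signal_to_blank_min * blank_total:
            non_detectable = True
    return RatioResult(mean, sd, len(ratios), non_detectable)


def abundance_amol(ratio: float, spike_amol: float) -> float:
    """Endogenous abundance in attomoles: detected ratio x spike amount."""
    if ratio < 0:
        raise QuantError("detected ratio must be >= 0")
    if spike_amol <= 0:
        raise QuantError("spike amount must be > 0 amol")
    return ratio * spike_amol


def copies_per_cell(
    amount_amol: float, cell_count: float = DEFAULT_CELL_COUNT, decimals: int = 1
) -> float:
    """Copy number per tumor cell, rounded half-up to ``decimals``."""
    if cell_count <= 0:
        raise QuantError("cell count must be > 0")
    copies = amount_amol * 1e-18 * AVOGADRO / cell_count
    return _round_half_up(copies, decimals)


def quantify(
    areas: pd.DataFrame,
    spike_amol: float,
    cell_count: float = DEFAULT_CELL_COUNT,
) -> pd.DataFrame:
    """Per-target quantification table from a long-format area table.

    ``areas`` columns: ``target_id``, ``replicate``, ``transition_key``,
    ``light_area``, ``heavy_area`` (optionally ``blank_area``).
    """
    rows = []
    for target_id, group in areas.groupby("target_id", sort=False):
        ratio = detected_ratio(group)
        result = QuantResult(str(target_id), ratio, spike_amol, cell_count)
        rows.append(
            {
                "target_id": result.target_id,
                "ratio_mean": ratio.mean,
                "ratio_sd": ratio.sd,
                "n_replicates": ratio.n_replicates,
                "abundance_amol": result.abundance_amol,
                "copies_per_cell": result.copies_per_cell,
                "non_detectable": ratio.non_detectable,
            }
        )
    return pd.DataFrame(rows)


def site_summary(
    copies: Mapping[str, float] | pd.Series, site_of: Mapping[str, str]
) -> pd.DataFrame:
    """Mean (and range of) copies per cell per mutation site.

    ``copies`` maps target id -> copies per cell; ``site_of`` maps
    target id -> site label (e.g. ``KRAS_G12V_9mer`` -> ``KRAS_G12``).
    """
    items = copies.items() if isinstance(copies, Mapping) else copies.items()
    frame = pd.DataFrame(
        [(site_of[t], float(v)) for t, v in items], columns=["site", "copies"]
    )
    if frame.empty:
        raise QuantError("no quantification results to summarize")
    out = frame.groupby("site")["copies"].agg(["mean", "min", "max", "count"]).reset_index()
    out["mean"] = out["mean"].map(_round_half_up)
    return out.rename(columns={"count": "n"})


def fold_improvement(
    with_carrier: Mapping[str, float], without_carrier: Mapping[str, float]
) -> pd.DataFrame:
    """Per-target sensitivity gain of running with the carrier cocktail.

    fold = detected ratio with carriers / detected ratio without.  A
    target that was non-detectable without carriers (ratio 0) is
    flagged as infinite gain and excluded from the mean.
    """
    rows = []
    for target, w in with_carrier.items():
        wo = without_carrier[target]
        if wo < 0 or w < 0:
            raise QuantError("ratios must be >= 0")
        rows.append(
            {
                "target_id": target,
                "fold": (w / wo) if wo > 0 else math.inf,
                "infinite_gain": wo == 0,
            }
        )
    frame = pd.DataFrame(rows)
    finite = frame.loc[~frame["infinite_gain"], "fold"]
    frame.attrs["mean_fold"] = float(finite.mean()) if len(finite) else math.nan
    frame.attrs["fold_range"] = (
        (float(finite.min()), float(finite.max())) if len(finite) else (math.nan, math.nan)
    )
    return frame


def replicate_cv(values: Sequence[float] | Iterable[float]) -> float:
    """Percent coefficient of variation: 100 x sample sd / mean."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise QuantError("CV requires at least two replicates")
    mean = values.mean()
    if mean == 0:
        raise QuantError("CV undefined: replicate mean is zero")
    return float(100.0 * values.std(ddof=1) / mean)
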