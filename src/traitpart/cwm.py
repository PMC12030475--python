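"""Community-weighted trait means under specific, fixed, and ITV conventions.

A community-weighted mean (CWM) is the abundance-weighted average trait value
of the species in a plot, CWM = sum_i w_i t_i with w_i the relative cover of
species i among the species carrying trait data.  Three conventions are
computed per plot and trait:

* ``specific`` — species trait values measured in that plot (total variation);
* ``fixed``    — each species' pooled average across all plots where it was
  measured (variation from species turnover only);
* ``itv``      — specific minus fixed, the intraspecific component.

The ``itv`` rows are always obtained by subtraction, never recomputed
independently, so the identity itv = specific - fixed holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import (
    POOLED,
    AbundanceMatrix,
    CommonSpeciesFilter,
    PlotDesign,
    TraitTable,
    ValidationError,
)

log = logging.getLogger(__name__)

CONVENTIONS = ("specific", "fixed", "itv")

#: warn when more than this fraction of a plot's cover lacks trait data
COVERAGE_LOSS_WARNING = 0.20


class CWMValue(NamedTuple):
    value: float
    coverage_lost: float  # fraction of the plot's cover carried by trait-less species
    n_species: int


def community_weighted_mean(
    covers: pd.Series,
    trait_values: pd.Series,
    normalize: bool = True,
) -> CWMValue:
    """Weighted mean of ``trait_values`` using ``covers`` as weights.

    Species with zero cover or without a trait value are dropped from both the
    numerator and the weights; the cover fraction lost that way is reported.
    With ``normalize`` (default) weights are relative abundances, making the
    result invariant to rescaling a plot's covers; without it the raw summed
    cover is used (sensitivity check mirroring an unnormalised weighted sum).
    """
    covers = covers[covers > 0]
    if covers.empty:
        raise ValidationError(f"plot {covers.name!r}: no positive cover")
    total = float(covers.sum())
    usable = covers.index.intersection(trait_values.dropna().index)
    if len(usable) == 0:
        raise ValidationError(
            f"plot {covers.name!r}: no species with trait data for this trait"
        )
    w = covers.loc[usable].to_numpy(dtype=float)
    t = trait_values.loc[usable].to_numpy(dtype=float)
    lost = 1.0 - w.sum() / total
    weights = w / w.sum() if normalize else w
    return CWMValue(float(weights @ t), float(lost), int(len(usable)))


@dataclass(frozen=True)
class CWMTable:
    """Long table of CWMs: columns plot_id, trait, convention, value.

    ``coverage`` records, per (plot, trait), the cover fraction excluded
    because species lacked trait data under the specific/fixed convention.
    """

    table: pd.DataFrame
    coverage: pd.DataFrame

    def wide(self, convention: str) -> pd.DataFrame:
        """plot x trait matrix of CWM values for one convention."""
        sel = self.table[self.table["convention"] == convention]
        return sel.pivot(index="plot_id", columns="trait", values="value")

    def response(self, trait: str, convention: str) -> pd.Series:
        sel = self.table[
            (self.table["trait"] == trait) & (self.table["convention"] == convention)
        ]
        return sel.set_index("plot_id")["value"].rename(f"{convention}_{trait}")

    @property
    def traits(self) -> list[str]:
        return sorted(set(self.table["trait"]))

    def traits_with_itv(self) -> list[str]:
        sel = self.table[self.table["convention"] == "itv"]
        return sorted(set(sel["trait"]))

    def to_csv(self, path: str | Path) -> None:
        from .data_model import _repr_float

        self.table.to_csv(path, index=False, float_format=_repr_float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CWMTable":
        df = pd.read_csv(path, float_precision="round_trip")
        cov = df[["plot_id", "trait"]].drop_duplicates().assign(
            coverage_lost_specific=np.nan, coverage_lost_fixed=np.nan
        )
        return cls(df, cov)


def cwm_table(
    design: PlotDesign,
    abundance: AbundanceMatrix,
    traits: TraitTable,
    species_filter: CommonSpeciesFilter | None = None,
    normalize: bool = True,
) -> CWMTable:
    """Compute per-plot CWMs for every trait under all computable conventions.

    Specific CWMs exist only for traits with plot-level measurements in the
    given plot; fixed CWMs exist wherever pooled averages do; itv rows are the
    exact difference and therefore require both.  Traits known only from
    pooled records (e.g. literature seed mass) yield fixed rows alone.
    """
    if species_filter is not None:
        abundance = species_filter.apply(abundance)
    long = traits.table
    specific_long = long[long["plot_id"] != POOLED]
    rows: list[dict] = []
    cov_rows: list[dict] = []
    for trait in traits.traits:
        pooled = traits.pooled_values(trait)
        sub = specific_long[specific_long["trait"] == trait]
        specific_wide = (
            sub.pivot(index="species", columns="plot_id", values="value")
            if len(sub)
            else pd.DataFrame()
        )
        for plot_id in design.plot_ids:
            if plot_id not in abundance.matrix.index:
                continue
            covers = abundance.matrix.loc[plot_id]
            if plot_id in specific_wide.columns:
                specific = specific_wide[plot_id].dropna()
            else:
                specific = pd.Series(dtype=float)
            rec: dict[str, float] = {}
            lost: dict[str, float] = {}
            if not pooled.empty:
                res = community_weighted_mean(covers, pooled, normalize=normalize)
                rec["fixed"], lost["fixed"] = res.value, res.coverage_lost
            if not specific.empty:
                res = community_weighted_mean(covers, specific, normalize=normalize)
                rec["specific"], lost["specific"] = res.value, res.coverage_lost
            if "specific" in rec and "fixed" in rec:
                rec["itv"] = rec["specific"] - rec["fixed"]
            for convention, value in rec.items():
                rows.append(
                    {"plot_id": plot_id, "trait": trait,
                     "convention": convention, "value": value}
                )
            if rec:
                cov_rows.append(
                    {
                        "plot_id": plot_id,
                        "trait": trait,
                        "coverage_lost_specific": lost.get("specific", np.nan),
                        "coverage_lost_fixed": lost.get("fixed", np.nan),
                    }
                )
            worst = max(lost.values(), default=0.0)
            if worst > COVERAGE_LOSS_WARNING:
                log.warning(
                    "plot %s, trait %s: %.0f%% of cover lacks trait data",
                    plot_id, trait, 100 * worst,
                )
    if not rows:
        raise ValidationError("no CWM computable: trait table shares no species with abundances")
    return CWMTable(pd.DataFrame(rows), pd.DataFrame(cov_rows))
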