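"""Core domain types for factorial vegetation-survey datasets.

Three tables describe a study: a plot design (climate level x herbivore
treatment x block), a plot-by-species percent-cover matrix, and a long trait
table holding plot-specific trait measurements plus pooled ("fixed") species
averages.  All downstream stages (community-weighted means, functional
diversity, turnover/ITV decomposition, dissimilarity tests, mixed models)
consume these validated containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

CLIMATES = ("arid", "intermediate", "mesic")
TREATMENTS = ("all_herbivores", "wildlife_only", "no_herbivores")
POOLED = "POOLED"

#: Canonical trait vocabulary with measurement units.
TRAIT_UNITS: Mapping[str, str] = {
    "LA": "mm^2",
    "SLA": "mm^2/mg",
    "LDMC": "mg/g",
    "LNC": "mg/g",
    "seed_mass": "mg",
}


def _repr_float(v: float) -> str:
    """Shortest round-tripping decimal representation (bit-exact CSV I/O)."""
    return repr(float(v))


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IntegrityError(ValueError):
    """Duplicate or internally inconsistent records."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. negative cover)."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


@dataclass(frozen=True)
class PlotDesign:
    """Experimental frame: one row per plot with its three factors.

    ``table`` is indexed by ``plot_id`` and carries ``climate``,
    ``treatment`` and ``block`` columns.  Climate and treatment labels are
    restricted to the fixed vocabularies; ``block`` is an arbitrary site
    letter shared by the plots of one physical location.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "plot_id":
            _require_columns(df, ["plot_id"], "plots")
            df = df.set_index("plot_id")
        _require_columns(df, ["climate", "treatment", "block"], "plots")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate plot_id(s): {dup}")
        bad = set(df["climate"]) - set(CLIMATES)
        if bad:
            raise ValidationError(f"unknown climate label(s): {sorted(bad)}")
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment label(s): {sorted(bad)}")
        cells = df.groupby(["climate", "treatment"], observed=True).size()
        for c in sorted(set(df["climate"])):
            for t in sorted(set(df["treatment"])):
                if (c, t) not in cells.index:
                    raise ValidationError(f"empty design cell: ({c}, {t})")
        object.__setattr__(self, "table", df[["climate", "treatment", "block"]])

    @property
    def plot_ids(self) -> list[str]:
        return list(self.table.index)

    def factors(self, plot_id: str) -> tuple[str, str, str]:
        row = self.table.loc[plot_id]
        return row["climate"], row["treatment"], row["block"]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlotDesign":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


@dataclass(frozen=True)
class AbundanceMatrix:
    """Plot x species percent-cover matrix (quadrat-averaged, 0-100 per species)."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix
        if m.columns.duplicated().any():
            raise IntegrityError(
                f"duplicate species column(s): {m.columns[m.columns.duplicated()].tolist()}"
            )
        if m.index.duplicated().any():
            raise IntegrityError(
                f"duplicate plot row(s): {m.index[m.index.duplicated()].tolist()}"
            )
        vals = m.to_numpy(dtype=float)
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative cover for species {m.columns[j]!r} in plot {m.index[i]!r}"
            )
        if np.any(vals.sum(axis=1) <= 0):
            empty = m.index[vals.sum(axis=1) <= 0].tolist()
            raise ValidationError(f"plot(s) with no positive cover: {empty}")
        object.__setattr__(self, "matrix", m.astype(float))

    @property
    def plot_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)

    def present_species(self, plot_id: str) -> list[str]:
        row = self.matrix.loc[plot_id]
        return list(row.index[row > 0])

    def to_long(self) -> pd.DataFrame:
        long = self.matrix.stack().rename("cover").reset_index()
        long.columns = ["plot_id", "species", "cover"]
        return long[long["cover"] > 0].reset_index(drop=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        _require_columns(df, ["plot_id", "species", "cover"], "abundance")
        dup = df.duplicated(["plot_id", "species"])
        if dup.any():
            rec = df[dup].iloc[0]
            raise IntegrityError(
                f"duplicate abundance record for plot {rec['plot_id']!r}, "
                f"species {rec['species']!r}"
            )
        neg = df[df["cover"].astype(float) < 0]
        if len(neg):
            rec = neg.iloc[0]
            raise ValidationError(
                f"negative cover for species {rec['species']!r} in plot {rec['plot_id']!r}"
            )
        wide = (
            df.pivot(index="plot_id", columns="species", values="cover")
            .fillna(0.0)
            .rename_axis(index="plot_id", columns=None)
        )
        return cls(wide.sort_index(axis=0).sort_index(axis=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceMatrix":
        return cls.from_long(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False, float_format=_repr_float)


@dataclass(frozen=True)
class TraitTable:
    """Long table of trait measurements.

    Records are ``(species, plot_id, trait, value)`` with strictly positive
    values.  ``plot_id == "POOLED"`` marks a species' fixed average — by
    construction the arithmetic mean of its plot-specific values across all
    plots where it was measured.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        _require_columns(df, ["species", "plot_id", "trait", "value"], "traits")
        bad = set(df["trait"]) - set(TRAIT_UNITS)
        if bad:
            raise ValidationError(f"unknown trait name(s): {sorted(bad)}")
        if (df["value"].astype(float) <= 0).any():
            rec = df[df["value"].astype(float) <= 0].iloc[0]
            raise ValidationError(
                f"non-positive trait value: {rec['trait']} for {rec['species']!r} "
                f"at {rec['plot_id']!r}"
            )
        dup = df.duplicated(["species", "plot_id", "trait"])
        if dup.any():
            rec = df[dup].iloc[0]
            raise IntegrityError(
                f"duplicate trait record: ({rec['species']!r}, {rec['plot_id']!r}, "
                f"{rec['trait']!r})"
            )
        df = df[["species", "plot_id", "trait", "value"]].copy()
        df["value"] = df["value"].astype(float)
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def traits(self) -> list[str]:
        return sorted(set(self.table["trait"]))

    def traits_with_specific_values(self) -> list[str]:
        """Traits holding at least one plot-specific (non-pooled) record."""
        sp = self.table[self.table["plot_id"] != POOLED]
        return sorted(set(sp["trait"]))

    def specific_values(self, trait: str, plot_id: str) -> pd.Series:
        """Plot-specific trait values for one plot, indexed by species."""
        sel = self.table[
            (self.table["trait"] == trait) & (self.table["plot_id"] == plot_id)
        ]
        return sel.set_index("species")["value"]

    def pooled_values(self, trait: str) -> pd.Series:
        """Fixed (pooled) trait averages indexed by species."""
        sel = self.table[
            (self.table["trait"] == trait) & (self.table["plot_id"] == POOLED)
        ]
        return sel.set_index("species")["value"]

    def with_pooled(self) -> "TraitTable":
        """Return a copy with POOLED rows (re)derived from plot-specific rows.

        The fixed average of species *s* for trait *t* is the unweighted mean
        of its plot-specific values over every plot where it was measured.
        Existing POOLED rows for traits that also have specific rows are
        replaced; pooled-only traits (e.g. seed mass from literature values)
        are kept as-is.
        """
        df = self.table
        specific = df[df["plot_id"] != POOLED]
        derived = (
            specific.groupby(["species", "trait"], as_index=False)["value"]
            .mean()
            .assign(plot_id=POOLED)
        )
        keep_pooled = df[
            (df["plot_id"] == POOLED)
            & ~df["trait"].isin(set(specific["trait"]))
        ]
        out = pd.concat(
            [specific, keep_pooled, derived[["species", "plot_id", "trait", "value"]]],
            ignore_index=True,
        )
        return TraitTable(out)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format=_repr_float)


@dataclass(frozen=True)
class CommonSpeciesFilter:
    """Per-plot common-species rule: keep the top-cover species that together
    reach at least ``coverage_threshold`` of the plot's total cover.

    Species are ranked by cover descending with lexicographic species-code
    tie-break; the minimal such prefix is retained and all other covers are
    zeroed.  With the default 0.90 this reproduces the usual "species making
    up at least 90% of understory cover" survey convention.

    The threshold is always relative to the *input* row's total, so the
    filter is meant to run once on raw survey data: re-applying it to an
    already-filtered matrix can only restrict the retained sets further
    (e.g. covers {1, 1, 1} at threshold 0.5 keep two species on the first
    pass but one on a second).
    """

    coverage_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ValidationError(
                f"coverage_threshold must be in (0, 1], got {self.coverage_threshold}"
            )

    def retained_species(self, covers: pd.Series) -> list[str]:
        """Minimal prefix of the cover-ranked species list reaching the threshold."""
        covers = covers[covers > 0]
        total = float(covers.sum())
        if total <= 0:
            raise ValidationError(f"plot {covers.name!r} has no positive cover")
        ranked = covers.sort_index().sort_values(ascending=False, kind="stable")
        cum = ranked.cumsum() / total
        # first index whose cumulative share reaches the threshold
        n_keep = int(np.searchsorted(cum.to_numpy(), self.coverage_threshold - 1e-12) + 1)
        n_keep = min(n_keep, len(ranked))
        return list(ranked.index[:n_keep])

    def apply(self, ab: AbundanceMatrix) -> AbundanceMatrix:
        m = ab.matrix.copy()
        for plot_id, row in m.iterrows():
            keep = self.retained_species(row)
            row[~row.index.isin(keep)] = 0.0
            m.loc[plot_id] = row
        m = m.loc[:, (m > 0).any(axis=0)]
        return AbundanceMatrix(m)


def apply_common_species_filter(
    ab: AbundanceMatrix, f: CommonSpeciesFilter | float = 0.90
) -> AbundanceMatrix:
    """Apply the common-species cover rule plot by plot (see CommonSpeciesFilter)."""
    if not isinstance(f, CommonSpeciesFilter):
        f = CommonSpeciesFilter(float(f))
    return f.apply(ab)


class ReconciliationReport(NamedTuple):
    """Cross-table species bookkeeping produced by ``read_tables``."""

    species_without_traits: list[str]
    species_without_abundance: list[str]
    plots_without_abundance: list[str]

    @property
    def clean(self) -> bool:
        return not (
            self.species_without_traits
            or self.species_without_abundance
            or self.plots_without_abundance
        )


class Tables(NamedTuple):
    design: PlotDesign
    abundance: AbundanceMatrix
    traits: TraitTable
    report: ReconciliationReport


def reconcile(
    design: PlotDesign, ab: AbundanceMatrix, traits: TraitTable
) -> ReconciliationReport:
    ab_species = set(ab.species)
    trait_species = set(traits.table["species"])
    return ReconciliationReport(
        species_without_traits=sorted(ab_species - trait_species),
        species_without_abundance=sorted(trait_species - ab_species),
        plots_without_abundance=sorted(set(design.plot_ids) - set(ab.plot_ids)),
    )


def load_column_mapping(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a YAML profile mapping external column names to the canonical ones.

    Expected shape::

        plots:     {plot_id: Plot, climate: Level, ...}
        abundance: {plot_id: Plot, species: SpeciesCode, cover: Cover}
        traits:    {species: SpeciesCode, plot_id: Plot, trait: Trait, value: Value}

    Missing sections or keys default to identity.
    """
    with open(path) as fh:
        profile = yaml.safe_load(fh) or {}
    return {sec: dict(profile.get(sec) or {}) for sec in ("plots", "abundance", "traits")}


def read_tables(
    plots_path: str | Path,
    abundance_path: str | Path,
    traits_path: str | Path,
    mapping: dict[str, dict[str, str]] | str | Path | None = None,
) -> Tables:
    """Read and validate the three canonical CSVs.

    ``mapping`` may be a YAML profile path (or the loaded dict) renaming
    external column names to the canonical schema before validation.  Returns
    the validated objects plus a reconciliation report of species present in
    one table but missing from the other.
    """
    if mapping is not None and not isinstance(mapping, dict):
        mapping = load_column_mapping(mapping)
    mapping = mapping or {}

    def _read(path: str | Path, section: str) -> pd.DataFrame:
        df = pd.read_csv(path, float_precision="round_trip")
        ren = {v: k for k, v in mapping.get(section, {}).items()}
        return df.rename(columns=ren)

    design = PlotDesign(_read(plots_path, "plots"))
    ab = AbundanceMatrix.from_long(_read(abundance_path, "abundance"))
    traits = TraitTable(_read(traits_path, "traits"))
    return Tables(design, ab, traits, reconcile(design, ab, traits))
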