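"""Synthetic factorial plant communities with known turnover/ITV structure.

The generator emulates a grazing-exclosure experiment replicated along a
climate gradient: a full 3 climate x 3 treatment x 3 block design (27 plots by
default), climate-specific species pools whose pairwise overlap is tunable,
Dirichlet percent-cover abundances, lognormal species base traits, and
plot-level intraspecific shifts driven by climate, treatment and their
interaction.  Because every effect is recorded in a ``GroundTruth`` object,
downstream stages (CWMs, variance decomposition, dissimilarity tests, model
selection) can be tested against a known answer.

Regimes
-------
``turnover_only``   no intraspecific shifts or noise: all community trait
                    change comes from species composition.
``itv_only``        one shared species pool and identical abundances in every
                    plot: all change is intraspecific.
``mixed_positive``  intraspecific climate shifts aligned with the between-pool
                    base-trait gradient (reinforcing covariation).
``mixed_negative``  shifts anti-aligned with the gradient (opposing
                    covariation).
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    CLIMATES,
    POOLED,
    TRAIT_UNITS,
    TREATMENTS,
    AbundanceMatrix,
    PlotDesign,
    TraitTable,
    ValidationError,
)


class ConfigError(ValueError):
    """Simulation configuration violates a structural constraint."""


def _trait_dict(values: Mapping[str, float]) -> dict[str, float]:
    return {k: float(v) for k, v in values.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community generator.

    Trait-level dictionaries are keyed by trait name.  ``climate_log_gradient``
    shifts the base-trait log-mean per climate step (arid -> mesic) for species
    whose home pool is that climate, producing turnover-driven CWM gradients.
    ``itv_climate`` / ``itv_treatment`` / ``itv_interaction`` are additive
    plot-level intraspecific shifts (trait units per centred factor step).
    """

    n_climates: int = 3
    n_treatments: int = 3
    n_blocks: int = 3
    pool_size: int = 14
    pool_overlap: float = 0.4
    abundance_concentration: float = 1.0
    shared_abundances: bool = False
    specific_traits: tuple[str, ...] = ("LA", "SLA", "LDMC")
    pooled_only_traits: tuple[str, ...] = ("LNC", "seed_mass")
    trait_base_log_mean: dict[str, float] = field(
        default_factory=lambda: {
            "LA": np.log(300.0),   # mm^2
            "SLA": np.log(20.0),   # mm^2/mg
            "LDMC": np.log(250.0), # mg/g
            "LNC": np.log(20.0),   # mg/g
            "seed_mass": np.log(1.5),  # mg
        }
    )
    trait_base_log_sd: dict[str, float] = field(
        default_factory=lambda: {t: 0.4 for t in TRAIT_UNITS}
    )
    climate_log_gradient: dict[str, float] = field(
        default_factory=lambda: {
            "LA": -0.40,
            "SLA": -0.25,
            "LDMC": 0.25,
            "LNC": -0.15,
            "seed_mass": 0.10,
        }
    )
    itv_climate: dict[str, float] = field(
        default_factory=lambda: {"LA": 30.0, "SLA": 1.5, "LDMC": 15.0}
    )
    itv_treatment: dict[str, float] = field(
        default_factory=lambda: {"LA": 20.0, "SLA": 1.0, "LDMC": 10.0}
    )
    itv_interaction: dict[str, float] = field(
        default_factory=lambda: {"LA": 10.0, "SLA": 0.5, "LDMC": 5.0}
    )
    itv_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"LA": 15.0, "SLA": 0.8, "LDMC": 8.0}
    )
    covariation_mode: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pool_overlap <= 1.0):
            raise ConfigError(f"pool_overlap must be in [0, 1], got {self.pool_overlap}")
        if self.abundance_concentration <= 0:
            raise ConfigError("abundance_concentration must be positive")
        if self.covariation_mode not in ("independent", "reinforcing", "opposing"):
            raise ConfigError(f"unknown covariation_mode {self.covariation_mode!r}")
        for name in ("trait_base_log_sd", "itv_noise_sd"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ConfigError(f"{name} entries must be >= 0")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")
        shared = round(self.pool_overlap * self.pool_size)
        if self.pool_overlap < 1.0 and shared >= self.pool_size:
            raise ConfigError(
                f"pool_size {self.pool_size} too small to share "
                f"{shared} species while keeping pools distinct"
            )
        if self.shared_abundances and self.pool_overlap != 1.0:
            raise ConfigError("shared_abundances requires pool_overlap = 1")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")

    @property
    def shared_per_pair(self) -> int:
        """Species shared between adjacent climate pools."""
        return round(self.pool_overlap * self.pool_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator decided, for downstream verification."""

    config: SimulationConfig
    pools: dict[str, list[str]]            # climate -> species codes
    home_climate: dict[str, str]           # species -> pool of origin
    base_traits: pd.DataFrame              # species x trait base values
    itv_shift: pd.DataFrame                # (plot_id, trait) -> deterministic shift
    expected_covariation_sign: dict[str, int]  # trait -> -1 / 0 / +1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "pools": self.pools,
            "home_climate": self.home_climate,
            "base_traits": self.base_traits.to_dict(),
            "itv_shift": self.itv_shift.reset_index().to_dict(orient="list"),
            "expected_covariation_sign": self.expected_covariation_sign,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _block_letters(n_climates: int, n_blocks: int) -> list[str]:
    letters = string.ascii_uppercase
    n = n_climates * n_blocks
    if n > len(letters):
        return [f"S{i:02d}" for i in range(n)]
    return list(letters[:n])


_TREAT_SHORT = {"all_herbivores": "all", "wildlife_only": "wild", "no_herbivores": "none"}


def generate(
    config: SimulationConfig,
) -> tuple[PlotDesign, AbundanceMatrix, TraitTable, GroundTruth]:
    """Simulate one experiment; fully deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_climates > len(CLIMATES) or cfg.n_treatments > len(TREATMENTS):
        raise ConfigError("n_climates/n_treatments exceed the factor vocabularies")
    climates = CLIMATES[: cfg.n_climates]
    treatments = TREATMENTS[: cfg.n_treatments]

    # --- species pools along the climate chain: adjacent pools share
    # `shared_per_pair` species, realized by overlapping windows on a global list
    step = cfg.pool_size - cfg.shared_per_pair
    n_species = cfg.pool_size + step * (cfg.n_climates - 1)
    species = [f"sp{i:03d}" for i in range(n_species)]
    pools: dict[str, list[str]] = {}
    home: dict[str, str] = {}
    for c_idx, climate in enumerate(climates):
        members = species[c_idx * step : c_idx * step + cfg.pool_size]
        pools[climate] = members
        for s in members:
            home.setdefault(s, climate)

    # --- base trait values: lognormal around a home-climate-shifted log-mean
    all_traits = tuple(cfg.specific_traits) + tuple(cfg.pooled_only_traits)
    centre = (cfg.n_climates - 1) / 2.0
    base = pd.DataFrame(index=pd.Index(species, name="species"), columns=all_traits, dtype=float)
    for trait in all_traits:
        mu0 = cfg.trait_base_log_mean[trait]
        sd = cfg.trait_base_log_sd[trait]
        grad = cfg.climate_log_gradient.get(trait, 0.0)
        for s in species:
            c_idx = climates.index(home[s])
            mu = mu0 + grad * (c_idx - centre)
            base.loc[s, trait] = float(rng.lognormal(mean=mu, sigma=sd))

    # --- plot design
    rows = []
    letters = _block_letters(cfg.n_climates, cfg.n_blocks)
    for c_idx, climate in enumerate(climates):
        for b_idx in range(cfg.n_blocks):
            letter = letters[c_idx * cfg.n_blocks + b_idx]
            for treatment in treatments:
                plot_id = f"{climate[:3]}_{_TREAT_SHORT[treatment]}_{letter}"
                rows.append(
                    {"plot_id": plot_id, "climate": climate, "treatment": treatment, "block": letter}
                )
    design = PlotDesign(pd.DataFrame(rows))

    # --- abundances: symmetric Dirichlet over the climate pool, scaled to % cover
    ab = pd.DataFrame(
        0.0, index=pd.Index(design.plot_ids, name="plot_id"), columns=species
    )
    shared_draw: np.ndarray | None = None
    if cfg.shared_abundances:
        shared_draw = rng.dirichlet(np.full(cfg.pool_size, cfg.abundance_concentration))
    for plot_id in design.plot_ids:
        climate, _, _ = design.factors(plot_id)
        members = pools[climate]
        if shared_draw is not None:
            draw = shared_draw
        else:
            draw = rng.dirichlet(np.full(len(members), cfg.abundance_concentration))
        ab.loc[plot_id, members] = draw * 100.0
    abundance = AbundanceMatrix(ab)

    # --- intraspecific shifts: deterministic part per (plot, trait) + noise
    def _align(trait: str) -> float:
        grad_sign = np.sign(cfg.climate_log_gradient.get(trait, 0.0)) or 1.0
        if cfg.covariation_mode == "reinforcing":
            return float(grad_sign)
        if cfg.covariation_mode == "opposing":
            return float(-grad_sign)
        return 1.0

    shift_rows = []
    for plot_id in design.plot_ids:
        climate, treatment, _ = design.factors(plot_id)
        u = climates.index(climate) - centre
        v = treatments.index(treatment) - (cfg.n_treatments - 1) / 2.0
        for trait in cfg.specific_traits:
            shift = (
                _align(trait) * cfg.itv_climate.get(trait, 0.0) * u
                + cfg.itv_treatment.get(trait, 0.0) * v
                + cfg.itv_interaction.get(trait, 0.0) * u * v
            )
            shift_rows.append({"plot_id": plot_id, "trait": trait, "shift": shift})
    itv_shift = pd.DataFrame(shift_rows).set_index(["plot_id", "trait"])["shift"]

    # --- plot-specific trait records; floor keeps values positive when a
    # negative shift would otherwise overwhelm a small base value
    trait_rows = []
    for plot_id in design.plot_ids:
        present = abundance.present_species(plot_id)
        for trait in cfg.specific_traits:
            det = itv_shift.loc[(plot_id, trait)]
            noise_sd = cfg.itv_noise_sd.get(trait, 0.0)
            for s in present:
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                value = base.loc[s, trait] + det + noise
                value = max(value, 0.05 * base.loc[s, trait])
                trait_rows.append(
                    {"species": s, "plot_id": plot_id, "trait": trait, "value": value}
                )
    for trait in cfg.pooled_only_traits:
        for s in species:
            trait_rows.append(
                {"species": s, "plot_id": POOLED, "trait": trait, "value": base.loc[s, trait]}
            )
    traits = TraitTable(pd.DataFrame(trait_rows)).with_pooled()

    expected_sign = {
        t: {"independent": 0, "reinforcing": 1, "opposing": -1}[cfg.covariation_mode]
        for t in cfg.specific_traits
    }
    truth = GroundTruth(
        config=cfg,
        pools=pools,
        home_climate=home,
        base_traits=base,
        itv_shift=itv_shift.to_frame(),
        expected_covariation_sign=expected_sign,
    )
    return design, abundance, traits, truth


_REGIMES = ("turnover_only", "itv_only", "mixed_positive", "mixed_negative")


def regime(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Preset configurations exercising one decomposition regime.

    ``turnover_only`` zeroes every intraspecific effect, ``itv_only`` shares a
    single pool and abundance vector across all plots (so turnover vanishes),
    and the two ``mixed_*`` presets set the covariation mode.
    """
    if name not in _REGIMES:
        raise ValidationError(f"unknown regime {name!r}; expected one of {_REGIMES}")
    kw: dict = {"seed": seed}
    if name == "turnover_only":
        zero = {t: 0.0 for t in ("LA", "SLA", "LDMC")}
        kw.update(itv_climate=zero, itv_treatment=dict(zero),
                  itv_interaction=dict(zero), itv_noise_sd=dict(zero))
    elif name == "itv_only":
        kw.update(
            pool_overlap=1.0,
            shared_abundances=True,
            climate_log_gradient={t: 0.0 for t in TRAIT_UNITS},
        )
    elif name == "mixed_positive":
        kw.update(covariation_mode="reinforcing")
    elif name == "mixed_negative":
        kw.update(covariation_mode="opposing")
    kw.update(overrides)
    return SimulationConfig(**kw)


def write_outputs(
    out_dir: str | Path,
    design: PlotDesign,
    abundance: AbundanceMatrix,
    traits: TraitTable,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the canonical CSV trio plus ground_truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "plots": out / "plots.csv",
        "abundance": out / "abundance.csv",
        "traits": out / "traits.csv",
        "ground_truth": out / "ground_truth.json",
    }
    design.to_csv(paths["plots"])
    abundance.to_csv(paths["abundance"])
    traits.to_csv(paths["traits"])
    truth.to_json(paths["ground_truth"])
    return paths
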