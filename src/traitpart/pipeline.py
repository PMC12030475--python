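"""One-command pipeline: data -> filter -> CWM -> FD -> decomposition ->
dissimilarity/ANOSIM -> mixed models, with a run manifest for provenance.

The pipeline is pure with respect to its configuration: every random
operation draws from an explicit seed recorded in the manifest, and rerunning
with the same configuration reproduces deterministic stage outputs
byte-for-byte (content hashes in the manifest make this checkable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cwm import cwm_table
from .data_model import (
    CommonSpeciesFilter,
    PlotDesign,
    TraitTable,
    ValidationError,
    read_tables,
)
from .decomposition import decompose_all
from .dissimilarity import jaccard_matrix, run_study_anosims
from .fd import fd_table
from .models import analyse_response
from .synthetic import SimulationConfig, generate, regime, write_outputs

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and entity."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)      # stage -> {path: hash}
    timings: dict = field(default_factory=dict)      # stage -> seconds

    def record(self, stage: str, paths: dict[str, Path], elapsed: float) -> None:
        self.outputs[stage] = {str(p): _sha256(Path(p)) for p in paths.values()}
        self.timings[stage] = round(elapsed, 4)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_all(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    ``config["data"]`` either names a synthetic regime (``regime`` plus
    optional generator overrides) or points at the three canonical CSVs
    (``plots``/``abundance``/``traits`` with an optional column ``mapping``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)

    # --- data
    data_cfg = dict(config.get("data") or {"regime": "mixed_positive"})
    t0 = time.perf_counter()
    if "regime" in data_cfg or "simulate" in data_cfg:
        name = data_cfg.pop("regime", None)
        data_cfg.pop("simulate", None)
        if name:
            sim_cfg = regime(name, seed=seed, **data_cfg)
        else:
            sim_cfg = SimulationConfig(seed=seed, **data_cfg)
        design, abundance, traits, truth = generate(sim_cfg)
        paths = write_outputs(out, design, abundance, traits, truth)
        manifest.record("simulate", paths, time.perf_counter() - t0)
    else:
        tables = read_tables(
            data_cfg["plots"], data_cfg["abundance"], data_cfg["traits"],
            mapping=data_cfg.get("mapping"),
        )
        design, abundance, traits = tables.design, tables.abundance, tables.traits
        if not tables.report.clean:
            log.warning("reconciliation report: %s", tables.report)
        manifest.input_hashes = {
            k: _sha256(Path(data_cfg[k])) for k in ("plots", "abundance", "traits")
        }
        manifest.timings["load"] = round(time.perf_counter() - t0, 4)

    threshold = float((config.get("filter") or {}).get("coverage_threshold", 0.90))
    species_filter = CommonSpeciesFilter(threshold)

    # --- CWMs
    t0 = time.perf_counter()
    cwms = cwm_table(
        design, abundance, traits, species_filter=species_filter,
        normalize=bool((config.get("cwm") or {}).get("normalize", True)),
    )
    cwm_path = out / "cwm.csv"
    cwms.to_csv(cwm_path)
    manifest.record("cwm", {"cwm": cwm_path}, time.perf_counter() - t0)

    # --- functional diversity
    t0 = time.perf_counter()
    geometry = (config.get("fd") or {}).get("geometry", "gower-pcoa")
    fd = fd_table(design, abundance, traits, species_filter=species_filter,
                  geometry=geometry)
    fd_path = out / "fd.csv"
    fd.to_csv(fd_path)
    manifest.record("fd", {"fd": fd_path}, time.perf_counter() - t0)

    # --- turnover / ITV decomposition
    t0 = time.perf_counter()
    dec_cfg = config.get("decomposition") or {}
    dec = decompose_all(
        cwms, design, mode=dec_cfg.get("mode", "anova"),
        n_permutations=int(dec_cfg.get("n_permutations", 999)), seed=seed,
    )
    dec_path = out / "decomposition.csv"
    dec.to_csv(dec_path, index=False)
    manifest.record("decomposition", {"decomposition": dec_path}, time.perf_counter() - t0)

    # --- dissimilarity + ANOSIM
    t0 = time.perf_counter()
    d = jaccard_matrix(abundance, species_filter)
    d_path = out / "dissimilarity.csv"
    d.to_csv(d_path)
    an_cfg = config.get("anosim") or {}
    results = run_study_anosims(
        d, design, n_permutations=int(an_cfg.get("n_permutations", 999)), seed=seed
    )
    an_path = out / "anosim.json"
    an_path.write_text(json.dumps(
        {k: dataclasses.asdict(v) for k, v in results.items()}, indent=2, sort_keys=True
    ))
    manifest.record("anosim", {"dissimilarity": d_path, "anosim": an_path},
                    time.perf_counter() - t0)

    # --- mixed models
    t0 = time.perf_counter()
    model_data = design.table.copy()
    spec_wide = cwms.wide("specific")
    for trait in spec_wide.columns:
        model_data[f"CWM_{trait}"] = spec_wide[trait]
    for metric in ("FRic", "FEve", "FDiv", "FDis"):
        model_data[metric] = fd[metric]
    responses = (config.get("models") or {}).get("responses")
    if not responses:
        responses = [c for c in model_data.columns if c.startswith("CWM_")] + \
                    ["FRic", "FEve", "FDiv", "FDis"]
    sel_tables, contrast_tables = [], []
    for response in responses:
        sub = model_data.dropna(subset=[response]).reset_index()
        if len(sub) < 12:
            log.warning("response %s: too few complete plots (%d), skipped",
                        response, len(sub))
            continue
        try:
            sel, _, contrasts = analyse_response(response, sub)
        except (ValidationError, ValueError) as err:
            raise StageError(f"stage 'models' failed on response {response!r}: {err}")
        tab = sel.table
        tab.insert(0, "response", response)
        sel_tables.append(tab)
        if len(contrasts):
            contrasts.insert(0, "response", response)
            contrast_tables.append(contrasts)
    sel_path = out / "selection.csv"
    pd.concat(sel_tables, ignore_index=True).to_csv(sel_path, index=False)
    con_path = out / "contrasts.csv"
    if contrast_tables:
        pd.concat(contrast_tables, ignore_index=True).to_csv(con_path, index=False)
    else:
        pd.DataFrame().to_csv(con_path, index=False)
    manifest.record("models", {"selection": sel_path, "contrasts": con_path},
                    time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest
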