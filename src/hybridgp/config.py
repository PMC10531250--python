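"""Run configuration: schema validation, seed derivation, pipeline driver.

A run is described by one YAML/JSON document.  Either a ``sim`` block
(synthetic-data settings) or an ``inputs`` block (paths to marker,
pedigree and phenotype CSVs) provides the data; ``strategies``,
``kernels``, ``cv`` and ``mcmc`` control the evaluation grid.  A single
master seed deterministically derives every stage seed through a
counter-based scheme, so one integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import yaml

from .bayes import MCMCSettings
from .covariates import STRATEGIES
from .evaluation import (
    aggregate_and_report,
    make_cv_folds,
    prepare_inputs,
    run_strategy_grid,
)
from .kernels import KERNEL_NAMES, KernelSpec
from .markers import read_marker_csv
from .simulate import SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger("hybridgp")

#: informal JSON-schema of the run config (documented in docs/methods.md)
CONFIG_SCHEMA = {
    "sim": "optional mapping of SimConfig fields",
    "inputs": "optional mapping: markers_male, markers_female, pedigree, phenotypes (CSV paths)",
    "traits": "optional list of trait names (default GY, DTF, DTH)",
    "strategies": f"subset of {list(STRATEGIES)}",
    "kernels": f"list of mappings with name in {list(KERNEL_NAMES)} (+gamma/degree)",
    "cv": "mapping: k (folds, default 7)",
    "mcmc": "mapping: iterations, burn_in, thin",
    "out_dir": "output directory",
    "seed": "master seed (integer)",
}


class ConfigError(ValueError):
    """Configuration failed validation; the message names the field."""


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "hybridgp_out"
    sim: SimConfig | None = None
    inputs: dict | None = None
    traits: list[str] = dataclasses.field(default_factory=lambda: ["GY", "DTF", "DTH"])
    strategies: list[str] = dataclasses.field(default_factory=lambda: list(STRATEGIES))
    kernels: list[KernelSpec] = dataclasses.field(default_factory=lambda: [KernelSpec("linear")])
    cv_k: int = 7
    mcmc: MCMCSettings = dataclasses.field(default_factory=MCMCSettings)


def derive_seed(master: int, stage: int) -> int:
    """Counter-based stage seed, always below 2**31."""
    return int(np.random.SeedSequence([int(master), int(stage)]).generate_state(1)[0] % (2**31))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(pathlib.Path(path).read_text())
    return parse_config(raw or {})


def parse_config(raw: dict) -> RunConfig:
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    strategies = raw.get("strategies", list(STRATEGIES))
    for s in strategies:
        if s not in STRATEGIES:
            raise ConfigError(f"strategies: unknown strategy {s!r}; choose from {list(STRATEGIES)}")
    kernels = []
    for kdef in raw.get("kernels", [{"name": "linear"}]):
        if isinstance(kdef, str):
            kdef = {"name": kdef}
        name = kdef.get("name")
        if name not in KERNEL_NAMES:
            raise ConfigError(f"kernels: unknown kernel name {name!r}; choose from {list(KERNEL_NAMES)}")
        kernels.append(KernelSpec(**kdef))
    mcmc_raw = raw.get("mcmc", {})
    try:
        mcmc = MCMCSettings(**mcmc_raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"mcmc: {e}") from e
    sim = None
    if "sim" in raw:
        try:
            sim = SimConfig(**raw["sim"])
        except (TypeError, ValueError) as e:
            raise ConfigError(f"sim: {e}") from e
    inputs = raw.get("inputs")
    if sim is None and inputs is None:
        raise ConfigError("config needs either a 'sim' or an 'inputs' block")
    if inputs is not None:
        needed = {"markers_male", "markers_female", "pedigree", "phenotypes"}
        missing = needed - set(inputs)
        if missing:
            raise ConfigError(f"inputs: missing path(s) {sorted(missing)}")
    cv_k = int(raw.get("cv", {}).get("k", 7))
    if cv_k < 2:
        raise ConfigError("cv.k: must be >= 2")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "hybridgp_out")),
        sim=sim,
        inputs=inputs,
        traits=list(raw.get("traits", ["GY", "DTF", "DTH"])),
        strategies=list(strategies),
        kernels=kernels,
        cv_k=cv_k,
        mcmc=mcmc,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """simulate/load -> prepare -> cross-validate -> report; returns manifest."""
    import pandas as pd

    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=derive_seed(cfg.seed, 0))
        data = simulate_dataset(sim_cfg)
        write_dataset(data, out / "data")
        males, females, ped, phenos = data.males, data.females, data.ped, data.phenos
        traits = list(sim_cfg.traits)
    else:
        males = read_marker_csv(cfg.inputs["markers_male"])
        females = read_marker_csv(cfg.inputs["markers_female"])
        ped = pd.read_csv(cfg.inputs["pedigree"])
        phenos = pd.read_csv(cfg.inputs["phenotypes"])
        traits = cfg.traits

    prep = prepare_inputs(
        males,
        females,
        ped,
        phenos,
        traits,
        bv_mcmc=MCMCSettings(
            iterations=max(cfg.mcmc.iterations, 1000),
            burn_in=max(cfg.mcmc.burn_in, 400),
            thin=cfg.mcmc.thin,
            seed=derive_seed(cfg.seed, 1),
        ),
    )
    hybrids = sorted(set(prep.design["obs"]["entry_id"].astype(str)))
    cv = make_cv_folds(hybrids, k=cfg.cv_k, seed=derive_seed(cfg.seed, 2))
    mcmc = dataclasses.replace(cfg.mcmc, seed=derive_seed(cfg.seed, 3))
    res = run_strategy_grid(prep, cv, strategies=cfg.strategies, kernels=cfg.kernels, mcmc=mcmc)
    written = aggregate_and_report(res, out)

    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {s: derive_seed(cfg.seed, i) for i, s in enumerate(["sim", "bv", "cv", "mcmc"])},
        "strategies": cfg.strategies,
        "kernels": [k.name for k in cfg.kernels],
        "cv_k": cfg.cv_k,
        "mcmc": dataclasses.asdict(cfg.mcmc),
        "artifacts": {k: str(v) for k, v in written.items()},
        "failures": res.failures,
        "artifact_hashes": {
            k: hashlib.sha256(pathlib.Path(v).read_bytes()).hexdigest()[:16]
            for k, v in written.items()
            if str(v).endswith(".csv")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
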