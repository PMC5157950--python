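"""Configuration loading, RNG plumbing and result serialization.

Run configurations are plain key-value documents (YAML or JSON — YAML is a
superset, one parser handles both).  Every life-history constant carries a
provenance tag: ``"paper"`` when the published model prints the value
(s, T_sur, the beta and nu coefficients, the c range, R0, initial cell
counts), ``"assumed"`` for the order-of-magnitude defaults (delta, tau, mu,
R_half).  The full effective configuration, tags included, is echoed next to
every result file so a run can be reproduced from its output directory alone.

Reproducibility: a single master seed is turned into independent named
streams with :func:`seeded_rng`; the same (seed, label) pair is bitwise
reproducible and distinct labels are statistically independent.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .evolution import EnvironmentSpec, EvolutionResult
from .life_history import (
    ConfigurationError,
    Genotype,
    GenotypeGridSpec,
    LifeHistoryParams,
)

__all__ = [
    "PARAM_SOURCES",
    "AssaySettings",
    "RunConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "seeded_rng",
    "write_results",
    "genotypes_to_frame",
    "frame_to_genotypes",
]

FLOAT_FMT = "%.12g"  # 12 significant digits in every CSV cell

# provenance of each life-history default
PARAM_SOURCES: dict[str, str] = {
    "s": "paper",
    "delta": "assumed",
    "tau": "assumed",
    "mu": "assumed",
    "T_sur": "paper",
    "beta_b0": "paper",
    "beta_b1": "paper",
    "nu_a0": "paper",
    "nu_a1": "paper",
    "R_half": "assumed",
    "c_min": "paper",
    "c_max": "paper",
}


@dataclass(frozen=True)
class AssaySettings:
    """Initial densities and protocol for the chimera assays."""

    X0_values: tuple[float, ...] = (1e3, 1e7, 1e10)
    R0: float = 1e8
    mode: str = "GS"

    def __post_init__(self) -> None:
        if self.mode not in ("S", "GS"):
            raise ConfigurationError(f"assay mode must be 'S' or 'GS', got {self.mode!r}")
        if any(x <= 0 for x in self.X0_values) or self.R0 <= 0:
            raise ConfigurationError("assay densities must be > 0")


@dataclass
class RunConfig:
    """Validated bundle of everything a simulation campaign needs."""

    params: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    grid: GenotypeGridSpec = field(default_factory=GenotypeGridSpec)
    environments: list[EnvironmentSpec] = field(default_factory=list)
    assay: AssaySettings = field(default_factory=AssaySettings)
    seed: int = 0
    preset: str = "reduced"
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.preset not in ("paper", "reduced"):
            raise ConfigurationError(f"preset must be 'paper' or 'reduced', got {self.preset!r}")


def _build_section(cls, data: dict, section: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"bad key under '{section}': {exc}") from None
    except (ConfigurationError, ValueError) as exc:
        raise ConfigurationError(f"invalid '{section}' configuration: {exc}") from None


def _grid_from_dict(data: dict) -> GenotypeGridSpec:
    data = dict(data)
    if "trait_segments" in data:
        data["trait_segments"] = tuple(tuple(seg) for seg in data["trait_segments"])
    if "c_range" in data:
        data["c_range"] = tuple(data["c_range"])
    return _build_section(GenotypeGridSpec, data, "grid")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON configuration file into a validated RunConfig.

    Missing sections fall back to the defaults; an empty file yields the full
    default configuration.  Schema and range violations raise
    :class:`ConfigurationError` naming the offending section.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    known = {"life_history", "grid", "environments", "assay", "seed", "preset", "outdir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    params = _build_section(LifeHistoryParams, data.get("life_history", {}), "life_history")
    grid = _grid_from_dict(data.get("grid", {}))
    envs = [
        _build_section(EnvironmentSpec, e, f"environments[{i}]")
        for i, e in enumerate(data.get("environments", []))
    ]
    assay_data = dict(data.get("assay", {}))
    if "X0_values" in assay_data:
        assay_data["X0_values"] = tuple(assay_data["X0_values"])
    assay = _build_section(AssaySettings, assay_data, "assay")
    return RunConfig(
        params=params,
        grid=grid,
        environments=envs,
        assay=assay,
        seed=int(data.get("seed", 0)),
        preset=str(data.get("preset", "reduced")),
        outdir=str(data.get("outdir", "results")),
    )


def config_to_dict(cfg: RunConfig, tag_sources: bool = True) -> dict[str, Any]:
    """Serializable effective configuration, provenance tags included."""
    lh: dict[str, Any] = {}
    for f in dataclasses.fields(LifeHistoryParams):
        value = getattr(cfg.params, f.name)
        if tag_sources:
            source = PARAM_SOURCES.get(f.name, "assumed")
            if value != f.default:
                source = "user"
            lh[f.name] = {"value": value, "source": source}
        else:
            lh[f.name] = value
    return {
        "life_history": lh,
        "grid": {
            "mechanism": cfg.grid.mechanism,
            "trait_segments": [list(s) for s in cfg.grid.trait_segments],
            "c_range": list(cfg.grid.c_range),
        },
        "environments": [dataclasses.asdict(e) for e in cfg.environments],
        "assay": {
            "X0_values": list(cfg.assay.X0_values),
            "R0": cfg.assay.R0,
            "mode": cfg.assay.mode,
        },
        "seed": cfg.seed,
        "preset": cfg.preset,
        "outdir": cfg.outdir,
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(config_to_dict(cfg, tag_sources=False), indent=2, sort_keys=True)
    )


def seeded_rng(master_seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream derived from (master seed, label).

    The label is hashed (CRC-32) into the spawn key of a
    :class:`numpy.random.SeedSequence`, so streams for different labels are
    statistically independent while the same pair is bitwise reproducible.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# genotype table I/O


def genotypes_to_frame(genotypes: Sequence[Genotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        rows.append(
            {
                "mechanism": g.mechanism,
                "alpha": g.alpha if g.mechanism == "discrete" else np.nan,
                "gamma": g.gamma if g.mechanism == "continuous" else np.nan,
                "c": g.c,
            }
        )
    return pd.DataFrame(rows, columns=["mechanism", "alpha", "gamma", "c"])


def frame_to_genotypes(df: pd.DataFrame) -> list[Genotype]:
    out = []
    for _, row in df.iterrows():
        mech = str(row["mechanism"])
        if mech == "discrete":
            out.append(Genotype("discrete", c=float(row["c"]), alpha=float(row["alpha"])))
        else:
            out.append(Genotype("continuous", c=float(row["c"]), gamma=float(row["gamma"])))
    return out


# ---------------------------------------------------------------------------
# result writing


def _winner_frame(results: Sequence[EvolutionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        env = res.environment
        w = res.winner
        rows.append(
            {
                "kind": env.kind,
                "timescale_h": env.timescale,
                "mechanism": w.mechanism,
                "winner_trait": w.trait,
                "winner_c": w.c,
                "winner_rel_abundance": float(res.relative_abundance[res.winner_index]),
                "n_runs": env.n_runs if env.kind == "stochastic" else 1,
                "mean_cycles": res.n_cycles,
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[EvolutionResult],
    cfg: RunConfig,
    outdir: str | Path,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the winner table (CSV), and run metadata + the effective config
    (JSON) into ``outdir``.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    winners = outdir / "winners.csv"
    _winner_frame(results).to_csv(winners, index=False, float_format=FLOAT_FMT)
    paths["winners"] = winners
    meta = {
        "seed": cfg.seed,
        "config": config_to_dict(cfg),
        "environments_run": [r.environment.describe() for r in results],
        "per_run_winners": [
            [g.label() for g in r.per_run_winners] for r in results
        ],
    }
    if extra_metadata:
        meta.update(extra_metadata)
    metapath = outdir / "metadata.json"
    metapath.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["metadata"] = metapath
    return paths


def write_matrix_csv(
    matrix: np.ndarray, genotypes: Sequence[Genotype], path: str | Path
) -> None:
    """Square pairwise matrix as labelled CSV (12 significant digits)."""
    labels = [g.label() for g in genotypes]
    df = pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)
    df.to_csv(path, float_format=FLOAT_FMT)
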