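"""Configuration files, TSV logs and snapshots, fixtures, run manifests.

All on-disk formats are plain text: a YAML key-value config, tab-separated
generation logs and genome snapshots (floats written with 17 significant
digits so they round-trip bit-exactly), and a JSON run manifest holding the
config, seed and termination reason needed to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import (
    A_ALLELE,
    R_ALLELE,
    Genome,
    locus_names,
)
from .simulate import (
    ConfigError,
    GenerationRecord,
    Population,
    RunResult,
    SimulationConfig,
)

__all__ = [
    "ParseError",
    "load_config",
    "save_config",
    "fixture_genomes",
    "write_generation_log",
    "read_generation_log",
    "write_snapshot",
    "read_snapshot",
    "write_run",
    "write_run_manifest",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A log or snapshot file is malformed."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: Optional[str | Path] = None, **overrides) -> SimulationConfig:
    """Load a simulation config from a YAML document.

    Unspecified fields take the standard defaults (population 500, phi = 3,
    epsilon = 1.5, abruptness = 2.5, the printed mutation rates, and the
    20k/80k/100k phase schedule).  An empty document yields the full default
    config.  Unknown or out-of-range fields raise `ConfigError` naming the
    field.
    """
    data: Dict[str, object] = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update(overrides)
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    if "resource_values" in data:
        data["resource_values"] = tuple(float(v) for v in data["resource_values"])  # type: ignore[arg-type]
    if "signals" in data:
        data["signals"] = tuple(tuple(float(c) for c in s) for s in data["signals"])  # type: ignore[arg-type]
    try:
        config = SimulationConfig(**data)  # type: ignore[arg-type]
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return config.validate()


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as YAML; `load_config` round-trips it exactly."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=None)
    )


# ---------------------------------------------------------------------------
# Fixture genomes
# ---------------------------------------------------------------------------

def _weights_from(assignments: Dict[str, float], n_hidden: int = 3) -> np.ndarray:
    names = locus_names(n_hidden)
    w = np.zeros(len(names))
    for key, value in assignments.items():
        w[names.index(key)] = value
    return w


def _specialist1_weights() -> np.ndarray:
    # hidden node 1 switches on below s1 = 0.3; output fires only then
    return _weights_from({"w11": -20.0, "bh1": -6.0, "wout1": 20.0, "bo": 10.0})


def _specialist3_weights() -> np.ndarray:
    # node 1 on above s1 = 0.5, node 2 on above s1 = 0.7; output = node1 AND NOT node2
    return _weights_from(
        {
            "w11": 20.0,
            "bh1": 10.0,
            "w12": 20.0,
            "bh2": 14.0,
            "wout1": 20.0,
            "wout2": -20.0,
            "bo": 10.0,
        }
    )


def _generalist_weights() -> np.ndarray:
    # constitutively excited output node: prefers every niche
    return _weights_from({"bo": -10.0})


_FIXTURE_KINDS = ("specialist1", "specialist3", "generalist", "heterozygote")


def fixture_genomes(
    kind: str,
    n: int,
    rng: Optional[np.random.Generator] = None,
    jitter: float = 0.0,
    mating: Sequence[str] = (R_ALLELE, R_ALLELE),
) -> List[Genome]:
    """Hand-constructed genomes whose rounded response arrays equal a known
    phenotype class under the default signals.

    kinds: ``specialist1`` ([1,0,0,0]), ``specialist3`` ([0,0,1,0]),
    ``generalist`` ([1,1,1,1]), and ``heterozygote`` — two distinct
    haplotypes averaging to the specialist-1 weights (class [1,0,0,0],
    silent variation on the unused third super-gene).

    ``jitter`` adds uniform(-jitter, jitter) noise to every allele (the
    classes above are robust to jitter <= 0.5).
    """
    if kind == "specialist1":
        haps = (_specialist1_weights(), _specialist1_weights())
    elif kind == "specialist3":
        haps = (_specialist3_weights(), _specialist3_weights())
    elif kind == "generalist":
        haps = (_generalist_weights(), _generalist_weights())
    elif kind == "heterozygote":
        base = _specialist1_weights()
        delta = _weights_from({"w13": 3.0, "w23": -3.0, "bh3": 2.0})
        haps = (base + delta, base - delta)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_FIXTURE_KINDS}")
    if jitter > 0 and rng is None:
        raise ValueError("jitter > 0 requires an rng")
    genomes = []
    for _ in range(n):
        pref = np.stack(haps)
        if jitter > 0:
            pref = pref + rng.uniform(-jitter, jitter, size=pref.shape)
        genomes.append(Genome(pref, tuple(mating)))
    return genomes


# ---------------------------------------------------------------------------
# Generation logs
# ---------------------------------------------------------------------------

def write_generation_log(records: Sequence[GenerationRecord], path: str | Path) -> None:
    """Write per-generation records as a TSV with a header row."""
    df = pd.DataFrame([r.as_row() for r in records], columns=list(GenerationRecord.FIELDS))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_generation_log(path: str | Path) -> pd.DataFrame:
    """Read a generation log back into a DataFrame."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises various parse errors
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(GenerationRecord.FIELDS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Genome snapshots
# ---------------------------------------------------------------------------

def _snapshot_columns(n_loci: int) -> List[str]:
    return (
        ["id"]
        + [f"hap1_{i}" for i in range(n_loci)]
        + [f"hap2_{i}" for i in range(n_loci)]
        + ["mating1", "mating2"]
    )


def write_snapshot(population: Population, path: str | Path) -> None:
    """Serialise a population: one tab-separated row per individual —
    id, the 13 alleles of each haplotype (full precision), and the two
    mating alleles as r/a characters."""
    n, L = len(population), population.n_loci
    alleles = np.array([R_ALLELE, A_ALLELE])
    cols = _snapshot_columns(L)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(n):
            row = [str(i)]
            row += [_FLOAT_FMT % v for v in population.pref[i, 0]]
            row += [_FLOAT_FMT % v for v in population.pref[i, 1]]
            row += [alleles[population.mating[i, 0]], alleles[population.mating[i, 1]]]
            fh.write("\t".join(row) + "\n")


def read_snapshot(path: str | Path) -> Population:
    """Parse a snapshot back into a Population (bit-exact round trip)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty snapshot file")
    header = lines[0].split("\t")
    n_cols = len(header)
    if n_cols < 7 or (n_cols - 3) % 2 != 0:
        raise ParseError(f"{path}: line 1: malformed snapshot header")
    L = (n_cols - 3) // 2
    if header != _snapshot_columns(L):
        raise ParseError(f"{path}: line 1: unexpected snapshot columns")
    pref = np.empty((len(lines) - 1, 2, L))
    mating = np.empty((len(lines) - 1, 2), dtype=np.int8)
    code = {R_ALLELE: 0, A_ALLELE: 1}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols} fields, got {len(parts)}"
            )
        i = lineno - 2
        try:
            pref[i, 0] = [float(v) for v in parts[1 : 1 + L]]
            pref[i, 1] = [float(v) for v in parts[1 + L : 1 + 2 * L]]
            mating[i] = [code[parts[-2]], code[parts[-1]]]
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return Population(pref, mating)


# ---------------------------------------------------------------------------
# Whole-run output + manifest
# ---------------------------------------------------------------------------

def write_run_manifest(
    result: RunResult,
    outdir: str | Path,
    files: Sequence[str],
) -> Path:
    from . import __version__

    manifest = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "version": __version__,
        "termination": result.termination,
        "n_generations_recorded": len(result.records),
        "files": sorted(files),
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_run(result: RunResult, outdir: str | Path) -> Dict[str, Path]:
    """Write a run's generation log, snapshots, config and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}
    log_path = outdir / "generations.tsv"
    write_generation_log(result.records, log_path)
    files["generations"] = log_path
    for gen, pop in sorted(result.snapshots.items()):
        snap_path = outdir / f"snapshot_{gen:06d}.tsv"
        write_snapshot(pop, snap_path)
        files[f"snapshot_{gen}"] = snap_path
    cfg_path = outdir / "config.yaml"
    save_config(result.config, cfg_path)
    files["config"] = cfg_path
    files["manifest"] = write_run_manifest(
        result, outdir, [p.name for p in files.values()]
    )
    return files
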