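"""Experiment drivers: single-trigger traces, removal-fraction sweeps,
failed-edge category censuses and realization averaging.

Two designs are provided.  ``single_trigger_experiment`` removes the single
highest-load edge of each realization and follows the driver-node count and
the SCC edge count stage by stage through the resulting cascade — the
stage-aligned, realization-averaged trace shows where along a cascade
controllability is lost.  ``fraction_sweep`` removes a fraction ``f`` of
edges under random (RA) and intentional (IA) attack for a grid of ``f``,
runs the cascade to termination, and records the final driver count, the
number of overload-failed edges and the census of failed edges over the
three controllability categories (computed on the intact, pre-attack graph,
so the census reflects what was destroyed, not a moving baseline).

All randomness descends from one master seed via ``numpy.random.SeedSequence``
spawning, so a config + master seed reproduces every number byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .attacks import (
    INTENTIONAL,
    RANDOM,
    select_edges_intentional,
    select_edges_random,
    select_highest_load_edge,
)
from .cascade import CascadeTrace, assign_capacities, compute_loads, run_cascade
from .controllability import (
    CRITICAL,
    ORDINARY,
    REDUNDANT,
    EdgeClassification,
    classify_edges,
    driver_report,
)
from .generators import GeneratorSpec, generate
from .graph_core import DirectedGraph, Edge, read_edge_list, scc_edge_count

__all__ = [
    "ExperimentConfig",
    "TriggerResult",
    "SweepResult",
    "CensusResult",
    "single_trigger_experiment",
    "fraction_sweep",
    "failed_edge_census",
    "aggregate_realizations",
    "critical_fraction",
]

# 0.0 .. 1.0; the upper end is needed to observe the cascade-free region
# (under moderate tolerance RA-triggered cascades persist past f = 0.8)
_DEFAULT_F_GRID = tuple(round(0.05 * i, 2) for i in range(21))


@dataclass(frozen=True)
class ExperimentConfig:
    """Reproducible description of one experiment.

    Exactly one of ``generator`` / ``input_path`` must be set.  With a
    generator, each realization draws a fresh graph from a seed derived from
    ``master_seed``; with an input file the graph is fixed and only the
    attack randomness varies across realizations.
    """

    generator: GeneratorSpec | None = None
    input_path: str | None = None
    alpha: float = 0.3
    strategies: tuple[str, ...] = (RANDOM, INTENTIONAL)
    f_grid: tuple[float, ...] = _DEFAULT_F_GRID
    n_realizations: int = 50
    master_seed: int = 0
    fractional_load: bool = False
    largest_scc_only: bool = False

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_path is None):
            raise ValueError("set exactly one of generator / input_path")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for s in self.strategies:
            if s not in (RANDOM, INTENTIONAL):
                raise ValueError(f"unknown sweep strategy {s!r}")
        for f in self.f_grid:
            if not 0.0 <= f <= 1.0:
                raise ValueError("f_grid values must lie in [0, 1]")

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "input_path": self.input_path,
            "alpha": self.alpha,
            "strategies": list(self.strategies),
            "f_grid": list(self.f_grid),
            "n_realizations": self.n_realizations,
            "master_seed": self.master_seed,
            "fractional_load": self.fractional_load,
            "largest_scc_only": self.largest_scc_only,
        }
        if self.generator is not None:
            g = self.generator
            d["generator"] = {
                "model": g.model,
                "n": g.n,
                "mean_degree": g.mean_degree,
                "gamma": g.gamma,
                "seed": g.seed,
            }
        else:
            d["generator"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        if gen is not None:
            gen = GeneratorSpec(**gen)
        known = {
            k: d[k]
            for k in (
                "input_path",
                "alpha",
                "n_realizations",
                "master_seed",
                "fractional_load",
                "largest_scc_only",
            )
            if k in d
        }
        if "strategies" in d:
            known["strategies"] = tuple(d["strategies"])
        if "f_grid" in d:
            known["f_grid"] = tuple(d["f_grid"])
        return cls(generator=gen, **known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _derived_seed(*entropy: int) -> int:
    """Deterministic sub-seed below 2**31 from an entropy tuple."""
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def _graph_for(config: ExperimentConfig, realization: int) -> DirectedGraph:
    if config.input_path is not None:
        return read_edge_list(config.input_path)
    seed = _derived_seed(config.master_seed, 1, realization)
    return generate(replace(config.generator, seed=seed))


def _manifest(config: ExperimentConfig) -> dict:
    return {"package": "ctrlcascade", "version": __version__, "config": config.to_dict()}


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, 0.0
    return mean, float(np.std(values, ddof=1) / np.sqrt(len(values)))


# -- single highest-load-edge trigger ------------------------------------


@dataclass(frozen=True)
class TriggerResult:
    """Stage-averaged trace and per-realization records of a trigger run."""

    records: pd.DataFrame  # one row per realization
    trace: pd.DataFrame  # one row per (aligned) stage
    config: ExperimentConfig

    def to_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "trigger_records.tsv", sep="\t", index=False)
        self.trace.to_csv(out / "trigger_trace.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(
            json.dumps(_manifest(self.config), indent=2, sort_keys=True) + "\n"
        )


def single_trigger_experiment(config: ExperimentConfig) -> TriggerResult:
    """Remove each realization's highest-load edge and trace the cascade.

    Stages are aligned by index across realizations; traces shorter than the
    longest one are padded with their terminal value before averaging (a
    finished cascade simply stays in its final state).
    """
    rows = []
    nd_series: list[list[int]] = []
    scc_series: list[list[int]] = []
    for r in range(config.n_realizations):
        graph = _graph_for(config, r)
        if graph.M == 0:
            raise ValueError("graph has no edges; cannot trigger a cascade")
        loads = compute_loads(graph, config.fractional_load)
        capacities = assign_capacities(loads, config.alpha)
        attacked = select_highest_load_edge(
            graph, loads, _derived_seed(config.master_seed, 2, r)
        )
        trace = run_cascade(
            graph, capacities, attacked, config.fractional_load, config.largest_scc_only
        )
        intact = driver_report(graph)
        intact_scc = scc_edge_count(graph, config.largest_scc_only)
        rows.append(
            {
                "realization": r,
                "n_nodes": graph.N,
                "n_edges": graph.M,
                "intact_n_drivers": intact.n_drivers,
                "intact_scc_edges": intact_scc,
                "final_n_drivers": trace.stages[-1].n_drivers,
                "delta_n_drivers": trace.stages[-1].n_drivers - intact.n_drivers,
                "final_scc_edges": trace.stages[-1].scc_edges,
                "total_failed": trace.total_failed,
                "n_stages": len(trace.stages),
            }
        )
        nd_series.append([st.n_drivers for st in trace.stages])
        scc_series.append([st.scc_edges for st in trace.stages])
    longest = max(len(s) for s in nd_series)
    trace_rows = []
    for stage in range(longest):
        nd = np.array([s[min(stage, len(s) - 1)] for s in nd_series], dtype=float)
        sc = np.array([s[min(stage, len(s) - 1)] for s in scc_series], dtype=float)
        nd_m, nd_se = _mean_se(nd)
        sc_m, sc_se = _mean_se(sc)
        trace_rows.append(
            {
                "stage": stage,
                "n_drivers_mean": nd_m,
                "n_drivers_se": nd_se,
                "scc_edges_mean": sc_m,
                "scc_edges_se": sc_se,
            }
        )
    return TriggerResult(pd.DataFrame(rows), pd.DataFrame(trace_rows), config)


# -- failed-edge census ---------------------------------------------------


@dataclass(frozen=True)
class CensusResult:
    """Densities of the three edge categories among all failed edges.

    ``defined`` is False when no edge failed (attack included); the densities
    are then NaN and must be excluded from averages.
    """

    defined: bool
    critical: float
    ordinary: float
    redundant: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.critical, self.ordinary, self.redundant)


def failed_edge_census(
    classification: EdgeClassification,
    trace: CascadeTrace,
    attacked: frozenset[Edge] | None = None,
) -> CensusResult:
    """Category composition of attacked plus overload-failed edges.

    ``classification`` must come from the intact pre-attack graph; the census
    asks which controllability roles the destroyed edges played originally.
    """
    failed = (trace.attacked if attacked is None else attacked) | trace.cascade_failed_edges
    if not failed:
        return CensusResult(False, float("nan"), float("nan"), float("nan"))
    counts = {CRITICAL: 0, ORDINARY: 0, REDUNDANT: 0}
    for e in failed:
        counts[classification[e]] += 1
    total = len(failed)
    return CensusResult(
        True,
        counts[CRITICAL] / total,
        counts[ORDINARY] / total,
        counts[REDUNDANT] / total,
    )


# -- removal-fraction sweep ----------------------------------------------


@dataclass(frozen=True)
class SweepResult:
    """Realization-averaged sweep curves plus the raw per-cell records."""

    summary: pd.DataFrame  # one row per (strategy, f)
    records: pd.DataFrame  # one row per (realization, strategy, f)
    config: ExperimentConfig

    def to_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "sweep_summary.tsv", sep="\t", index=False)
        self.records.to_csv(out / "sweep_records.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(
            json.dumps(_manifest(self.config), indent=2, sort_keys=True) + "\n"
        )


def fraction_sweep(config: ExperimentConfig, classify: bool = True) -> SweepResult:
    """Full factorial over (realization, strategy, f).

    Per realization the graph, its loads, capacities and (optionally) its
    intact edge classification are computed once and shared across all
    attack cells.  ``classify=False`` skips the census columns, which is
    noticeably cheaper on large graphs.
    """
    rows = []
    strategies = tuple(config.strategies)
    for r in range(config.n_realizations):
        graph = _graph_for(config, r)
        if graph.M == 0:
            raise ValueError("graph has no edges; nothing to sweep")
        loads = compute_loads(graph, config.fractional_load)
        capacities = assign_capacities(loads, config.alpha)
        classification = classify_edges(graph) if classify else None
        for si, strategy in enumerate(strategies):
            for fi, f in enumerate(config.f_grid):
                seed = _derived_seed(config.master_seed, 3, r, si, fi)
                if strategy == RANDOM:
                    attacked = select_edges_random(graph, f, seed)
                else:
                    attacked = select_edges_intentional(graph, loads, f, seed)
                trace = run_cascade(
                    graph,
                    capacities,
                    attacked,
                    config.fractional_load,
                    config.largest_scc_only,
                )
                row = {
                    "realization": r,
                    "strategy": strategy,
                    "f": f,
                    "n_attacked": len(attacked),
                    "n_drivers_final": trace.stages[-1].n_drivers,
                    "total_failed": trace.total_failed,
                }
                if classification is not None:
                    census = failed_edge_census(classification, trace)
                    row.update(
                        {
                            "census_defined": census.defined,
                            "density_critical": census.critical,
                            "density_ordinary": census.ordinary,
                            "density_redundant": census.redundant,
                        }
                    )
                rows.append(row)
    return aggregate_realizations(pd.DataFrame(rows), config)


def aggregate_realizations(
    records: pd.DataFrame, config: ExperimentConfig | None = None
) -> SweepResult:
    """Mean and standard error per (strategy, f) cell.

    Census densities are averaged over the realizations where at least one
    edge failed; ``n_census_defined`` records how many that was.  With a
    single realization the standard error is reported as 0 and
    ``single_sample`` is set.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    out_rows = []
    for (strategy, f), cell in records.groupby(["strategy", "f"], sort=True):
        nd_m, nd_se = _mean_se(cell["n_drivers_final"].to_numpy(dtype=float))
        tf_m, tf_se = _mean_se(cell["total_failed"].to_numpy(dtype=float))
        row = {
            "strategy": strategy,
            "f": f,
            "n_realizations": len(cell),
            "single_sample": len(cell) == 1,
            "n_drivers_final_mean": nd_m,
            "n_drivers_final_se": nd_se,
            "total_failed_mean": tf_m,
            "total_failed_se": tf_se,
        }
        if "census_defined" in cell.columns:
            defined = cell[cell["census_defined"].astype(bool)]
            row["n_census_defined"] = len(defined)
            for col in ("density_critical", "density_ordinary", "density_redundant"):
                if len(defined):
                    m, se = _mean_se(defined[col].to_numpy(dtype=float))
                else:
                    m, se = float("nan"), float("nan")
                row[f"{col}_mean"] = m
                row[f"{col}_se"] = se
        out_rows.append(row)
    summary = pd.DataFrame(out_rows)
    if config is None:
        config = ExperimentConfig(
            generator=GeneratorSpec("er", 2, 0.0), n_realizations=len(records)
        )
    return SweepResult(summary, records.reset_index(drop=True), config)


def critical_fraction(sweep: SweepResult) -> float | None:
    """Smallest grid ``f`` beyond which no cascade failures occur at all.

    Returns the smallest ``f`` in the grid such that every strategy and
    realization at every ``f' >= f`` has ``total_failed = 0``; ``None`` if
    cascades persist to the top of the grid.
    """
    per_f = sweep.records.groupby("f")["total_failed"].max().sort_index()
    f_c = None
    for f in reversed(per_f.index.tolist()):
        if per_f[f] == 0:
            f_c = f
        else:
            break
    return f_c
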