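"""Experiment grids: AE kind x import strategy x training approach sweeps,
plus latent-dimension, imputation-strategy and encoder-depth studies.

Every grid cell resolves to one cross-validation run. Cells execute in
lexicographic order over (task, ae_kind, strategy, approach, latent_dim,
imputation, encoder_depth) for reproducible logs; completed cells are
persisted as JSON and skipped on re-run, so an interrupted sweep resumes
where it stopped.
"""

from __future__ import annotations

import copy
import hashlib
import itertools
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .assembly import APPROACHES, STRATEGIES, AssemblySpec
from .autoencoders import AE_KINDS, AEConfig, geometric_layer_sizes
from .matrix import ExpressionMatrix
from .preprocessing import IMPUTATION_STRATEGIES, impute, label_one_vs_rest
from .train_eval import SCALAR_METRICS, TrainConfig, cross_validate


@dataclass
class ExperimentGrid:
    """Cross-product of pipeline configurations to evaluate.

    ``tasks`` lists positive-class names for one-vs-rest labeling (use
    ``[None]`` when the data are already binary). The study's sweeps:
    latent_dims {128, 64, 32, 16} (128 default), imputation strategies
    {mean, constant_zero, most_frequent}, encoder depths {1, 2, 3}.
    """

    tasks: list = field(default_factory=lambda: [None])
    ae_kinds: list[str] = field(default_factory=lambda: ["basic"])
    strategies: list[str] = field(default_factory=lambda: ["encoder_only"])
    approaches: list[str] = field(default_factory=lambda: ["fine_tune"])
    latent_dims: list[int] = field(default_factory=lambda: [128])
    imputation_strategies: list[str] = field(default_factory=lambda: ["mean"])
    encoder_depths: list[int] = field(default_factory=lambda: [1])
    seeds: list[int] = field(default_factory=lambda: [0])

    def validate(self) -> None:
        for name, values, allowed in (
            ("ae_kinds", self.ae_kinds, AE_KINDS),
            ("strategies", self.strategies, STRATEGIES),
            ("approaches", self.approaches, APPROACHES),
            ("imputation_strategies", self.imputation_strategies,
             IMPUTATION_STRATEGIES),
        ):
            bad = [v for v in values if v not in allowed]
            if bad:
                raise ValueError(f"{name}: unknown value(s) {bad}; allowed {allowed}")
        if not all([self.tasks, self.ae_kinds, self.strategies, self.approaches,
                    self.latent_dims, self.imputation_strategies,
                    self.encoder_depths, self.seeds]):
            raise ValueError("every grid axis must be non-empty")

    def cells(self) -> list[dict]:
        """All grid cells in lexicographic execution order."""
        self.validate()
        axes = itertools.product(
            sorted(self.tasks, key=str), sorted(self.ae_kinds),
            sorted(self.strategies), sorted(self.approaches),
            sorted(self.latent_dims), sorted(self.imputation_strategies),
            sorted(self.encoder_depths))
        out = []
        for task, kind, strategy, approach, latent, imp, depth in axes:
            if strategy == "none" and approach != "fine_tune":
                continue  # the bare head has no imported weights to fix
            out.append({"task": task, "ae_kind": kind, "strategy": strategy,
                        "approach": approach, "latent_dim": latent,
                        "imputation": imp, "encoder_depth": depth})
        return out


def cell_id(cell: dict) -> str:
    """Stable, filesystem-safe identifier of one grid cell."""
    parts = [str(cell[k]) for k in ("task", "ae_kind", "strategy", "approach",
                                    "latent_dim", "imputation", "encoder_depth")]
    return "_".join(p.replace("/", "-") for p in parts)


def config_hash(grid: ExperimentGrid, train_config: TrainConfig) -> str:
    """Provenance digest; changes iff the resolved configuration changes."""
    blob = json.dumps({"grid": asdict(grid), "train": asdict(train_config)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SweepResult:
    """One grid cell's coordinates, per-metric summary and provenance."""

    cell: dict
    summary: dict[str, dict[str, float]]
    provenance: dict
    error: str | None = None


def _run_cell(cell: dict, data: ExpressionMatrix, train_config: TrainConfig,
              pretrain_scope: str) -> dict:
    work = data
    if cell["task"] is not None:
        work = label_one_vs_rest(work, cell["task"])
    if work.n_missing:
        work = impute(work, cell["imputation"])
    sizes = (geometric_layer_sizes(work.n_features, cell["latent_dim"],
                                   cell["encoder_depth"])
             if cell["encoder_depth"] > 1 else [cell["latent_dim"]])
    ae_config = AEConfig(kind=cell["ae_kind"], input_dim=work.n_features,
                         encoder_layer_sizes=sizes)
    spec = AssemblySpec(strategy=cell["strategy"], approach=cell["approach"])
    summaries = []
    for seed in cell["seeds"]:
        cfg = copy.deepcopy(train_config)
        cfg.seed = seed
        _, summary = cross_validate(work, ae_config, spec, cfg,
                                    pretrain_scope=pretrain_scope)
        summaries.append(summary)
    # average the per-seed summaries
    out = {k: {"mean": sum(s[k]["mean"] for s in summaries) / len(summaries),
               "sd": sum(s[k]["sd"] for s in summaries) / len(summaries)}
           for k in SCALAR_METRICS}
    return out


def run_grid(grid: ExperimentGrid, data: ExpressionMatrix,
             train_config: TrainConfig, out_dir: str | Path | None = None,
             pretrain_scope: str = "fold") -> list[SweepResult]:
    """Execute every grid cell via cross-validation.

    With ``out_dir`` set, each finished cell is written to
    ``<out_dir>/<cell_id>.json`` immediately and already-present cells are
    skipped, making interrupted sweeps resumable. Per-cell failures are
    recorded (with the error message) and the sweep continues.
    """
    train_config.validate()
    digest = config_hash(grid, train_config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    results: list[SweepResult] = []
    for cell in grid.cells():
        cid = cell_id(cell)
        prov = {"config_hash": digest, "seeds": list(grid.seeds), "cell_id": cid}
        path = out_dir / f"{cid}.json" if out_dir is not None else None
        if path is not None and path.exists():
            cached = json.loads(path.read_text())
            results.append(SweepResult(cell=cached["cell"], summary=cached["summary"],
                                       provenance=cached["provenance"],
                                       error=cached.get("error")))
            continue
        t0 = time.perf_counter()
        try:
            summary = _run_cell({**cell, "seeds": grid.seeds}, data,
                                train_config, pretrain_scope)
            res = SweepResult(cell=cell, summary=summary, provenance=prov)
        except Exception as exc:  # record and continue with the next cell
            res = SweepResult(cell=cell, summary={}, provenance=prov,
                              error=f"{type(exc).__name__}: {exc}")
        res.provenance["elapsed_s"] = round(time.perf_counter() - t0, 3)
        if path is not None:
            path.write_text(json.dumps(
                {"cell": res.cell, "summary": res.summary,
                 "provenance": res.provenance, "error": res.error}, indent=2))
        results.append(res)
    return results


def rank_results(results: list[SweepResult], metric: str = "f1"
                 ) -> list[SweepResult]:
    """Order results by descending mean of ``metric``; ties break by lower
    SD, then lexicographic cell id. The first entry is the best cell."""
    if not results:
        raise ValueError("no results to rank")
    if metric not in SCALAR_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {SCALAR_METRICS}")
    ok = [r for r in results if r.error is None and r.summary]
    ok.sort(key=lambda r: (-r.summary[metric]["mean"], r.summary[metric]["sd"],
                           cell_id(r.cell)))
    failed = [r for r in results if r.error is not None or not r.summary]
    return ok + failed
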