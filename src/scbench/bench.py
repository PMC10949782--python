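"""Benchmark harness: run configs, multi-seed averaging, grid search.

A :class:`RunConfig` fully specifies one benchmark (task, model, dataset,
hyperparameters, seeds) and serializes to exactly one command line, so any
reported number is reproducible by re-running that line.  ``run_benchmark``
executes load -> preprocess -> fit -> predict -> score per seed and
aggregates mean/sd per metric; ``grid_search`` enumerates a finite parameter
grid in deterministic order and ranks configurations by the task's primary
metric (ARI for clustering, accuracy for annotation, MSE for imputation and
deconvolution).
"""

from __future__ import annotations

import dataclasses
import json
import shlex
import warnings
from dataclasses import dataclass, field, fields, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import AnnotatorConfig, fit_gnn_annotator, fit_logreg_annotator, fit_mlp_annotator
from .clustering import TrainConfig, fit_graph_ae_cluster, fit_zinb_dec
from .data import get_dataset, split
from .deconvolution import (NMFConfig, ProportionMatrix, build_signature,
                            nnls_deconvolve, score_deconvolution, seeded_nmf_deconvolve)
from .imputation import (ImputerConfig, baseline_gene_mean_impute, fit_block_mlp_imputer,
                         fit_graph_ae_imputer, mask_nonzero_entries, score_imputation)
from .metrics import MetricReport, ari, nmi
from .synthetic import sample_constraints
from .transforms import default_pipeline

TASKS = ("clustering", "annotation", "imputation", "deconvolution")

TASK_MODELS = {
    "clustering": ("zinb_dec", "zinb_dec_constrained", "graph_ae_cluster"),
    "annotation": ("logreg", "mlp", "gnn_annotator"),
    "imputation": ("block_mlp_imputer", "graph_ae_imputer"),
    "deconvolution": ("nnls_deconv", "seeded_nmf_deconv"),
}

# primary metric and preferred direction per task
PRIMARY_METRIC = {
    "clustering": ("ari", "max"),
    "annotation": ("accuracy", "max"),
    "imputation": ("mse", "min"),
    "deconvolution": ("mse", "min"),
}

DEFAULT_SEEDS = tuple(range(20))


@dataclass(frozen=True)
class RunConfig:
    task: str
    model: str
    dataset: str
    hyperparameters: tuple = ()  # sorted tuple of (name, value) pairs
    seeds: tuple = DEFAULT_SEEDS
    device: str = "cpu"

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {TASKS}")
        if self.model not in TASK_MODELS[self.task]:
            raise ValueError(
                f"model {self.model!r} is not registered for task {self.task!r}; "
                f"choose from {TASK_MODELS[self.task]}")
        hp = tuple(sorted(dict(self.hyperparameters).items()))
        object.__setattr__(self, "hyperparameters", hp)
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


@dataclass
class BenchmarkResult:
    config: RunConfig
    per_seed: dict            # seed -> MetricReport
    summary: dict             # metric -> (mean, sd)
    command_line: str
    tool_version: str = __version__
    failures: dict = field(default_factory=dict)


# -- command-line (de)serialization --------------------------------------

def to_command_line(cfg: RunConfig) -> str:
    """Canonical one-line representation; flags in sorted order."""
    parts = [f"--dataset {cfg.dataset}", f"--device {cfg.device}",
             f"--model {cfg.model}"]
    for k, v in cfg.hyperparameters:
        parts.append(f"--param {k}={json.dumps(v)}")
    for s in cfg.seeds:
        parts.append(f"--seed {s}")
    parts.append(f"--task {cfg.task}")
    return " ".join(parts)


def parse_command_line(argv) -> RunConfig:
    """Inverse of :func:`to_command_line`; unknown flags are rejected."""
    if isinstance(argv, str):
        argv = shlex.split(argv)
    out = {"hyperparameters": [], "seeds": []}
    i = 0
    while i < len(argv):
        flag = argv[i]
        if not flag.startswith("--") or i + 1 >= len(argv):
            raise ValueError(f"malformed flag {flag!r}")
        value = argv[i + 1]
        i += 2
        name = flag[2:]
        if name in ("task", "model", "dataset", "device"):
            out[name] = value
        elif name == "seed":
            out["seeds"].append(int(value))
        elif name == "param":
            if "=" not in value:
                raise ValueError(f"--param expects key=value, got {value!r}")
            k, _, raw = value.partition("=")
            try:
                v = json.loads(raw)
            except json.JSONDecodeError:
                v = raw
            out["hyperparameters"].append((k, v))
        else:
            raise ValueError(f"unknown flag --{name}")
    for required in ("task", "model", "dataset"):
        if required not in out:
            raise ValueError(f"missing required flag --{required}")
    return RunConfig(task=out["task"], model=out["model"], dataset=out["dataset"],
                     hyperparameters=tuple(out["hyperparameters"]),
                     seeds=tuple(out["seeds"]) or DEFAULT_SEEDS,
                     device=out.get("device", "cpu"))


def _subconfig(cls, hp: dict, seed: int):
    names = {f.name for f in fields(cls)} - {"seed"}
    kwargs = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in hp.items() if k in names}
    return cls(seed=seed, **kwargs)


# -- per-task runners ----------------------------------------------------

def _run_clustering(cfg: RunConfig, seed: int) -> MetricReport:
    ds = get_dataset(cfg.dataset)
    dsp = default_pipeline("zinb_dec" if cfg.model.startswith("zinb") else cfg.model).apply(ds)
    truth = dsp.cell_table["cell_type"].to_numpy()
    hp = cfg.hp
    K = int(hp.get("k", len(set(truth))))
    tc = _subconfig(TrainConfig, hp, seed)
    if cfg.model == "zinb_dec":
        model = fit_zinb_dec(dsp, K, tc)
    elif cfg.model == "zinb_dec_constrained":
        cons = sample_constraints(truth, int(hp.get("n_must", 100)),
                                  int(hp.get("n_cannot", 100)), seed=seed)
        model = fit_zinb_dec(dsp, K, tc, constraints=cons)
    else:
        model = fit_graph_ae_cluster(dsp, K, tc)
    pred = model.predict()
    return MetricReport(task="clustering",
                        values={"ari": ari(truth, pred), "nmi": nmi(truth, pred)},
                        n_items=len(truth))


def _run_annotation(cfg: RunConfig, seed: int) -> MetricReport:
    hp = cfg.hp
    ds = get_dataset(cfg.dataset)
    dsp = default_pipeline(cfg.model).apply(ds)
    train, test = split(dsp, float(hp.get("test_fraction", 0.2)),
                        stratify_by="cell_type", seed=seed)
    ac = _subconfig(AnnotatorConfig, hp, seed)
    if cfg.model == "logreg":
        model = fit_logreg_annotator(train, ac)
    elif cfg.model == "mlp":
        model = fit_mlp_annotator(train, ac)
    else:
        model = fit_gnn_annotator(train, test, ac)
    return MetricReport(task="annotation",
                        values={"accuracy": model.score(test)},
                        n_items=test.n_cells)


def _run_imputation(cfg: RunConfig, seed: int) -> MetricReport:
    hp = cfg.hp
    ds = get_dataset(cfg.dataset)
    mds = mask_nonzero_entries(ds, float(hp.get("mask_fraction", 0.1)), seed=seed)
    ic = _subconfig(ImputerConfig, hp, seed)
    fit = fit_block_mlp_imputer if cfg.model == "block_mlp_imputer" else fit_graph_ae_imputer
    model = fit(mds, ic)
    return MetricReport(
        task="imputation",
        values={"mse": model.score(mds),
                "mse_gene_mean_baseline": score_imputation(mds, baseline_gene_mean_impute(mds))},
        n_items=len(mds.held_out))


def _deconv_truth(spots) -> ProportionMatrix:
    cols = [c for c in spots.cell_table.columns if c.startswith("prop_")]
    if not cols:
        raise ValueError(f"dataset {spots!r} has no ground-truth proportion columns")
    types = [c[len("prop_"):] for c in cols]
    return ProportionMatrix(P=spots.cell_table[cols].to_numpy(),
                            spot_ids=list(spots.cell_ids), type_names=types)


def _run_deconvolution(cfg: RunConfig, seed: int) -> MetricReport:
    hp = cfg.hp
    spots = get_dataset(cfg.dataset)
    reference = get_dataset(hp.get("reference", cfg.dataset + "_ref"))
    truth = _deconv_truth(spots)
    sig = build_signature(reference, int(hp.get("n_markers", 50)))
    if cfg.model == "nnls_deconv":
        pred = nnls_deconvolve(spots, sig, log_weighting=bool(hp.get("log_weighting", False)))
    else:
        pred = seeded_nmf_deconvolve(reference, spots, sig, _subconfig(NMFConfig, hp, seed))
    return MetricReport(task="deconvolution",
                        values={"mse": score_deconvolution(pred, truth)},
                        n_items=truth.P.size)


_RUNNERS = {"clustering": _run_clustering, "annotation": _run_annotation,
            "imputation": _run_imputation, "deconvolution": _run_deconvolution}


def run_benchmark(cfg: RunConfig) -> BenchmarkResult:
    """Execute load -> preprocess -> fit -> predict -> score for every seed."""
    per_seed, failures = {}, {}
    for seed in cfg.seeds:
        try:
            per_seed[seed] = _RUNNERS[cfg.task](cfg, seed)
        except Exception as e:  # record and continue with remaining seeds
            failures[seed] = f"{type(e).__name__}: {e}"
    if failures:
        warnings.warn(f"{len(failures)} seed(s) failed: {failures}")
    if not per_seed:
        raise RuntimeError(f"all seeds failed: {failures}")
    metrics = sorted({m for r in per_seed.values() for m in r.values})
    summary = {}
    for m in metrics:
        vals = np.array([r.values[m] for r in per_seed.values() if m in r.values])
        summary[m] = (float(vals.mean()), float(vals.std()))
    return BenchmarkResult(config=cfg, per_seed=per_seed, summary=summary,
                           command_line=to_command_line(cfg), failures=failures)


@dataclass(frozen=True)
class SearchSpace:
    """Parameter name -> finite candidate list; enumerated in sorted-key order."""

    grid: tuple  # sorted tuple of (name, tuple_of_values)

    @classmethod
    def from_dict(cls, d: dict) -> "SearchSpace":
        if not d or any(len(v) == 0 for v in d.values()):
            raise ValueError("search space must be non-empty with non-empty candidate lists")
        return cls(tuple(sorted((k, tuple(v)) for k, v in d.items())))

    def points(self):
        keys = [k for k, _ in self.grid]
        for combo in product(*(v for _, v in self.grid)):
            yield dict(zip(keys, combo))


def grid_search(space: SearchSpace, base: RunConfig):
    """Evaluate every grid point with base.seeds; return (best config, table).

    The table is sorted best-first by the task's primary metric; ties keep
    grid enumeration order.
    """
    metric, direction = PRIMARY_METRIC[base.task]
    table = []
    for i, point in enumerate(space.points()):
        cfg = replace(base, hyperparameters=tuple({**base.hp, **point}.items()))
        result = run_benchmark(cfg)
        table.append((i, cfg, result.summary))
    sign = -1.0 if direction == "max" else 1.0
    table.sort(key=lambda row: (sign * row[2][metric][0], row[0]))
    best = table[0][1]
    return best, [(cfg, summary) for _, cfg, summary in table]


def write_results(results, path) -> Path:
    """Detail CSV (one row per config/seed/metric), summary CSV, JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    detail_rows, summary_rows, sidecar = [], [], []
    for res in results:
        c = res.config
        for seed, report in res.per_seed.items():
            for m, v in report.values.items():
                detail_rows.append({"task": c.task, "model": c.model,
                                    "dataset": c.dataset, "seed": seed,
                                    "metric": m, "value": v})
        for m, (mean, sd) in res.summary.items():
            summary_rows.append({"task": c.task, "model": c.model,
                                 "dataset": c.dataset, "metric": m,
                                 "mean": mean, "sd": sd})
        sidecar.append({"config": dataclasses.asdict(c),
                        "command_line": res.command_line,
                        "tool_version": res.tool_version,
                        "summary": {m: list(v) for m, v in res.summary.items()}})
    pd.DataFrame(detail_rows).to_csv(path / "details.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(path / "summary.csv", index=False)
    (path / "runs.json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_configs(path) -> list:
    """Reconstruct the RunConfigs stored in a results JSON sidecar."""
    out = []
    for entry in json.loads(Path(path).read_text()):
        c = entry["config"]
        out.append(RunConfig(task=c["task"], model=c["model"], dataset=c["dataset"],
                             hyperparameters=tuple((k, v) for k, v in c["hyperparameters"]),
                             seeds=tuple(c["seeds"]), device=c["device"]))
    return out
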