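"""Cross-brand transfer study orchestration.

Runs the full experiment grid: a pooled all-brands calibration, the 12
ordered brand-pair transfer tasks under three methods (direct PLSR,
TCA-PLSR, CORAL-PLSR), and model-updating sweeps in which a small
fraction of labeled target-domain samples is moved into the calibration
pool before (optionally) re-running domain adaptation.  Every task
derives its own seed deterministically from one master seed, so a report
is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adapt
from .chemometrics import compute_metrics, sorted_interleaved_split
from .io import SpectralDataset, concat_datasets
from .pls import PLSR

__all__ = [
    "METHODS",
    "StudyConfig",
    "TransferTask",
    "TransferResult",
    "StudyReport",
    "derive_seed",
    "pooled_model_experiment",
    "run_transfer_task",
    "update_domains",
    "run_updated_sweep",
    "run_full_study",
    "TransferStudy",
]

METHODS = ("direct", "tca", "coral")


def derive_seed(master: int, label: str) -> int:
    """Deterministic 31-bit per-task seed fanned out from the master seed."""
    return int(
        np.random.SeedSequence([int(master), zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class StudyConfig:
    """Hyperparameters of the study; defaults are the reference settings."""

    max_lv: int | None = None        # None -> min(20, n-1, d)
    k_folds: int = 10
    tca_dim: int = 30
    tca_mu: float = 0.1
    coral_lambda: float | str = "auto"
    coral_mean_mode: str = "match"
    update_selection: str = "systematic"   # or "random"
    sweep_fractions: tuple = tuple(f / 100 for f in range(1, 11))
    sweep_pairs: tuple = (("#1", "#4"),)
    sweep_methods: tuple = ("direct", "tca")
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_fractions"] = list(self.sweep_fractions)
        d["sweep_pairs"] = [list(p) for p in self.sweep_pairs]
        d["sweep_methods"] = list(self.sweep_methods)
        return d


@dataclass
class TransferTask:
    source_brand: str
    target_brand: str
    method: str
    updating_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS + ("pooled",):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 <= self.updating_fraction < 0.5):
            raise ValueError("updating_fraction must lie in [0, 0.5)")

    @property
    def label(self) -> str:
        return f"{self.source_brand}->{self.target_brand}:{self.method}:{self.updating_fraction:g}"


@dataclass
class TransferResult:
    """Per-task metrics in the layout R_c | RMSEC | R_p | RMSEP | MAE."""

    task: TransferTask
    r_c: float
    rmsec: float
    r_p: float
    rmsep: float
    mae: float
    n_source: int
    n_target_predicted: int
    chosen_n_latent: int

    def to_dict(self) -> dict:
        return {
            "source_brand": self.task.source_brand,
            "target_brand": self.task.target_brand,
            "method": self.task.method,
            "updating_fraction": self.task.updating_fraction,
            "seed": self.task.seed,
            "r_c": self.r_c,
            "rmsec": self.rmsec,
            "r_p": self.r_p,
            "rmsep": self.rmsep,
            "mae": self.mae,
            "n_source": self.n_source,
            "n_target_predicted": self.n_target_predicted,
            "chosen_n_latent": self.chosen_n_latent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferResult":
        task = TransferTask(
            source_brand=d["source_brand"],
            target_brand=d["target_brand"],
            method=d["method"],
            updating_fraction=d["updating_fraction"],
            seed=d["seed"],
        )
        return cls(
            task=task,
            r_c=d["r_c"],
            rmsec=d["rmsec"],
            r_p=d["r_p"],
            rmsep=d["rmsep"],
            mae=d["mae"],
            n_source=d["n_source"],
            n_target_predicted=d["n_target_predicted"],
            chosen_n_latent=d["chosen_n_latent"],
        )


def _check_common_grid(a: SpectralDataset, b: SpectralDataset) -> None:
    if not np.array_equal(a.wavenumbers, b.wavenumbers):
        raise ValueError("source and target are not on a common wavenumber grid")


def pooled_model_experiment(datasets: dict, config: StudyConfig | None = None,
                            seed: int | None = None) -> TransferResult:
    """Merge all brands, split 2:1 by sorted interleaving, fit and evaluate."""
    config = config or StudyConfig()
    if seed is None:
        seed = derive_seed(config.master_seed, "pooled")
    merged = concat_datasets(datasets.values())
    cal_idx, pred_idx = sorted_interleaved_split(merged.target)
    cal, pred = merged.take(cal_idx), merged.take(pred_idx)
    res = PLSR.from_dataset(cal).fit(max_lv=config.max_lv, k_folds=config.k_folds, seed=seed)
    pm = compute_metrics(pred.target, res.predict(pred.absorbance))
    task = TransferTask("all", "all", "pooled", 0.0, seed)
    return TransferResult(
        task=task,
        r_c=res.r_c,
        rmsec=res.rmsec,
        r_p=pm.pearson_r,
        rmsep=pm.rmse,
        mae=pm.mae,
        n_source=len(cal),
        n_target_predicted=len(pred),
        chosen_n_latent=res.n_latent,
    )


def run_transfer_task(
    source: SpectralDataset,
    target: SpectralDataset,
    method: str,
    config: StudyConfig | None = None,
    seed: int = 0,
    updating_fraction: float = 0.0,
) -> TransferResult:
    """One cross-brand task: calibrate on the source, predict the target.

    direct : PLSR on raw source spectra, applied to raw target spectra.
    tca    : fit TCA on both domains' spectra, project both, calibrate in
             the subspace and predict the projected target.
    coral  : recolor the source toward the target covariance, calibrate
             on the recolored source and predict the raw target.

    Calibration metrics are reported in the space where the model was
    fitted.  The latent-variable count is re-selected by CV inside every
    task.
    """
    config = config or StudyConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    _check_common_grid(source, target)
    src_ids = set(source.sample_id.tolist())
    tgt_ids = set(target.sample_id.tolist())
    overlap = src_ids & tgt_ids
    if overlap and src_ids != tgt_ids:
        raise ValueError(f"sample leakage between domains: {sorted(overlap)[:3]}...")

    Xs, ys = source.absorbance, source.target
    Xt, yt = target.absorbance, target.target
    if method == "direct":
        X_cal, X_pred = Xs, Xt
    elif method == "tca":
        m = min(config.tca_dim, Xs.shape[1], Xs.shape[0] + Xt.shape[0] - 2)
        t = adapt.tca_fit(Xs, Xt, m=m, mu=config.tca_mu)
        X_cal, X_pred = t.transform(Xs), t.transform(Xt)
    else:  # coral
        c = adapt.coral_fit(Xs, Xt, lam=config.coral_lambda, mean_mode=config.coral_mean_mode)
        X_cal, X_pred = c.transform(Xs), Xt

    res = PLSR(X_cal, ys).fit(max_lv=config.max_lv, k_folds=config.k_folds, seed=seed)
    pm = compute_metrics(yt, res.predict(X_pred))
    task = TransferTask(str(source.brand[0]), str(target.brand[0]), method, updating_fraction, seed)
    return TransferResult(
        task=task,
        r_c=res.r_c,
        rmsec=res.rmsec,
        r_p=pm.pearson_r,
        rmsep=pm.rmse,
        mae=pm.mae,
        n_source=len(source),
        n_target_predicted=len(target),
        chosen_n_latent=res.n_latent,
    )


def update_domains(
    source: SpectralDataset,
    target: SpectralDataset,
    fraction: float,
    selection_mode: str = "systematic",
    seed: int = 0,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Move ``round(fraction * n_target)`` target samples into the source.

    'systematic' (default) picks evenly spaced positions of the y-sorted
    target list, covering the target's blend-proportion range
    deterministically; 'random' draws a seeded uniform subset.  The moved
    samples are appended to the source and removed from the target, so
    the two stay disjoint and the total sample count is conserved.
    """
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must lie in [0, 0.5)")
    _check_common_grid(source, target)
    n_t = len(target)
    k = int(round(fraction * n_t))
    if k == 0:
        return source, target
    if n_t - k < 3:
        raise ValueError(f"moving {k} of {n_t} target samples leaves too few to predict")
    if selection_mode == "systematic":
        order = np.argsort(target.target, kind="stable")
        pos = np.unique(np.round(np.linspace(0, n_t - 1, k)).astype(int))
        chosen = order[pos]
    elif selection_mode == "random":
        chosen = np.random.default_rng(seed).choice(n_t, size=k, replace=False)
    else:
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    mask = np.zeros(n_t, dtype=bool)
    mask[chosen] = True
    moved = target.take(np.flatnonzero(mask))
    reduced = target.take(np.flatnonzero(~mask))
    updated = concat_datasets([source, moved])
    return updated, reduced


def run_updated_sweep(
    source: SpectralDataset,
    target: SpectralDataset,
    method: str,
    fractions,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> list:
    """Model-updating sweep: update the domains, then run the task.

    With ``method='direct'`` this is Updated-PLSR; with 'tca'/'coral' the
    updated domains are re-aligned before calibration (updating combined
    with domain adaptation).
    """
    config = config or StudyConfig()
    out = []
    for fraction in fractions:
        if not (0 < fraction < 0.5):
            raise ValueError(f"sweep fractions must lie in (0, 0.5), got {fraction}")
        upd_src, red_tgt = update_domains(
            source, target, fraction, selection_mode=config.update_selection, seed=seed
        )
        out.append(
            run_transfer_task(
                upd_src, red_tgt, method, config, seed=seed, updating_fraction=fraction
            )
        )
    return out


@dataclass
class StudyReport:
    """All results of one study run, serializable losslessly to JSON."""

    pooled: TransferResult
    tasks: list
    sweeps: list
    config: dict
    master_seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "master_seed": self.master_seed,
                "config": self.config,
                "pooled": self.pooled.to_dict(),
                "tasks": [r.to_dict() for r in self.tasks],
                "sweeps": [r.to_dict() for r in self.sweeps],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        doc = json.loads(text)
        return cls(
            pooled=TransferResult.from_dict(doc["pooled"]),
            tasks=[TransferResult.from_dict(d) for d in doc["tasks"]],
            sweeps=[TransferResult.from_dict(d) for d in doc["sweeps"]],
            config=doc["config"],
            master_seed=doc["master_seed"],
        )

    def to_table(self) -> pd.DataFrame:
        """Tabular view mirroring the transfer-task result layout."""
        rows = []
        for r in [self.pooled] + list(self.tasks) + list(self.sweeps):
            rows.append(
                {
                    "task": f"{r.task.source_brand}->{r.task.target_brand}",
                    "method": r.task.method,
                    "updating_fraction": r.task.updating_fraction,
                    "R_c": r.r_c,
                    "RMSEC (%)": r.rmsec,
                    "R_p": r.r_p,
                    "RMSEP (%)": r.rmsep,
                    "MAE (%)": r.mae,
                    "n_latent": r.chosen_n_latent,
                }
            )
        return pd.DataFrame(rows)

    def plot_sweeps(self, ax=None):
        """RMSEP vs updating fraction, one line per (pair, method)."""
        import matplotlib.pyplot as plt  # heavy import kept optional

        if ax is None:
            _, ax = plt.subplots()
        series: dict = {}
        for r in self.sweeps:
            key = (f"{r.task.source_brand}->{r.task.target_brand}", r.task.method)
            series.setdefault(key, []).append((r.task.updating_fraction, r.rmsep))
        for (pair, method), points in sorted(series.items()):
            points.sort()
            fr, vals = zip(*points)
            ax.plot([100 * f for f in fr], vals, marker="o", label=f"{pair} {method}")
        ax.set_xlabel("target samples moved to source (%)")
        ax.set_ylabel("RMSEP (%)")
        ax.legend()
        return ax

    def result_for(self, source: str, target: str, method: str,
                   fraction: float = 0.0) -> TransferResult:
        pool = self.tasks if fraction == 0.0 else self.sweeps
        for r in pool:
            if (
                r.task.source_brand == source
                and r.task.target_brand == target
                and r.task.method == method
                and abs(r.task.updating_fraction - fraction) < 1e-12
            ):
                return r
        raise KeyError(f"no result for {source}->{target}:{method}@{fraction}")


def run_full_study(datasets: dict, config: StudyConfig | None = None) -> StudyReport:
    """Pooled model + all ordered brand pairs x methods + updating sweeps."""
    config = config or StudyConfig()
    brands = sorted(datasets)
    if len(brands) < 2:
        raise ValueError("a transfer study needs at least 2 brands")
    master = config.master_seed
    pooled = pooled_model_experiment(datasets, config, seed=derive_seed(master, "pooled"))
    tasks = []
    for src in brands:
        for tgt in brands:
            if src == tgt:
                continue
            for method in METHODS:
                label = f"{src}->{tgt}:{method}"
                tasks.append(
                    run_transfer_task(
                        datasets[src], datasets[tgt], method, config,
                        seed=derive_seed(master, label),
                    )
                )
    sweeps = []
    for src, tgt in config.sweep_pairs:
        for method in config.sweep_methods:
            label = f"sweep:{src}->{tgt}:{method}"
            sweeps.extend(
                run_updated_sweep(
                    datasets[src], datasets[tgt], method, config.sweep_fractions,
                    config, seed=derive_seed(master, label),
                )
            )
    return StudyReport(
        pooled=pooled,
        tasks=tasks,
        sweeps=sweeps,
        config=config.to_dict(),
        master_seed=master,
    )


class TransferStudy:
    """Convenience wrapper: ``TransferStudy(datasets, config).run()``."""

    def __init__(self, datasets: dict, config: StudyConfig | None = None):
        self.datasets = datasets
        self.config = config or StudyConfig()

    def run(self) -> StudyReport:
        return run_full_study(self.datasets, self.config)
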