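"""Config-driven orchestration of the full screening analysis.

Stages run in a fixed order: simulate/load -> preprocess -> split -> fit ->
validate -> S-TOCSY -> report. One master seed is deterministically forked
per randomized stage (simulation, split, cross-validation), so the same
config and seed reproduce the report bit-identically; wall-clock timestamps
are written to a separate run log, never into the report, to keep the
report diffable.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diagnostics import (
    SplitPlan,
    confusion_from_labels,
    roc,
    sensitivity_specificity,
    split_train_validation,
    univariate_panel,
)
from .opls import ClassCoding, classify, fit_opls, predict, q2_cross_val, save_model
from .spectral_processing import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_TSP_REGION,
    DEFAULT_WATER_REGION,
    preprocess_cohort,
    read_binned_csv,
    read_spectra_csv,
    write_binned_csv,
)
from .stocsy import annotate, stocsy
from .synthetic_data import CohortSpec, build_template_library, simulate_cohort


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    # input: exactly one of synthetic / spectra_csv / binned_csv
    synthetic: dict = field(default_factory=dict)
    spectra_csv: str | None = None
    binned_csv: str | None = None
    metadata_tsv: str | None = None

    bin_width: float = DEFAULT_BIN_WIDTH
    water_region: tuple[float, float] = DEFAULT_WATER_REGION
    tsp_region: tuple[float, float] | None = DEFAULT_TSP_REGION
    normalize: bool = True

    n_ortho: int = 2
    scaling: str = "center"
    folds: int = 7

    validation_fraction: float = 1.0 / 3.0
    stage_filter: list[str] | None = None

    stocsy_ppm_tol: float = 0.02
    stocsy_corr_threshold: float = 0.3

    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.water_region is not None:
            cfg.water_region = tuple(cfg.water_region)
        if cfg.tsp_region is not None:
            cfg.tsp_region = tuple(cfg.tsp_region)
        return cfg


def _fork_seeds(master: int, n: int = 3) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _canonical(obj):
    """Round floats to 12 significant digits so the report is diffable."""
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if not math.isfinite(f):
            return repr(f)
        return float(f"{f:.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _canonical(obj.tolist())
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_canonical(report), sort_keys=True, indent=2))


def run(config: RunConfig) -> dict:
    """Execute the full analysis and return the machine-readable report."""
    sim_seed, split_seed, cv_seed = _fork_seeds(config.seed)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    library = build_template_library()

    # --- load / simulate -------------------------------------------------
    try:
        cohort = None
        if config.binned_csv:
            matrix = read_binned_csv(config.binned_csv, width=config.bin_width)
            labels, stages = _read_metadata(config.metadata_tsv, matrix.sample_ids)
        else:
            if config.spectra_csv:
                spectra = read_spectra_csv(config.spectra_csv)
                labels, stages = _read_metadata(
                    config.metadata_tsv, [s.sample_id for s in spectra]
                )
            else:
                spec = CohortSpec(**{**config.synthetic, "seed": sim_seed})
                cohort = simulate_cohort(spec, library)
                spectra, labels, stages = cohort.spectra, cohort.labels, cohort.stages
            matrix = None
    except StageError:
        raise
    except Exception as e:
        raise StageError("load", str(e)) from e

    # --- optional stage-subgroup filter ----------------------------------
    if config.stage_filter is not None:
        keep_stage = set(config.stage_filter)
        keep = [
            i for i, lab in enumerate(labels)
            if lab != "case" or stages[i] in keep_stage
        ]
        if sum(labels[i] == "case" for i in keep) < 3:
            raise StageError("subgroup", "fewer than 3 cases after stage filter")
        labels = [labels[i] for i in keep]
        stages = [stages[i] for i in keep]
        if matrix is not None:
            matrix = _subset_matrix(matrix, keep)
        else:
            spectra = [spectra[i] for i in keep]

    # --- preprocess -------------------------------------------------------
    try:
        if matrix is None:
            matrix = preprocess_cohort(
                spectra,
                width=config.bin_width,
                water_region=config.water_region,
                tsp_region=config.tsp_region,
                normalize=config.normalize,
            )
        if out:
            write_binned_csv(matrix, out / "matrix.csv")
    except Exception as e:
        raise StageError("preprocess", str(e)) from e

    # --- split ------------------------------------------------------------
    try:
        plan = SplitPlan(validation_fraction=config.validation_fraction, seed=split_seed)
        train_idx, val_idx = split_train_validation(labels, plan)
    except Exception as e:
        raise StageError("split", str(e)) from e

    coding = ClassCoding()
    y = coding.encode(labels)
    X = matrix.values

    # --- fit --------------------------------------------------------------
    try:
        model = fit_opls(X[train_idx], y[np.array(train_idx)],
                         n_ortho=config.n_ortho, scaling=config.scaling,
                         bin_edges=matrix.bin_edges)
        model.q2 = q2_cross_val(X[train_idx], y[np.array(train_idx)],
                                n_ortho=config.n_ortho, folds=config.folds,
                                seed=cv_seed, scaling=config.scaling)
        if out:
            save_model(model, out / "model.json")
    except Exception as e:
        raise StageError("fit", str(e)) from e

    # --- validate ---------------------------------------------------------
    try:
        y_hat_val = predict(model, X[val_idx])
        pred_labels = classify(y_hat_val, coding)
        true_labels = [labels[i] for i in val_idx]
        counts = confusion_from_labels(true_labels, pred_labels)
        sens, spec_ = sensitivity_specificity(counts)
        if out:
            _write_predictions(out / "predictions.tsv", matrix, val_idx,
                               true_labels, y_hat_val, pred_labels)
    except Exception as e:
        raise StageError("validate", str(e)) from e

    # --- S-TOCSY ----------------------------------------------------------
    try:
        # drive from the training predictive scores, oriented cancer-high
        t = model.t
        y_train = y[np.array(train_idx)]
        if np.corrcoef(t, y_train)[0, 1] < 0:
            t = -t
        train_matrix = _subset_matrix(matrix, train_idx)
        sres = stocsy(train_matrix, t)
        hits = annotate(sres, library, ppm_tol=config.stocsy_ppm_tol,
                        corr_threshold=config.stocsy_corr_threshold)
        if out:
            _write_stocsy(out / "stocsy.tsv", sres)
    except Exception as e:
        raise StageError("stocsy", str(e)) from e

    # --- per-marker univariate panel and ROC ------------------------------
    try:
        markers = [tpl for tpl in library if tpl.direction != "none"]
        centers = matrix.bin_centers
        marker_rows = []
        levels = np.empty((X.shape[0], len(markers)))
        for j, tpl in enumerate(markers):
            b = int(np.argmin(np.abs(centers - tpl.peaks[0].center)))
            levels[:, j] = X[:, b]
            scores = X[:, b] if tpl.direction == "up" else -X[:, b]
            rc = roc(scores, labels)
            marker_rows.append({
                "metabolite": tpl.name,
                "bin_ppm": float(centers[b]),
                "auc": rc.auc,
                "youden_sensitivity": rc.best_sensitivity,
                "youden_specificity": rc.best_specificity,
            })
        pvals, qvals = univariate_panel(levels, labels)
        for row, p, q in zip(marker_rows, pvals, qvals):
            row["p_value"] = float(p)
            row["fdr_q"] = float(q)
    except Exception as e:
        raise StageError("panel", str(e)) from e

    report = {
        "software_version": __version__,
        "config": _canonical(dataclasses.asdict(config)),
        "seeds": {"master": config.seed, "simulate": sim_seed,
                  "split": split_seed, "cv": cv_seed},
        "n_samples": len(labels),
        "n_bins": int(X.shape[1]),
        "split": {"n_train": len(train_idx), "n_validation": len(val_idx),
                  "validation_cases": sum(l == "case" for l in true_labels),
                  "validation_controls": sum(l == "control" for l in true_labels)},
        "training": {"r2y": model.r2y, "q2": model.q2, "n_ortho": model.n_ortho},
        "validation": {
            "confusion": {"tp": counts.tp, "fp": counts.fp,
                          "tn": counts.tn, "fn": counts.fn},
            "sensitivity_pct": sens,
            "specificity_pct": spec_,
        },
        "stocsy_hits": [dataclasses.asdict(h) for h in hits],
        "marker_panel": marker_rows,
    }
    if out:
        write_report(report, out / "report.json")
        (out / "run.log").write_text(
            f"urinemet {__version__}\nelapsed_s {time.time() - t0:.2f}\n"
        )
    return report


def subgroup_run(config: RunConfig, stage_filter) -> dict:
    """Re-run the pipeline keeping only cases whose stage is in the filter
    (controls are always retained), as for an early-stage-only model."""
    cfg = dataclasses.replace(config, stage_filter=sorted(stage_filter))
    return run(cfg)


# ---------------------------------------------------------------------------
# helpers

def _subset_matrix(matrix, idx):
    from .spectral_processing import BinnedMatrix

    return BinnedMatrix(
        values=matrix.values[np.array(idx)],
        bin_edges=matrix.bin_edges,
        sample_ids=[matrix.sample_ids[i] for i in idx],
        excluded_regions=list(matrix.excluded_regions),
        normalized=matrix.normalized,
    )


def _read_metadata(path, sample_ids):
    import pandas as pd

    if path is None:
        raise ValueError("metadata_tsv is required with file input")
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    labels = [df.loc[s, "group"] for s in sample_ids]
    stages = [df.loc[s].get("stage", "-") for s in sample_ids]
    return labels, stages


def _write_predictions(path, matrix, val_idx, true_labels, y_hat, pred_labels):
    lines = ["sample_id\ttrue\ty_hat\tpredicted"]
    for k, i in enumerate(val_idx):
        lines.append(
            f"{matrix.sample_ids[i]}\t{true_labels[k]}\t{y_hat[k]:.6f}\t{pred_labels[k]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_stocsy(path, sres):
    lines = ["bin_left\tbin_right\tp_corr\tp_cov"]
    for (lo, hi), pc, pv in zip(sres.bin_edges, sres.p_corr, sres.p_cov):
        lines.append(f"{lo:.4f}\t{hi:.4f}\t{pc:.6f}\t{pv:.6e}")
    Path(path).write_text("\n".join(lines) + "\n")
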