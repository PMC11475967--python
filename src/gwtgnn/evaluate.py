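"""Metrics and the ablation harness.

Metrics are the regression standards: MAE = (1/P) sum |y_i - y_i'|,
MSE = (1/P) sum (y_i - y_i')^2, RMSE = sqrt(MSE), plus a tolerance
accuracy — the percentage of predictions whose absolute error is within
a stated tolerance tau (default half the training-target standard
deviation), which operationalizes "accuracy %" for a regression model.

The ablation harness runs five arms on identical seeded 70/30 splits:

    gwt+gnn  graph-wavelet features (original + min + max orders) -> GNN
    gwt+nn   the same features -> feed-forward network (no graph)
    gnn      raw standardized features -> GNN
    dwt+gnn  plain wavelet decomposition (original order only) -> GNN
    ft+gnn   magnitude Fourier spectrum -> GNN

Feature standardization, the greedy orderings and the target scaling are
all fitted on the training split only and applied to the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import feature_graph as fg
from . import gnn as nn
from . import wavelets as wv
from .preprocess import (FeatureMatrix, FeatureTable, ScoreVector, clean_table,
                         encode_numeric, split_train_test, standardize_features,
                         take_rows)

ARMS = ("gwt+gnn", "gwt+nn", "gnn", "dwt+gnn", "ft+gnn")


@dataclass
class EvalMetrics:
    n: int
    mae: float
    mse: float
    rmse: float
    accuracy_pct: float
    tolerance: float


def compute_metrics(y_true, y_pred, tolerance: float) -> EvalMetrics:
    """MAE/MSE/RMSE and tolerance accuracy for paired score vectors."""
    yt = y_true.values if isinstance(y_true, ScoreVector) else np.asarray(y_true, float)
    yp = y_pred.values if isinstance(y_pred, ScoreVector) else np.asarray(y_pred, float)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise ValueError("cannot compute metrics on empty vectors")
    resid = yt - yp
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid ** 2))
    return EvalMetrics(n=yt.size, mae=mae, mse=mse, rmse=float(np.sqrt(mse)),
                       accuracy_pct=float(100.0 * np.mean(np.abs(resid) <= tolerance)),
                       tolerance=float(tolerance))


@dataclass
class AblationReport:
    cells: pd.DataFrame            # arm, target, seed, n, mae, mse, rmse, accuracy_pct
    split_indices: dict = field(default_factory=dict)   # seed -> (train, test)
    failures: list = field(default_factory=list)        # (arm, seed, reason)
    config: nn.TrainConfig | None = None

    def summary(self) -> pd.DataFrame:
        """Across-seed mean and standard deviation per (arm, target)."""
        return (self.cells
                .groupby(["arm", "target"], sort=False)[["mae", "mse", "rmse",
                                                         "accuracy_pct"]]
                .agg(["mean", "std"]))

    def mean_metric(self, arm: str, target: str, metric: str = "mse") -> float:
        sel = self.cells[(self.cells.arm == arm) & (self.cells.target == target)]
        return float(sel[metric].mean())

    def render(self) -> str:
        lines = ["Ablation study (per-(arm, target) mean over seeds)",
                 self.summary().round(4).to_string()]
        if self.failures:
            lines.append("failures: " + "; ".join(
                f"{a}/seed {s}: {r}" for a, s, r in self.failures))
        return "\n".join(lines)


def _arm_features(arm: str, X_train: FeatureMatrix, X_test: FeatureMatrix,
                  levels: int | None, start_vertex: int | None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    if arm in ("gwt+gnn", "gwt+nn"):
        u_min, u_max = fg.min_max_orderings(X_train, start_vertex)
        ftr = wv.assemble_features(X_train, u_min, u_max, levels=levels)
        fte = wv.assemble_features(X_test, u_min, u_max, levels=levels)
    elif arm == "dwt+gnn":
        ftr = wv.dwt_only_features(X_train, levels=levels)
        fte = wv.dwt_only_features(X_test, levels=levels)
    elif arm == "ft+gnn":
        ftr = wv.fourier_features(X_train)
        fte = wv.fourier_features(X_test)
    elif arm == "gnn":
        ftr = wv.identity_features(X_train)
        fte = wv.identity_features(X_test)
    else:
        raise ValueError(f"unknown ablation arm {arm!r}")
    return ftr.values, fte.values


def run_arm(arm: str, X_train: FeatureMatrix, X_test: FeatureMatrix,
            y_train: ScoreVector, y_test: ScoreVector,
            config: nn.TrainConfig, levels: int | None = None,
            start_vertex: int | None = None,
            tolerance: float | None = None) -> EvalMetrics:
    """One (arm, split): transform, fit, predict held-out rows, score.

    Targets are z-scored with training statistics for fitting and mapped
    back to the original scale before metrics are computed.
    """
    Ftr, Fte = _arm_features(arm, X_train, X_test, levels, start_vertex)
    y_std = y_train.standardize()
    if tolerance is None:
        tolerance = 0.5 * y_std.scale_sd
    if arm == "gwt+nn":
        pred_std = nn.mlp_baseline(Ftr, y_std.values, Fte, config)
    else:
        graph = nn.build_sample_graph(Ftr, Fte, k=config.k_neighbors,
                                      bandwidth=config.kernel_bandwidth)
        model, _ = nn.train_gnn(graph, y_std.values, config)
        pred_std = nn.predict(model, graph)[graph.test_indices]
    pred = pred_std * y_std.scale_sd + y_std.scale_mean
    return compute_metrics(y_test.values, pred, tolerance)


def run_ablation(table: FeatureTable, arms=ARMS, seeds=(0, 1, 2, 3, 4),
                 config: nn.TrainConfig | None = None,
                 train_fraction: float = 0.7,
                 levels: int | None = None,
                 missing_policy: str = "impute_median") -> AblationReport:
    """Full ablation matrix: every arm on identical splits, per seed."""
    if not arms or not seeds:
        raise ValueError("need at least one arm and one seed")
    base_config = config or nn.TrainConfig()
    cleaned = clean_table(table, missing_policy)
    X_all, targets, _ = encode_numeric(cleaned, standardize=False)
    M = X_all.shape[0]
    rows = []
    split_indices = {}
    failures = []
    for seed in seeds:
        tr_idx, te_idx = split_train_test(M, train_fraction, seed)
        split_indices[int(seed)] = (tr_idx, te_idx)
        X_tr_raw = take_rows(X_all, tr_idx)
        X_te_raw = take_rows(X_all, te_idx)
        X_tr = standardize_features(X_tr_raw)
        X_te = standardize_features(X_te_raw, X_tr.scale_means, X_tr.scale_sds)
        for arm in arms:
            cfg = nn.TrainConfig(**{**base_config.__dict__, "seed": int(seed)})
            for tname, y in targets.items():
                y_tr = ScoreVector(y.values[tr_idx], name=tname)
                y_te = ScoreVector(y.values[te_idx], name=tname)
                try:
                    m = run_arm(arm, X_tr, X_te, y_tr, y_te, cfg, levels=levels)
                except Exception as exc:   # noqa: BLE001 - isolate arm failures
                    failures.append((arm, int(seed), f"{tname}: {exc}"))
                    continue
                rows.append({"arm": arm, "target": tname, "seed": int(seed),
                             "n": m.n, "mae": m.mae, "mse": m.mse,
                             "rmse": m.rmse, "accuracy_pct": m.accuracy_pct,
                             "tolerance": m.tolerance})
    cells = pd.DataFrame(rows)
    return AblationReport(cells=cells, split_indices=split_indices,
                          failures=failures, config=base_config)
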