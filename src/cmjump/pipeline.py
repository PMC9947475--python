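"""End-to-end study pipeline: simulate/load jumps → features → model → reports.

`run_study` reproduces the whole experimental workflow on synthetic paired
recordings: the force-platform height (TOV on the clean 1000 samples/s trace)
is the reference outcome, the 26 smartphone-trace descriptors are the
predictors, and the comparison contrasts the raw smartphone height ``hSP``
with the learned estimate ``hMLP`` on the held-out test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    AgreementReport,
    BlandAltman,
    FeatureImportance,
    evaluate_heights,
    permutation_importance,
)
from .features import FEATURE_NAMES, feature_table, features_from_trace
from .kinematics import measure_jump
from .model import ModelBundle, predict_height, split_dataset, train_height_model
from .synthetic import DatasetConfig, JumpPair, simulate_dataset
from .vmd import VmdParams

logger = logging.getLogger(__name__)


def build_feature_table(pairs: list[JumpPair], vmd_params: VmdParams | None = None) -> pd.DataFrame:
    """Per-jump features from the SP traces plus the FP reference height.

    Layout: ``jump_id, hFP`` + the 26 canonical feature columns.
    """
    rows, h_fp = [], []
    for pair in pairs:
        fp_meas = measure_jump(pair.fp, pair.static_window)
        feats, _ = features_from_trace(pair.sp, pair.static_window, vmd_params=vmd_params)
        rows.append(feats)
        h_fp.append(fp_meas.height)
    return feature_table(rows, h_fp=h_fp)


@dataclass
class StudyResult:
    """Everything the end-to-end comparison produces."""

    features: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray
    bundle: ModelBundle
    h_fp_test: np.ndarray  # m
    h_sp_test: np.ndarray  # m
    h_mlp_test: np.ndarray  # m
    report_sp: AgreementReport
    report_mlp: AgreementReport
    ba_sp: BlandAltman
    ba_mlp: BlandAltman
    importance: FeatureImportance

    def summary(self) -> str:
        return (
            "raw smartphone (hSP) vs force platform:\n"
            + str(self.report_sp)
            + "\n\nMLP estimate (hMLP) vs force platform:\n"
            + str(self.report_mlp)
        )


def run_study(
    n: int = 200,
    seed: int = 0,
    config: DatasetConfig | None = None,
    alpha: float = 0.1,
    grid: dict | None = None,
    folds: int = 5,
    frac: float = 0.75,
    max_iter: int = 2000,
    pfi_repeats: int = 10,
) -> StudyResult:
    """Simulate n jumps, train the height model, and evaluate both estimators."""
    pairs = simulate_dataset(n, config=config, seed=seed)
    features = build_feature_table(pairs)
    return analyze_feature_table(
        features,
        seed=seed,
        alpha=alpha,
        grid=grid,
        folds=folds,
        frac=frac,
        max_iter=max_iter,
        pfi_repeats=pfi_repeats,
    )


def analyze_feature_table(
    features: pd.DataFrame,
    seed: int = 0,
    alpha: float = 0.1,
    grid: dict | None = None,
    folds: int = 5,
    frac: float = 0.75,
    max_iter: int = 2000,
    pfi_repeats: int = 10,
) -> StudyResult:
    """Split → train → predict → compare, from an assembled feature table."""
    if "hFP" not in features.columns:
        raise ValueError("feature table must contain the reference column 'hFP'")
    x = features[list(FEATURE_NAMES)]
    y = features["hFP"].to_numpy(dtype=float)
    train_idx, test_idx = split_dataset(len(features), frac=frac, seed=seed)
    bundle = train_height_model(
        x.iloc[train_idx], y[train_idx],
        alpha=alpha, grid=grid, folds=folds, seed=seed, max_iter=max_iter,
    )
    h_mlp_test = predict_height(bundle, x.iloc[test_idx])
    h_sp_test = x["hSP"].to_numpy(dtype=float)[test_idx]
    h_fp_test = y[test_idx]
    report_sp, ba_sp = evaluate_heights(h_fp_test, h_sp_test)
    report_mlp, ba_mlp = evaluate_heights(h_fp_test, h_mlp_test)
    fi = permutation_importance(
        bundle, x.iloc[train_idx], y[train_idx], seed=seed, n_repeats=pfi_repeats
    )
    logger.info("test-set MAE: hSP %.1f cm, hMLP %.1f cm", report_sp.mae, report_mlp.mae)
    return StudyResult(
        features=features,
        train_idx=train_idx,
        test_idx=test_idx,
        bundle=bundle,
        h_fp_test=h_fp_test,
        h_sp_test=h_sp_test,
        h_mlp_test=h_mlp_test,
        report_sp=report_sp,
        report_mlp=report_mlp,
        ba_sp=ba_sp,
        ba_mlp=ba_mlp,
        importance=fi,
    )
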