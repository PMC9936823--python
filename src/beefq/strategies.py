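"""The four phenotype-prediction strategies.

Two training models and four ways of assembling a validation prediction:

* Model 1 (full): y = mu + cg + days_aged + carcass_weight + PC1..PC4 +
  heterosis + Zg + e — breed structure handled explicitly as fixed effects.
* Model 5 (reduced): y = mu + cg + days_aged + carcass_weight + Zg + e —
  breed and heterosis effects left to be absorbed by the SNP effects.

Strategy 1: y_hat = Z g_hat                                   (Model 1)
Strategy 2: y_hat = Z g_hat + days_aged + carcass_weight
                    + PC1..PC4 + heterosis terms              (Model 1)
Strategy 3: y_hat = Z g_hat + PC1..PC4 + heterosis terms      (Model 1)
Strategy 4: y_hat = Z g_hat                                   (Model 5)

Each covariate term is the validation animal's covariate value times the
posterior-mean coefficient from training. The intercept and contemporary
group effects never enter a prediction: a validation animal's cg is treated
as unknown at prediction time.

Validation-animal PCs are computed by projecting validation genotypes onto
the training PCA (no leakage) by default; a joint all-animal PCA mode is
available since cross-validating one genotyped cohort typically computes
structure once on everyone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesr import BayesRConfig, BayesRPosterior, fit_bayesr

PC_NAMES = ("pc1", "pc2", "pc3", "pc4")
STRATEGY_TERMS = {
    1: ("Zg",),
    2: ("Zg", "days_aged", "carcass_weight", "pc1", "pc2", "pc3", "pc4", "het"),
    3: ("Zg", "pc1", "pc2", "pc3", "pc4", "het"),
    4: ("Zg",),
}


class StrategyUsageError(ValueError):
    pass


@dataclass
class TrainingData:
    """Complete per-animal arrays for one training set."""

    y: np.ndarray                 # clipped trait score
    cg: np.ndarray                # contemporary-group labels
    days_aged: np.ndarray
    carcass_weight: np.ndarray
    pcs: np.ndarray               # (n, 4) GRM principal components
    het: np.ndarray               # heterozygosity proportion
    Z: np.ndarray                 # (n, m) complete allele dosages


@dataclass
class StrategyPrediction:
    strategy: int
    y_hat: np.ndarray
    terms: tuple


def _cg_dummies(cg: np.ndarray):
    levels = sorted(pd.unique(np.asarray(cg, dtype=object)))
    if len(levels) < 1:
        raise ValueError("no contemporary groups")
    cols, names = [], []
    for lev in levels[1:]:  # drop the first level to identify the intercept
        cols.append((np.asarray(cg) == lev).astype(float))
        names.append(f"cg[{lev}]")
    return cols, names, levels


def _build_design(data: TrainingData, with_structure: bool):
    n = len(data.y)
    cols = [np.ones(n)]
    names = ["intercept"]
    cg_cols, cg_names, levels = _cg_dummies(data.cg)
    cols += cg_cols
    names += cg_names
    cols += [np.asarray(data.days_aged, float),
             np.asarray(data.carcass_weight, float)]
    names += ["days_aged", "carcass_weight"]
    if with_structure:
        for j, pc in enumerate(PC_NAMES):
            cols.append(np.asarray(data.pcs[:, j], float))
            names.append(pc)
        cols.append(np.asarray(data.het, float))
        names.append("het")
    return np.column_stack(cols), names, levels


def model1_design(data: TrainingData):
    """Full fixed design: intercept + cg dummies + days_aged +
    carcass_weight + PC1..PC4 + heterozygosity."""
    return _build_design(data, with_structure=True)


def model5_design(data: TrainingData):
    """Reduced fixed design: intercept + cg dummies + days_aged +
    carcass_weight (breed effects left to the SNPs)."""
    return _build_design(data, with_structure=False)


def train_model1(data: TrainingData, config: BayesRConfig) -> BayesRPosterior:
    X, names, _ = model1_design(data)
    return fit_bayesr(data.y, X, data.Z, config, fixed_names=names)


def train_model5(data: TrainingData, config: BayesRConfig) -> BayesRPosterior:
    X, names, _ = model5_design(data)
    return fit_bayesr(data.y, X, data.Z, config, fixed_names=names)


def _is_model1(posterior: BayesRPosterior) -> bool:
    return "pc1" in posterior.fixed_names


def predict(
    strategy: int,
    posterior: BayesRPosterior,
    Z: np.ndarray,
    days_aged: np.ndarray | None = None,
    carcass_weight: np.ndarray | None = None,
    pcs: np.ndarray | None = None,
    het: np.ndarray | None = None,
) -> StrategyPrediction:
    """Assemble the validation prediction for one strategy.

    ``Z`` holds raw allele dosages for the validation animals; covariates are
    required only for the terms the strategy includes.
    """
    if strategy not in STRATEGY_TERMS:
        raise StrategyUsageError(f"unknown strategy {strategy}")
    if strategy in (1, 2, 3) and not _is_model1(posterior):
        raise StrategyUsageError(
            f"strategy {strategy} needs a Model-1 posterior (with PC terms)"
        )
    if strategy == 4 and _is_model1(posterior):
        raise StrategyUsageError("strategy 4 needs a Model-5 posterior")

    y_hat = np.asarray(Z, float) @ posterior.mean_g
    if strategy == 2:
        if days_aged is None or carcass_weight is None:
            raise StrategyUsageError("strategy 2 needs days_aged and carcass_weight")
        y_hat = y_hat + np.asarray(days_aged, float) * posterior.fixed_effect("days_aged")
        y_hat = y_hat + np.asarray(carcass_weight, float) * posterior.fixed_effect(
            "carcass_weight"
        )
    if strategy in (2, 3):
        if pcs is None or het is None:
            raise StrategyUsageError(f"strategy {strategy} needs pcs and het")
        pcs = np.asarray(pcs, float)
        for j, pc in enumerate(PC_NAMES):
            y_hat = y_hat + pcs[:, j] * posterior.fixed_effect(pc)
        y_hat = y_hat + np.asarray(het, float) * posterior.fixed_effect("het")
    return StrategyPrediction(
        strategy=strategy, y_hat=y_hat, terms=STRATEGY_TERMS[strategy]
    )


def project_pcs(
    Z_train: np.ndarray, Z_val: np.ndarray, k: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Training-set GRM PCA with Nystrom projection of validation animals.

    Returns ``(train_scores, val_scores)``, both scaled by the square root of
    the training eigenvalues, with signs fixed as in the joint PCA.
    """
    Z_train = np.asarray(Z_train, float)
    Z_val = np.asarray(Z_val, float)
    p = Z_train.mean(axis=0) / 2.0
    seg = (p > 0) & (p < 1)
    denom = np.sqrt(2 * p[seg] * (1 - p[seg]))
    Wt = (Z_train[:, seg] - 2 * p[seg]) / denom
    Wv = (Z_val[:, seg] - 2 * p[seg]) / denom
    m = seg.sum()
    G = Wt @ Wt.T / m
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 1e-12, None)
    U = evecs[:, order]
    for j in range(k):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] = -U[:, j]
    train_scores = U * np.sqrt(lam)
    # kinship of validation to training animals, projected onto training axes
    val_scores = (Wv @ Wt.T / m) @ U / np.sqrt(lam)
    return train_scores, val_scores
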