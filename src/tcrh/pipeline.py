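"""Feature scaling and correlation pruning between featurization and training.

Fixed composition order: drop degenerate (zero-variance) features, prune
correlated features at |r| > threshold on the training matrix, then
standardize with train-fitted mean/variance. Train-only fitting is the
default to avoid information leaking from test to train; joint scaling is
available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean and standard deviation fitted on a training matrix."""

    feature_names: tuple
    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        if not np.all(self.scale > 0):
            raise ValueError("retained features must have positive sd")


@dataclass(frozen=True)
class PruneReport:
    """Outcome of correlation pruning: retained names and removal pairs."""

    threshold: float
    seed: int
    retained: tuple
    removed: tuple = field(default_factory=tuple)  # (removed_name, partner_name)

    @property
    def removed_names(self) -> tuple:
        return tuple(r for r, _ in self.removed)


def drop_degenerate(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove zero-variance (constant) columns; the training matrix decides."""
    variances = features.var(axis=0, ddof=0)
    dropped = list(features.columns[variances == 0.0])
    if len(dropped) == features.shape[1]:
        raise ValueError("all features are degenerate")
    return features.drop(columns=dropped), dropped


def fit_scaler(train_features: pd.DataFrame) -> ScalerParams:
    """Fit per-feature mean and (population) standard deviation on train."""
    sc = StandardScaler().fit(train_features.to_numpy())
    return ScalerParams(tuple(train_features.columns), sc.mean_.copy(),
                        np.sqrt(sc.var_))


def apply_scaler(params: ScalerParams, features: pd.DataFrame) -> pd.DataFrame:
    """Standardize a matrix with train-fitted parameters (names must match)."""
    if tuple(features.columns) != params.feature_names:
        raise ValueError("feature names/order differ from the fitted scaler")
    return (features - params.mean) / params.scale


def prune_correlated(train_features: pd.DataFrame, threshold: float = 0.8,
                     seed: int = 0) -> PruneReport:
    """Greedy removal of one member of every feature pair with |r| > threshold.

    Pearson correlations are computed on the training matrix only. Pairs are
    enumerated in lexicographic name order; whenever both members of an
    over-threshold pair are still retained, a seeded coin flip removes one.
    A single ordered pass suffices: any pair still jointly retained at the end
    was examined while both were retained, hence is within threshold.
    """
    if train_features.shape[1] < 2:
        raise ValueError("need at least 2 features to prune")
    corr = train_features.corr().abs()
    rng = np.random.default_rng(seed)
    retained = set(train_features.columns)
    removed = []
    for a, b in combinations(sorted(train_features.columns), 2):
        if a in retained and b in retained and corr.loc[a, b] > threshold:
            victim, partner = (a, b) if rng.integers(2) == 0 else (b, a)
            retained.discard(victim)
            removed.append((victim, partner))
    kept = tuple(c for c in train_features.columns if c in retained)
    return PruneReport(threshold, seed, kept, tuple(removed))


def apply_prune(report: PruneReport, features: pd.DataFrame) -> pd.DataFrame:
    return features[list(report.retained)]


def prepare_features(train: pd.DataFrame, test: pd.DataFrame,
                     threshold: float = 0.8, seed: int = 0,
                     scale_jointly: bool = False):
    """Full preprocessing: degenerate drop -> prune -> scale (train-fitted).

    Returns ``(train_scaled, test_scaled, prune_report, scaler, dropped)``.
    With ``scale_jointly`` the scaler is fitted on train+test stacked (the
    permissive reading of whole-dataset scaling); default is train-only.
    """
    train2, dropped = drop_degenerate(train)
    test2 = test[train2.columns]
    report = prune_correlated(train2, threshold, seed)
    train3, test3 = apply_prune(report, train2), apply_prune(report, test2)
    fit_on = pd.concat([train3, test3], ignore_index=True) if scale_jointly else train3
    scaler = fit_scaler(fit_on)
    return apply_scaler(scaler, train3), apply_scaler(scaler, test3), report, scaler, dropped
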