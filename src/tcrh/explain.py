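"""Model-agnostic KernelSHAP feature attributions.

A coalition z in {0,1}^M keeps the instance's value for features with z_j = 1
and substitutes background values elsewhere; its value v(z) is the mean model
score over the background rows so masked. Shapley attributions phi solve the
Shapley-kernel-weighted least squares

    min_phi  sum_z pi(z) (v(z) - phi_0 - sum_j phi_j z_j)^2,
    pi(z) = (M - 1) / (C(M, |z|) * |z| * (M - |z|)),

subject to the efficiency constraint phi_0 + sum_j phi_j = f(x), with
phi_0 the base value (mean score over the background). The constraint is
enforced exactly by eliminating one unknown, so every explanation satisfies
local accuracy to solver precision. With all 2^M - 2 interior coalitions the
solution equals the classical Shapley value; the sampled estimator draws
coalitions from the kernel distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ShapConfig:
    """Sampling settings for KernelSHAP."""

    n_samples: int = 100
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass(frozen=True)
class Explanation:
    """Per-instance Shapley attributions plus the background base value."""

    base_value: float
    phi: pd.Series
    instance_id: object = None

    @property
    def prediction(self) -> float:
        return self.base_value + float(self.phi.sum())


def shapley_kernel_weight(M: int, s: int) -> float:
    """pi(z) for a coalition of size s out of M (infinite at s in {0, M})."""
    if s <= 0 or s >= M:
        return float("inf")
    return (M - 1) / (comb(M, s) * s * (M - s))


def _coalition_values(score_fn, instance: np.ndarray, background: np.ndarray,
                      Z: np.ndarray) -> np.ndarray:
    """v(z) for each coalition row of Z, batched into one score_fn call."""
    n_z, M = Z.shape
    k = background.shape[0]
    tiled = np.repeat(background[None, :, :], n_z, axis=0)  # (n_z, k, M)
    mask = Z.astype(bool)[:, None, :]
    tiled = np.where(mask, instance[None, None, :], tiled)
    scores = np.asarray(score_fn(tiled.reshape(n_z * k, M)), dtype=float)
    return scores.reshape(n_z, k).mean(axis=1)


def _solve_constrained(Z: np.ndarray, v: np.ndarray, w: np.ndarray,
                       base: float, fx: float) -> np.ndarray:
    """Weighted least squares with the efficiency constraint eliminated
    through the last feature: phi_M = (fx - base) - sum_{j<M} phi_j."""
    M = Z.shape[1]
    e = fx - base
    zM = Z[:, -1].astype(float)
    A = Z[:, :-1].astype(float) - zM[:, None]
    y = v - base - zM * e
    sw = np.sqrt(w)
    phi_head, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    phi = np.empty(M)
    phi[:-1] = phi_head
    phi[-1] = e - phi_head.sum()
    return phi


def _sample_coalitions(M: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw coalitions from the size-aggregated kernel distribution
    p(s) ∝ (M-1) / (s (M-s)), subsets uniform within a size."""
    sizes = np.arange(1, M)
    p = (M - 1) / (sizes * (M - sizes))
    p = p / p.sum()
    Z = np.zeros((n_samples, M), dtype=int)
    drawn_sizes = rng.choice(sizes, size=n_samples, p=p)
    for i, s in enumerate(drawn_sizes):
        Z[i, rng.choice(M, size=s, replace=False)] = 1
    return Z


def kernel_shap(score_fn, instance, background, config: ShapConfig = ShapConfig(),
                instance_id=None) -> Explanation:
    """Explain one instance of a real-valued model.

    ``score_fn`` maps an (n, M) array to n scores; ``instance`` is a length-M
    Series (named) or array; ``background`` is a (k, M) DataFrame or array
    serving as the reference distribution. Deterministic given
    ``config.seed``; with ``config.exhaustive`` all 2^M - 2 interior
    coalitions are used and the result is the exact Shapley value.
    """
    names = list(instance.index) if isinstance(instance, pd.Series) else None
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0 or bg.shape[1] != x.size:
        raise ValueError("background must be a non-empty (k, M) matrix")
    M = x.size
    if M < 2:
        raise ValueError("need at least 2 features")

    base = float(np.mean(np.asarray(score_fn(bg), dtype=float)))
    fx = float(np.asarray(score_fn(x[None, :]), dtype=float)[0])

    if config.exhaustive or config.n_samples >= 2 ** M - 2:
        sizes = np.arange(2 ** M)
        Z = ((sizes[:, None] >> np.arange(M)) & 1).astype(int)
        Z = Z[(Z.sum(axis=1) > 0) & (Z.sum(axis=1) < M)]
        w = np.array([shapley_kernel_weight(M, int(s)) for s in Z.sum(axis=1)])
    else:
        rng = np.random.default_rng(config.seed)
        Z = _sample_coalitions(M, config.n_samples, rng)
        for _ in range(10):  # degenerate design guard
            if len(np.unique(Z, axis=0)) >= 2:
                break
            warnings.warn("degenerate coalition sample; resampling")
            Z = _sample_coalitions(M, config.n_samples, rng)
        w = np.ones(len(Z))

    v = _coalition_values(score_fn, x, bg, Z)
    phi = _solve_constrained(Z, v, w, base, fx)
    index = names if names is not None else list(range(M))
    return Explanation(base, pd.Series(phi, index=index), instance_id)


def summarize(explanations: list[Explanation], top_k: int = 50) -> pd.DataFrame:
    """Global importance: mean |phi| per feature, ranked descending.

    Ties are broken by feature name; the table is truncated to ``top_k`` rows
    and is plot-ready (feature, mean_abs_shap, rank).
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    index0 = list(explanations[0].phi.index)
    for ex in explanations:
        if list(ex.phi.index) != index0:
            raise ValueError("explanations have inconsistent feature sets")
    mat = np.vstack([ex.phi.to_numpy() for ex in explanations])
    mean_abs = pd.Series(np.abs(mat).mean(axis=0), index=index0, name="mean_abs_shap")
    df = (mean_abs.rename_axis("feature").reset_index()
          .sort_values(["mean_abs_shap", "feature"], ascending=[False, True],
                       kind="stable")
          .reset_index(drop=True))
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(min(top_k, len(df)))


def explain_model(model, train_X: pd.DataFrame, test_X: pd.DataFrame,
                  n_instances: int = 200, n_background: int = 100,
                  n_samples: int = 100, top_k: int = 50, seed: int = 0):
    """Explain a seeded subsample of test instances against a seeded
    background subsample of the training matrix; returns
    ``(explanations, summary_table)``."""
    from .model_eval import decision_scores

    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(train_X), size=min(n_background, len(train_X)),
                        replace=False)
    inst_idx = rng.choice(len(test_X), size=min(n_instances, len(test_X)),
                          replace=False)
    background = train_X.iloc[bg_idx]

    def score_fn(arr):
        return decision_scores(model, pd.DataFrame(arr, columns=train_X.columns))

    explanations = []
    for j, i in enumerate(inst_idx):
        cfg = ShapConfig(n_samples=n_samples, seed=int(rng.integers(2 ** 31)))
        explanations.append(
            kernel_shap(score_fn, test_X.iloc[i], background, cfg,
                        instance_id=int(i)))
    return explanations, summarize(explanations, top_k)
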