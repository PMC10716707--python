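"""Shapley-value feature attribution.

Attributions use the interventional value function

    v(S) = E_b[ f(x_S, b_{~S}) ],

the expectation over a background sample of the model score with the
features in coalition S taken from the explained row and the rest from
the background row.  For a fitted decision tree the score depends only
on the features appearing on its decision paths, so every unused feature
is a dummy player with attribution exactly zero and exact enumeration
over the used features is exact for the full game.  For larger player
sets a seeded permutation-sampling estimate is used instead.

Local accuracy holds for the exact computation: the signed attributions
of a row sum to f(row) minus the background mean score.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

EXACT_PLAYER_LIMIT = 12


def _score_fn(model):
    """Continuous score: P(class 1) where available, decision margin
    otherwise.  Models fitted on DataFrames are scored on raw arrays
    here, so the feature-name mismatch warning is silenced."""
    import warnings

    if hasattr(model, "predict_proba"):
        raw = lambda X: model.predict_proba(X)[:, 1]
    elif hasattr(model, "decision_function"):
        raw = model.decision_function
    else:
        raise TypeError(f"{type(model).__name__} exposes no score function")

    def score(X):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*feature names.*")
            return raw(X)

    return score


def _coalition_values(f, x: np.ndarray, background: np.ndarray,
                      players: list[int]) -> dict[frozenset, float]:
    """v(S) for every coalition S over ``players`` in one batched call."""
    n_b, d = background.shape
    subsets = []
    for r in range(len(players) + 1):
        subsets.extend(frozenset(c) for c in combinations(players, r))
    blocks = np.empty((len(subsets) * n_b, d))
    for i, s in enumerate(subsets):
        block = background.copy()
        if s:
            block[:, list(s)] = x[list(s)]
        blocks[i * n_b:(i + 1) * n_b] = block
    scores = f(blocks).reshape(len(subsets), n_b).mean(axis=1)
    return dict(zip(subsets, scores))


def exact_shapley_row(f, x: np.ndarray, background: np.ndarray,
                      players: list[int] | None = None) -> np.ndarray:
    """Exact Shapley attributions of one row by coalition enumeration
    (all features are players unless a subset is given)."""
    d = x.shape[0]
    players = list(range(d)) if players is None else list(players)
    m = len(players)
    if m > EXACT_PLAYER_LIMIT:
        raise ValueError(f"{m} players exceeds exact enumeration limit "
                         f"{EXACT_PLAYER_LIMIT}")
    values = _coalition_values(f, x, background, players)
    phi = np.zeros(d)
    fact = [factorial(i) for i in range(m + 1)]
    for i in players:
        others = [p for p in players if p != i]
        total = 0.0
        for r in range(m):
            w = fact[r] * fact[m - r - 1] / fact[m]
            for combo in combinations(others, r):
                s = frozenset(combo)
                total += w * (values[s | {i}] - values[s])
        phi[i] = total
    return phi


def sampled_shapley_row(f, x: np.ndarray, background: np.ndarray,
                        rng: np.random.Generator,
                        players: list[int] | None = None,
                        n_permutations: int = 64) -> np.ndarray:
    """Permutation-sampling Shapley estimate of one row."""
    d = x.shape[0]
    players = list(range(d)) if players is None else list(players)
    phi = np.zeros(d)
    n_b = background.shape[0]
    for _ in range(n_permutations):
        order = rng.permutation(players)
        z = background.copy()
        prev = f(z).mean()
        for i in order:
            z[:, i] = x[i]
            cur = f(z).mean()
            phi[i] += cur - prev
            prev = cur
    return phi / n_permutations


def shapley_attributions(model, X: np.ndarray,
                         background: np.ndarray | None = None,
                         seed: int = 0, players: list[int] | None = None,
                         n_permutations: int = 64,
                         background_size: int = 64) -> np.ndarray:
    """Per-row, per-feature Shapley attributions for a fitted model.

    Exact enumeration when the player set is small enough, seeded
    permutation sampling otherwise.
    """
    f = _score_fn(model)
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if background is None:
        background = X
    background = np.asarray(background, dtype=float)
    if len(background) > background_size:
        background = background[rng.choice(len(background), background_size,
                                           replace=False)]
    d = X.shape[1]
    players = list(range(d)) if players is None else list(players)
    out = np.zeros_like(X)
    for r, x in enumerate(X):
        if len(players) <= EXACT_PLAYER_LIMIT:
            out[r] = exact_shapley_row(f, x, background, players)
        else:
            out[r] = sampled_shapley_row(f, x, background, rng, players,
                                         n_permutations)
    return out


def tree_used_features(tree: DecisionTreeClassifier) -> list[int]:
    feats = tree.tree_.feature
    return sorted(set(int(f) for f in feats if f >= 0))


def shap_tree_importance(X, y, seed: int = 0, max_depth: int = 5,
                         background_size: int = 64,
                         max_rows: int = 100) -> pd.DataFrame:
    """Mean |Shapley attribution| per feature for a decision tree fitted
    on (X, y), ranked descending.

    Only features on the tree's decision paths are players; everything
    else is a dummy with attribution exactly zero.  When the player set
    is small enough the attribution is exact; attributions are averaged
    over a seeded row subsample of at most ``max_rows`` rows.
    """
    frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(frame.to_numpy(dtype=float), y)
    players = tree_used_features(tree)
    rows = frame.to_numpy(dtype=float)
    if len(rows) > max_rows:
        sub = np.random.default_rng(seed).choice(len(rows), max_rows,
                                                 replace=False)
        explained = rows[sub]
    else:
        explained = rows
    attr = shapley_attributions(tree, explained, background=rows,
                                seed=seed, players=players,
                                background_size=background_size)
    mean_abs = np.abs(attr).mean(axis=0)
    out = pd.DataFrame({"feature": frame.columns, "mean_abs_shap": mean_abs})
    out = out.sort_values(["mean_abs_shap", "feature"],
                          ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
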