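"""Probing internal representations.

Spatial tuning maps of recurrent units, ridge decoding of position (and
other task variables) from module activities, decoding error, and the
uncertainty-sweep procedure that fingerprints an agent's effective Kalman
gain by how its stopping accuracy degrades when task noise exceeds the
training noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from fireflynav.behavior_metrics import psychometric_and_roc
from fireflynav.task_env import EpisodeRecord

__all__ = [
    "ActivityMatrix",
    "AucDropTable",
    "collect_activity",
    "spatial_tuning",
    "save_tuning_map",
    "ridge_fit",
    "ridge_decode",
    "decoding_error",
    "uncertainty_sweep",
    "gain_fingerprint_correlation",
    "UNCERTAINTY_GRID",
]

#: added-uncertainty grid (units of the joystick gain G)
UNCERTAINTY_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)


@dataclass
class ActivityMatrix:
    """Pooled unit activity (rows = time steps over trials, columns = units
    of one named module) with the aligned decoding-target matrix and the
    trial id of every row (for trial-level splits)."""

    X: np.ndarray
    S: np.ndarray
    trial_ids: np.ndarray
    module: str = ""

    def __post_init__(self) -> None:
        if len(self.X) != len(self.S) or len(self.X) != len(self.trial_ids):
            raise ValueError("activity, target and trial-id row counts differ")
        if np.isnan(self.X).any() or np.isnan(self.S).any():
            raise ValueError("missing values in activity or target matrix")


def collect_activity(episodes: Sequence[EpisodeRecord], module: str,
                     targets: str | Sequence[str] = ("x", "y")) -> ActivityMatrix:
    """Pool a module's recorded hidden activity across episodes.

    ``targets`` names columns of the state to decode (any of x, y, theta,
    v, omega, gx, gy).
    """
    if isinstance(targets, str):
        targets = [t.strip() for t in targets.split(",")]
    cols = {"x": 0, "y": 1, "theta": 2, "v": 3, "omega": 4, "gx": 5, "gy": 6}
    X_rows, S_rows, ids = [], [], []
    for k, ep in enumerate(episodes):
        if ep.hidden is None or module not in ep.hidden:
            raise KeyError(f"episode {k} has no recorded activity for {module!r}")
        X_rows.append(ep.hidden[module])
        s_cols = []
        for t in targets:
            if t in ("x_rel", "y_rel"):   # position relative to the target
                j = 0 if t == "x_rel" else 1
                s_cols.append(ep.states[:, j] - ep.states[:, 5 + j])
            else:
                s_cols.append(ep.states[:, cols[t]])
        S_rows.append(np.stack(s_cols, axis=1))
        ids.append(np.full(len(ep), k))
    return ActivityMatrix(np.vstack(X_rows), np.vstack(S_rows),
                          np.concatenate(ids), module=module)


# ---------------------------------------------------------------------------
# spatial tuning
# ---------------------------------------------------------------------------

def spatial_tuning(activity: np.ndarray, positions: np.ndarray,
                   cell_size: float = 5.0, boxcar: float = 40.0,
                   extent: Optional[tuple] = None):
    """2-D tuning map of one unit: linear interpolation of scattered
    (position, activity) samples onto a regular grid, then a boxcar filter
    of the given width/height.  Cells outside the convex hull are NaN.

    Returns (map, x_edges, y_edges).
    """
    from scipy.interpolate import griddata
    from scipy.ndimage import uniform_filter

    positions = np.asarray(positions, dtype=float)
    activity = np.asarray(activity, dtype=float).ravel()
    if len(positions) != len(activity):
        raise ValueError("positions and activity lengths differ")
    if len(positions) < 3 or np.linalg.matrix_rank(
            positions - positions.mean(0)) < 2:
        raise ValueError("degenerate (collinear) sample set")
    if extent is None:
        (x0, y0), (x1, y1) = positions.min(0), positions.max(0)
    else:
        x0, x1, y0, y1 = extent
    xg = np.arange(x0, x1 + cell_size, cell_size)
    yg = np.arange(y0, y1 + cell_size, cell_size)
    XX, YY = np.meshgrid(xg, yg, indexing="ij")
    interp = griddata(positions, activity, (XX, YY), method="linear")

    k = max(1, int(round(boxcar / cell_size)))
    valid = ~np.isnan(interp)
    filled = np.where(valid, interp, 0.0)
    smoothed = uniform_filter(filled, size=k, mode="constant")
    weight = uniform_filter(valid.astype(float), size=k, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = smoothed / weight
    out[weight <= 0] = np.nan
    out[~valid] = np.nan
    return out, xg, yg


def save_tuning_map(tuning_map: np.ndarray, x_edges: np.ndarray,
                    y_edges: np.ndarray, path) -> None:
    """Write a tuning map as a plain-text matrix with a JSON sidecar holding
    the grid origin and cell size."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savetxt(path, tuning_map)
    meta = {
        "x_origin": float(x_edges[0]),
        "y_origin": float(y_edges[0]),
        "cell_size": float(x_edges[1] - x_edges[0]),
        "shape": list(tuning_map.shape),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# ridge decoding
# ---------------------------------------------------------------------------

def ridge_fit(X: np.ndarray, S: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge estimator W = (X'X + lam I)^-1 X'S."""
    n = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(n), X.T @ S)


def ridge_decode(data: ActivityMatrix,
                 lambda_grid: Sequence[float] = (0.1, 1.0, 10.0),
                 train_frac: float = 0.7, n_folds: int = 5,
                 rng: Optional[np.random.Generator] = None):
    """Ridge decoding with a trial-level 70/30 split.

    lambda is chosen by k-fold cross-validation (over trials) within the
    training split.  Returns a dict with the weights, the chosen lambda,
    test-set predictions/targets, and the index arrays of the split.
    """
    rng = rng or np.random.default_rng(0)
    trials = np.unique(data.trial_ids)
    perm = rng.permutation(trials)
    n_train = int(round(train_frac * len(trials)))
    train_trials, test_trials = perm[:n_train], perm[n_train:]
    train_mask = np.isin(data.trial_ids, train_trials)
    test_mask = ~train_mask

    Xtr, Str = data.X[train_mask], data.S[train_mask]
    ids_tr = data.trial_ids[train_mask]

    folds = np.array_split(rng.permutation(train_trials), n_folds)
    cv_err = []
    for lam in lambda_grid:
        errs = []
        for fold in folds:
            if len(fold) == 0:
                continue
            val = np.isin(ids_tr, fold)
            W = ridge_fit(Xtr[~val], Str[~val], lam)
            errs.append(float(np.mean((Xtr[val] @ W - Str[val]) ** 2)))
        cv_err.append(np.mean(errs))
    lam = float(lambda_grid[int(np.argmin(cv_err))])

    W = ridge_fit(Xtr, Str, lam)
    pred = data.X[test_mask] @ W
    return {
        "W": W,
        "lambda": lam,
        "cv_errors": dict(zip(lambda_grid, cv_err)),
        "predictions": pred,
        "targets": data.S[test_mask],
        "test_trial_ids": data.trial_ids[test_mask],
        "train_trials": train_trials,
        "test_trials": test_trials,
    }


def decoding_error(predicted: np.ndarray, truth: np.ndarray,
                   trial_ids: Optional[np.ndarray] = None) -> float:
    """Mean Euclidean step-wise error; with ``trial_ids``, the per-trial
    means are averaged (the reported statistic)."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    err = np.linalg.norm(predicted - truth, axis=-1)
    if trial_ids is None:
        return float(np.mean(err))
    trial_ids = np.asarray(trial_ids)
    return float(np.mean([err[trial_ids == k].mean()
                          for k in np.unique(trial_ids)]))


# ---------------------------------------------------------------------------
# Kalman-gain fingerprinting
# ---------------------------------------------------------------------------

@dataclass
class AucDropTable:
    """AUC(training uncertainties) - AUC(test uncertainties) on the grid of
    added (sigma_a, sigma_o) uncertainties; rows index added sigma_a."""

    grid: tuple = UNCERTAINTY_GRID
    drops: np.ndarray = None
    baseline_auc: float = float("nan")

    def flat(self) -> np.ndarray:
        return np.asarray(self.drops, dtype=float).ravel()


def uncertainty_sweep(run_trials: Callable[[float, float, int, np.random.Generator], tuple],
                      alpha_a: float, alpha_o: float,
                      n_trials: int = 2000,
                      grid: Sequence[float] = UNCERTAINTY_GRID,
                      rng: Optional[np.random.Generator] = None) -> AucDropTable:
    """Sweep test uncertainties above the training levels and tabulate the
    AUC drop.

    ``run_trials(alpha_a, alpha_o, n, rng) -> (stops, targets)`` rolls out
    the frozen agent with the given *environment* noise levels (the agent's
    internal gain stays at its training value; that is the caller's
    responsibility).  The (+0, +0) cell is the baseline and its drop is 0
    by construction.
    """
    rng = rng or np.random.default_rng(0)
    grid = tuple(grid)
    aucs = np.empty((len(grid), len(grid)))
    for ia, da in enumerate(grid):
        for io, do in enumerate(grid):
            sub_rng = np.random.default_rng(rng.integers(2 ** 63))
            stops, targets = run_trials(alpha_a + da, alpha_o + do,
                                        n_trials, sub_rng)
            aucs[ia, io] = psychometric_and_roc(stops, targets,
                                                rng=sub_rng).auc
    drops = aucs[0, 0] - aucs
    drops[0, 0] = 0.0
    return AucDropTable(grid=grid, drops=drops, baseline_auc=float(aucs[0, 0]))


def gain_fingerprint_correlation(table: AucDropTable,
                                 reference: AucDropTable,
                                 rng: Optional[np.random.Generator] = None,
                                 n_boot: int = 10_000) -> dict:
    """Pearson correlation between two flattened AUC-drop tables with a
    bootstrap CI (resampling grid entries) and a shuffled-entry null."""
    if tuple(table.grid) != tuple(reference.grid):
        raise ValueError("tables are on different grids")
    a = table.flat()
    b = reference.flat()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant table: correlation undefined")
    rng = rng or np.random.default_rng(0)

    def _r(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    r = _r(a, b)
    n = len(a)
    boot = np.empty(n_boot)
    null = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.std(a[idx]) == 0 or np.std(b[idx]) == 0:
            idx = rng.integers(0, n, size=n)
        boot[k] = _r(a[idx], b[idx])
        null[k] = _r(a, b[rng.permutation(n)])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"r": r, "ci": (float(lo), float(hi)),
            "null_mean": float(np.mean(null)), "bootstrap": boot, "null": null}
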