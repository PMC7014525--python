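"""Method-comparison protocol: error rate, RMSE, Bland-Altman agreement.

Two speed estimators are compared on the same strides with three
criteria: the percentage of strides whose absolute error exceeds a
practical threshold (0.6 m/s, the accuracy show-jumping professionals
consider useful), the RMSE, and the width of the Bland-Altman 95% limits
of agreement.  To damp sampling fluctuation, the dataset is split 50
times into random 80% training / 20% test partitions at the stride
level, and per-repetition metrics are summarized (mean / min / max of
the error percentage; mean and SD of RMSE and LoA width).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import clone

from .types import StrideDataset


def _check_pair(measured, predicted, min_n: int = 1):
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {measured.size} measured vs {predicted.size} predicted"
        )
    if measured.size < min_n:
        raise ValueError(f"need at least {min_n} paired values, got {measured.size}")
    return measured, predicted


def percent_error_above(measured, predicted, threshold: float = 0.6) -> float:
    """Percentage of strides with |measured - predicted| strictly above
    the threshold (0.6 m/s by default); an error of exactly the threshold
    is not counted."""
    measured, predicted = _check_pair(measured, predicted, min_n=1)
    return 100.0 * float(np.mean(np.abs(measured - predicted) > threshold))


def rmse(measured, predicted) -> float:
    """Root-mean-squared error between measured and predicted speeds."""
    measured, predicted = _check_pair(measured, predicted, min_n=1)
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement between predicted and measured speeds.

    Differences are oriented predicted - measured, so a method that
    underestimates fast strides shows negative differences at high means.
    Limits of agreement are bias +/- 1.96 x sample SD of the differences.
    """

    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    differences: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)

    @property
    def width(self) -> float:
        """Span of the 95% limits of agreement, 2 x 1.96 x SD."""
        return self.loa_high - self.loa_low


def bland_altman(measured, predicted) -> BlandAltmanResult:
    """Bland-Altman analysis of two per-stride speed series (n >= 2)."""
    measured, predicted = _check_pair(measured, predicted, min_n=2)
    diff = predicted - measured
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(
        mean_bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        differences=diff,
        means=(predicted + measured) / 2.0,
    )


@dataclass
class EvaluationReport:
    """Per-repetition metric rows plus per-method summaries.

    ``rows`` has one record per (repetition, method) with pct_error_above,
    rmse and loa_width; ``summary`` aggregates them per method the way the
    comparison table is laid out (mean/min/max of the error percentage,
    mean and SD of RMSE and LoA width).  The summary is always
    recomputable from the rows.
    """

    rows: pd.DataFrame
    params: dict

    @property
    def summary(self) -> pd.DataFrame:
        return summarize_rows(self.rows)


def summarize_rows(rows: pd.DataFrame) -> pd.DataFrame:
    g = rows.groupby("method")
    out = pd.DataFrame(
        {
            "pct_error_above_mean": g["pct_error_above"].mean(),
            "pct_error_above_min": g["pct_error_above"].min(),
            "pct_error_above_max": g["pct_error_above"].max(),
            "rmse_mean": g["rmse"].mean(),
            "rmse_sd": g["rmse"].std(ddof=1),
            "loa_width_mean": g["loa_width"].mean(),
            "loa_width_sd": g["loa_width"].std(ddof=1),
        }
    )
    return out.reset_index()


def repeated_holdout(
    dataset: StrideDataset,
    methods: Mapping[str, object],
    n_reps: int = 50,
    train_fraction: float = 0.8,
    threshold: float = 0.6,
    seed: int | None = None,
    group_by_horse: bool = False,
) -> EvaluationReport:
    """Repeated random-split comparison of speed estimators.

    For each of ``n_reps`` repetitions a seeded uniform random split
    assigns ``train_fraction`` of the strides to training and the rest to
    test (disjoint: no stride appears in both).  Every method — a
    scikit-learn style estimator with fit/predict — is cloned, trained on
    the training strides and scored on the test strides with all three
    metrics.  Splits are drawn at the stride level by default; with
    ``group_by_horse`` whole horses are assigned to one side, preventing
    strides of one horse from informing its own test predictions.

    A master seed deterministically spawns one child seed per repetition,
    so repetitions are independent but the whole protocol is reproducible.
    """
    if not isinstance(methods, Mapping):
        pairs = list(methods)
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate method names")
        methods = dict(pairs)
    names = list(methods)
    n = len(dataset)
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError(
            f"train fraction {train_fraction} leaves an empty partition for n={n}"
        )
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_reps)
    X_all = dataset.window_array()
    records = []
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        if group_by_horse:
            horses = dataset.meta["horse_id"].to_numpy()
            uniq = np.array(sorted(set(horses)))
            perm = rng.permutation(len(uniq))
            n_h_train = max(1, int(round(train_fraction * len(uniq))))
            if n_h_train >= len(uniq):
                raise ValueError("too few horses for a grouped split")
            train_h = set(uniq[perm[:n_h_train]])
            train_idx = np.flatnonzero([h in train_h for h in horses])
            test_idx = np.flatnonzero([h not in train_h for h in horses])
        else:
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError("empty train or test partition")
        y_train = dataset.speeds[train_idx]
        y_test = dataset.speeds[test_idx]
        for name in names:
            est = clone(methods[name])
            est.fit(X_all[train_idx], y_train)
            pred = est.predict(X_all[test_idx])
            ba = bland_altman(y_test, pred)
            records.append(
                {
                    "repetition": rep,
                    "method": name,
                    "pct_error_above": percent_error_above(y_test, pred, threshold),
                    "rmse": rmse(y_test, pred),
                    "loa_width": ba.width,
                    "bias": ba.mean_bias,
                    "n_test": int(len(test_idx)),
                }
            )
    rows = pd.DataFrame.from_records(records)
    params = {
        "n_reps": n_reps,
        "train_fraction": train_fraction,
        "threshold": threshold,
        "seed": seed,
        "group_by_horse": group_by_horse,
        "n_strides": n,
    }
    return EvaluationReport(rows=rows, params=params)


def make_bland_altman_figure(result: BlandAltmanResult):
    """Build the Bland-Altman figure: difference vs. mean scatter with
    bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.differences, s=12, facecolors="none",
               edgecolors="tab:blue")
    ax.axhline(result.mean_bias, color="k", lw=1.2, label="bias")
    ax.axhline(result.loa_low, color="r", ls="--", lw=1.0, label="95% LoA")
    ax.axhline(result.loa_high, color="r", ls="--", lw=1.0)
    ax.set_xlabel("mean of measured and predicted speed (m/s)")
    ax.set_ylabel("predicted - measured speed (m/s)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def plot_bland_altman(result: BlandAltmanResult, path: str | Path) -> None:
    """Write the Bland-Altman plot for one repetition to ``path``."""
    import matplotlib.pyplot as plt

    fig = make_bland_altman_figure(result)
    fig.savefig(path, dpi=120)
    plt.close(fig)
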