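"""Cross-validation orchestration and the metric surface.

Provides grouped (block) k-fold splitting that respects overlapping-window
leakage, the binary metric set (accuracy mean +/- SD across folds, ROC/AUC,
confusion counts, per-class sensitivity/specificity), phase-contrast
behavior summaries with Welch t-tests, and an end-to-end pipeline evaluator
covering the tabular models, their majority-vote ensemble, and the sequence
model on shared folds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import DAY, NIGHT, EthogramStream, PhaseSchedule, phase_of
from .sequence import (
    SequenceArchSpec,
    build_sequence_model,
    predict_night_prob,
    train_sequence_model,
)
from .tabular import ModelSpec, fit_classifier, majority_vote
from .windows import SampleSeries, WindowSet, flatten_windows

__all__ = [
    "EvalReport",
    "BehaviorSummary",
    "Protocol",
    "block_kfold",
    "block_split",
    "confusion_counts",
    "roc_auc",
    "sensitivity_specificity",
    "behavior_summary",
    "bout_counts_per_window",
    "evaluate_pipeline",
    "balanced_indices",
]

TABULAR_KINDS = ("logistic", "forest", "svm")


# ---------------------------------------------------------------------------
# Splitting

def _blocks(n: int, block_len: int) -> list[np.ndarray]:
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    return [np.arange(lo, min(lo + block_len, n)) for lo in range(0, n, block_len)]


def block_kfold(
    n_windows: int, k: int = 5, block_len: int = 1, seed: int = 0,
    labels: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Grouped k-fold CV over contiguous blocks of windows.

    Blocks of ``block_len`` consecutive windows are the unit of assignment,
    so overlapping windows (which share samples) never straddle a
    train/test split when ``block_len >= ceil(window_len / stride)``.  Every
    window is tested exactly once and fold sizes differ by at most one
    block per stratum.

    When ``labels`` is given, blocks are stratified by their majority label
    before assignment.  Without stratification a no-signal dataset shows the
    classic pessimistic CV bias: the training fold's majority class is
    anti-correlated with the test fold's, dragging chance-level learners
    measurably below 0.5.
    """
    blocks = _blocks(n_windows, block_len)
    if len(blocks) < k:
        raise ValueError(f"need at least k={k} blocks, have {len(blocks)}")
    rng = np.random.default_rng(seed)
    if labels is None:
        order = rng.permutation(len(blocks))
    else:
        labels = np.asarray(labels)
        block_lab = np.array([np.bincount(labels[b]).argmax() for b in blocks])
        order = np.concatenate([
            rng.permutation(np.flatnonzero(block_lab == lab))
            for lab in np.unique(block_lab)
        ])
    folds = []
    for i in range(k):
        test_blocks = order[i::k]
        test_idx = np.sort(np.concatenate([blocks[j] for j in test_blocks]))
        mask = np.ones(n_windows, dtype=bool)
        mask[test_idx] = False
        folds.append((np.flatnonzero(mask), test_idx))
    return folds


def block_split(
    n_windows: int,
    fracs: tuple[float, ...],
    block_len: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, ...]:
    """Shuffled contiguous-block split into len(fracs) parts (e.g. 20/50/30)."""
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fracs must sum to 1")
    blocks = _blocks(n_windows, block_len)
    order = np.random.default_rng(seed).permutation(len(blocks))
    cuts = np.floor(np.cumsum(fracs) * len(blocks)).astype(int)
    parts = []
    lo = 0
    for hi in cuts:
        ids = order[lo:hi]
        parts.append(
            np.sort(np.concatenate([blocks[j] for j in ids]))
            if ids.size else np.array([], dtype=int)
        )
        lo = hi
    return tuple(parts)


def balanced_indices(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded subsample of the majority class down to the minority count.

    Used for chance-level checks: with a 10-h/14-h schedule the raw classes
    are imbalanced, so a majority-class predictor would sit at 0.58 rather
    than 0.5.  Returns sorted indices.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    idx_day = np.flatnonzero(labels == DAY)
    idx_night = np.flatnonzero(labels == NIGHT)
    n = min(idx_day.size, idx_night.size)
    keep = np.concatenate([
        rng.choice(idx_day, n, replace=False),
        rng.choice(idx_night, n, replace=False),
    ])
    return np.sort(keep)


# ---------------------------------------------------------------------------
# Metrics

def confusion_counts(y_true, y_pred) -> np.ndarray:
    """2x2 counts: rows true (day, night), columns predicted (day, night)."""
    y_true = np.asarray(y_true).astype(np.int64).ravel()
    y_pred = np.asarray(y_pred).astype(np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((2, 2), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """Empirical ROC points (FPR, TPR ordered by threshold) and AUC.

    The trapezoidal area equals the rank statistic
    P(score_pos > score_neg) + 0.5 * P(equal) with night as positive.
    """
    y_true = np.asarray(y_true).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes in y_true")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, pos_label=NIGHT)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def sensitivity_specificity(
    confusion: np.ndarray, positive_class: int = NIGHT
) -> tuple[float, float]:
    """(sensitivity, specificity) for the designated positive class.

    A zero denominator yields NaN (undefined is flagged, never silently 0).
    """
    cm = np.asarray(confusion)
    if cm.shape != (2, 2):
        raise ValueError("confusion must be 2x2")
    pos = int(positive_class)
    neg = 1 - pos
    tp = cm[pos, pos]
    fn = cm[pos, neg]
    tn = cm[neg, neg]
    fp = cm[neg, pos]
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sens), float(spec)


# ---------------------------------------------------------------------------
# Behavior summaries (phase-contrast statistics)

@dataclass
class BehaviorSummary:
    """Per-behavior day/night duration contrast over 5-min windows.

    ``table`` columns: behavior, day_mean_s, day_sd_s, night_mean_s,
    night_sd_s, t_stat, p_value (Welch two-sample t-test, uncorrected for
    multiple comparisons — flagged here so readers apply their own
    threshold).  ``bout_counts`` maps phase name to (mean, sd) bouts per
    window when a source stream was supplied.
    """

    table: "object"  # pandas.DataFrame
    bout_counts: dict | None = None
    window_s: float = 300.0
    multiple_testing: str = "uncorrected"


def bout_counts_per_window(
    stream: EthogramStream,
    schedule: PhaseSchedule,
    window_s: float = 300.0,
) -> dict[str, np.ndarray]:
    """Bout-start counts in non-overlapping phase-pure windows, per phase."""
    n_win = int(stream.total_s // window_s)
    edges = np.arange(n_win + 1) * window_s
    counts = np.histogram(stream.start_s, bins=edges)[0]
    p0 = phase_of(edges[:-1], schedule)
    p1 = phase_of(np.nextafter(edges[1:], 0), schedule)
    pure = p0 == p1
    return {
        "day": counts[pure & (p0 == DAY)],
        "night": counts[pure & (p0 == NIGHT)],
    }


def behavior_summary(
    samples: SampleSeries,
    schedule: PhaseSchedule,
    *,
    stream: EthogramStream | None = None,
    window_len: int = 100,
) -> BehaviorSummary:
    """Fig-1-style phase contrast of per-window behavior durations.

    Samples are tiled into non-overlapping windows of ``window_len``
    (phase-pure only); each behavior's within-window duration (seconds) is
    compared between day and night with Welch's unequal-variance t-test.
    """
    import pandas as pd

    n = samples.n_samples
    n_win = n // window_len
    if n_win < 2:
        raise ValueError("need at least 2 windows")
    comp = samples.composition[: n_win * window_len]
    dur = comp.reshape(n_win, window_len, -1).sum(axis=1) * samples.sample_s
    w_start = samples.start_s[np.arange(n_win) * window_len]
    w_end = w_start + window_len * samples.sample_s
    p0 = phase_of(w_start, schedule)
    p1 = phase_of(np.nextafter(w_end, 0), schedule)
    pure = p0 == p1
    day = dur[pure & (p0 == DAY)]
    night = dur[pure & (p0 == NIGHT)]
    if day.shape[0] < 2 or night.shape[0] < 2:
        raise ValueError("each phase needs at least 2 phase-pure windows")
    t, p = stats.ttest_ind(day, night, axis=0, equal_var=False)
    table = pd.DataFrame({
        "behavior": samples.catalog.names,
        "day_mean_s": day.mean(axis=0),
        "day_sd_s": day.std(axis=0, ddof=1),
        "night_mean_s": night.mean(axis=0),
        "night_sd_s": night.std(axis=0, ddof=1),
        "t_stat": t,
        "p_value": p,
    })
    bout_counts = None
    if stream is not None:
        window_s = window_len * samples.sample_s
        bc = bout_counts_per_window(stream, schedule, window_s)
        bout_counts = {
            ph: (float(v.mean()), float(v.std(ddof=1))) for ph, v in bc.items() if v.size > 1
        }
    return BehaviorSummary(table=table, bout_counts=bout_counts,
                           window_s=window_len * samples.sample_s)


# ---------------------------------------------------------------------------
# Pipeline evaluation

@dataclass(frozen=True)
class Protocol:
    """Cross-validation protocol shared across models.

    ``block_len`` (windows per contiguous block) defaults to
    ceil(window_len / stride), which guarantees that no test window shares a
    sample with a train window.  ``balance`` subsamples the majority class
    (seeded) before splitting — used for chance-level control experiments.
    ``seq_val_frac`` of each training fold (by block) is held out for the
    sequence model's early stopping.
    """

    k: int = 5
    block_len: int | None = None
    seed: int = 0
    balance: bool = False
    seq_val_frac: float = 0.15


@dataclass
class EvalReport:
    """Metric surface for one model on one window set."""

    model: str
    fold_accuracy: list
    accuracy_mean: float
    accuracy_sd: float
    roc_points: np.ndarray
    auc: float
    train_auc: float
    confusion: np.ndarray
    sensitivity: dict
    specificity: dict
    n_windows: int
    provenance: str = ""
    sd_basis: str = "across CV folds"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roc_points"] = np.asarray(self.roc_points).tolist()
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def write_tables(self, outdir) -> None:
        """Write ROC points and confusion counts as CSV tables."""
        import pandas as pd
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_{self.model}.csv", index=False
        )
        pd.DataFrame(
            self.confusion,
            index=["true_day", "true_night"],
            columns=["pred_day", "pred_night"],
        ).to_csv(outdir / f"confusion_{self.model}.csv")

    def plot_roc(self, path) -> None:
        """Optional ROC figure (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1],
                label=f"{self.model} (AUC {self.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _default_seq_spec(seed: int) -> SequenceArchSpec:
    return SequenceArchSpec(seed=seed)


def evaluate_pipeline(
    ws: WindowSet,
    models: dict,
    protocol: Protocol | None = None,
    *,
    return_predictions: bool = False,
):
    """k-fold evaluation of the selected models on shared folds.

    ``models`` maps names from {logistic, forest, svm, ensemble, sequence}
    to a spec (:class:`ModelSpec` / :class:`SequenceArchSpec`) or ``None``
    for defaults.  The ensemble needs all three tabular models and uses
    majority-vote labels with the mean of member scores as its ROC score.
    With ``return_predictions`` the per-window out-of-fold predictions and
    scores are returned as a DataFrame alongside the reports.
    """
    protocol = protocol or Protocol()
    if not models:
        raise ValueError("no models selected")
    unknown = set(models) - set(TABULAR_KINDS) - {"ensemble", "sequence"}
    if unknown:
        raise ValueError(f"unknown model selection: {sorted(unknown)}")
    if "ensemble" in models and not all(k in models for k in TABULAR_KINDS):
        raise ValueError("ensemble requires logistic, forest and svm")

    y_all = ws.labels.astype(np.int8)
    idx_all = np.arange(ws.n_windows)
    if protocol.balance:
        idx_all = balanced_indices(y_all, seed=protocol.seed)
    y = y_all[idx_all]
    if np.unique(y).size < 2:
        raise ValueError("window set does not contain both classes")
    X = flatten_windows(ws)[idx_all]
    seq = ws.sequential[idx_all]
    block_len = protocol.block_len or -(-ws.window_len // ws.stride)
    folds = block_kfold(len(y), k=protocol.k, block_len=block_len,
                        seed=protocol.seed, labels=y)

    names = [m for m in models if m != "ensemble"]
    preds = {m: np.empty(len(y), dtype=np.int8) for m in names}
    scores = {m: np.empty(len(y), dtype=np.float64) for m in names}
    fold_acc: dict[str, list] = {m: [] for m in models}
    train_aucs: dict[str, list] = {m: [] for m in models}

    for train_idx, test_idx in folds:
        fold_train_scores = {}
        for m in names:
            if m == "sequence":
                spec = models[m] or _default_seq_spec(protocol.seed)
                # hold out every m-th training block for early stopping, so
                # the validation split spans the recording (both classes)
                every = max(2, int(round(1.0 / protocol.seq_val_frac)))
                tr_blocks = train_idx // block_len
                val_mask = np.isin(tr_blocks, np.unique(tr_blocks)[::every])
                tr, val = train_idx[~val_mask], train_idx[val_mask]
                sm = build_sequence_model(spec, ws.window_len, ws.catalog.size)
                sm, _ = train_sequence_model(sm, seq[tr], y[tr], seq[val], y[val], spec)
                s_test = predict_night_prob(sm, seq[test_idx])
                s_train = predict_night_prob(sm, seq[train_idx])
                preds[m][test_idx] = (s_test >= 0.5).astype(np.int8)
                scores[m][test_idx] = s_test
            else:
                spec = models[m] or ModelSpec(kind=m, seed=protocol.seed)
                if spec.kind != m:
                    spec = dataclasses.replace(spec, kind=m)
                tm = fit_classifier(spec, X[train_idx], y[train_idx])
                preds[m][test_idx] = tm.predict(X[test_idx])
                scores[m][test_idx] = tm.score_night(X[test_idx])
                s_train = tm.score_night(X[train_idx])
            fold_train_scores[m] = s_train
            fold_acc[m].append(float(np.mean(preds[m][test_idx] == y[test_idx])))
            train_aucs[m].append(roc_auc(y[train_idx], s_train)[1])
        if "ensemble" in models:
            vote = majority_vote(*(preds[m][test_idx] for m in TABULAR_KINDS))
            fold_acc["ensemble"].append(float(np.mean(vote == y[test_idx])))
            ens_train = np.mean(
                [fold_train_scores[m] for m in TABULAR_KINDS], axis=0
            )
            train_aucs["ensemble"].append(roc_auc(y[train_idx], ens_train)[1])

    if "ensemble" in models:
        preds["ensemble"] = majority_vote(*(preds[m] for m in TABULAR_KINDS))
        scores["ensemble"] = np.mean([scores[m] for m in TABULAR_KINDS], axis=0)

    reports = {}
    prov = ws.content_hash()
    for m in models:
        cm = confusion_counts(y, preds[m])
        points, auc_val = roc_auc(y, scores[m])
        sens_n, spec_n = sensitivity_specificity(cm, NIGHT)
        sens_d, spec_d = sensitivity_specificity(cm, DAY)
        accs = fold_acc[m]
        reports[m] = EvalReport(
            model=m,
            fold_accuracy=accs,
            accuracy_mean=float(np.mean(accs)),
            accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            roc_points=points,
            auc=auc_val,
            train_auc=float(np.mean(train_aucs[m])),
            confusion=cm,
            sensitivity={"night": sens_n, "day": sens_d},
            specificity={"night": spec_n, "day": spec_d},
            n_windows=len(y),
            provenance=prov,
        )
    if return_predictions:
        import pandas as pd

        table = {"start_s": ws.start_s[idx_all], "truth": y}
        for m in preds:
            table[f"pred_{m}"] = preds[m]
            table[f"score_{m}"] = scores[m]
        return reports, pd.DataFrame(table)
    return reports
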