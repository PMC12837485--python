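"""TAPVC screening from per-video index values.

Takes a table of per-video PLD/PLA values (one row per case × model ×
index) and produces the screening analysis: group summaries (mean ± SD),
mean absolute error of each model's indices against the ground-truth
indices, and ROC/AUC discrimination of normal vs TAPVC videos.

The decision direction is fixed, not estimated from the data: TAPVC is the
positive class and a **higher** index value is more positive, for both
indices — a connected PV-LA junction pins PLD at its 1.00 floor and tends
to align the PV axis with the centroid line, while divergence raises both.
Fixing the direction means a model whose indices invert the clinical trend
correctly shows AUC < 0.5 instead of being silently flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import SchemaError, ValidationError
from .mask_io import GROUPS

POSITIVE_CLASS = "TAPVC"
INDEX_NAMES = ("PLD", "PLA")
GROUND_TRUTH = "ground_truth"

_REQUIRED_COLUMNS = ["case_id", "model_name", "index_name", "value", "group"]


@dataclass
class ROCResult:
    index_name: str
    model_name: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: str = POSITIVE_CLASS
    direction: str = "higher-value-is-positive"


def validate_screening_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"screening table missing columns {missing}")
    bad_group = set(table.group.unique()) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group value(s) {sorted(bad_group)}; expected {GROUPS}")
    bad_index = set(table.index_name.unique()) - set(INDEX_NAMES)
    if bad_index:
        raise ValidationError(f"unknown index name(s) {sorted(bad_index)}; expected {INDEX_NAMES}")
    dup = table.duplicated(subset=["case_id", "model_name", "index_name"])
    if dup.any():
        rows = table.loc[dup, ["case_id", "model_name", "index_name"]].values.tolist()
        raise ValidationError(f"duplicate (case_id, model_name, index_name) rows: {rows}")
    table = table.copy()
    table["value"] = table["value"].astype(float)
    return table


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD (n−1) per (model, index, group); SD is NaN at n = 1."""
    table = validate_screening_table(table)
    rows = []
    for (model, index, group), sub in table.groupby(["model_name", "index_name", "group"]):
        v = sub.value.to_numpy()
        rows.append(
            {
                "model_name": model,
                "index_name": index,
                "group": group,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mae_vs_ground_truth(table: pd.DataFrame) -> pd.DataFrame:
    """Mean |model − ground truth| per (model, index, group), matched on case."""
    table = validate_screening_table(table)
    gt = table[table.model_name == GROUND_TRUTH]
    models = table[table.model_name != GROUND_TRUTH]
    if models.empty:
        raise ValidationError("no model rows to compare against ground truth")
    merged = models.merge(
        gt[["case_id", "index_name", "value"]],
        on=["case_id", "index_name"],
        how="left",
        suffixes=("", "_gt"),
    )
    orphans = merged[merged.value_gt.isna()]
    if not orphans.empty:
        ids = sorted(set(orphans.case_id))
        raise ValidationError(f"cases without a ground-truth partner: {ids}")
    merged["abs_err"] = (merged.value - merged.value_gt).abs()
    out = (
        merged.groupby(["model_name", "index_name", "group"])
        .abs_err.agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mae", "count": "n"})
    )
    return out


def _mann_whitney_auc(values: np.ndarray, positive: np.ndarray) -> float:
    """Tie-corrected U/(n1·n0): the probability interpretation of AUC."""
    ranks = rankdata(values)  # average ranks: ties count 1/2
    n1 = int(positive.sum())
    n0 = len(values) - n1
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_curve(table: pd.DataFrame, model: str, index: str) -> ROCResult:
    """ROC of normal vs TAPVC for one (model, index); AUC by trapezoid.

    The trapezoidal AUC is cross-checked against the tie-corrected
    Mann-Whitney statistic U/(n1·n0); the two are the same quantity and
    must agree to 1e-12, which guards the threshold sweep against
    tie-handling mistakes.
    """
    table = validate_screening_table(table)
    sub = table[(table.model_name == model) & (table.index_name == index)]
    if sub.empty:
        raise ValidationError(f"no rows for model {model!r}, index {index!r}")
    y = (sub.group == POSITIVE_CLASS).to_numpy()
    if y.all() or not y.any():
        raise ValidationError(
            f"ROC needs both groups; model {model!r}/{index} has only "
            f"{'TAPVC' if y.all() else 'normal'} rows"
        )
    scores = sub.value.to_numpy()
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    auc_mw = _mann_whitney_auc(scores, y)
    if abs(auc - auc_mw) > 1e-12:
        raise RuntimeError(
            f"trapezoidal AUC {auc!r} disagrees with Mann-Whitney AUC {auc_mw!r}"
        )
    return ROCResult(
        index_name=index, model_name=model, thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc
    )


def aggregate_per_case(table: pd.DataFrame, case_map: dict | None = None) -> pd.DataFrame:
    """Mean value per (case, model, index) when several videos share a case.

    ``case_map`` maps a video-level case_id to the underlying case;
    unmapped ids pass through unchanged, so with no map this is a no-op.
    """
    table = validate_screening_table(table)
    if case_map:
        table = table.assign(case_id=table.case_id.map(lambda c: case_map.get(c, c)))
    return (
        table.groupby(["case_id", "model_name", "index_name", "group"], as_index=False)
        .value.mean()
    )


def compare_models(table: pd.DataFrame, models: list[str] | None = None) -> pd.DataFrame:
    """Per-model AUC for each index, ranked (AUC desc, name asc for ties)."""
    table = validate_screening_table(table)
    if models is None:
        models = sorted(table.model_name.unique())
    rows = []
    for index in sorted(table.index_name.unique()):
        for model in models:
            r = roc_curve(table, model, index)
            rows.append({"index_name": index, "model_name": model, "auc": r.auc})
    out = pd.DataFrame(rows).sort_values(
        ["index_name", "auc", "model_name"], ascending=[True, False, True]
    )
    out["rank"] = out.groupby("index_name").cumcount() + 1
    return out.reset_index(drop=True)


def bootstrap_auc_ci(
    table: pd.DataFrame,
    model: str,
    index: str,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap CI for one (model, index) AUC."""
    table = validate_screening_table(table)
    sub = table[(table.model_name == model) & (table.index_name == index)]
    y = (sub.group == POSITIVE_CLASS).to_numpy()
    scores = sub.value.to_numpy()
    rng = np.random.default_rng(seed)
    pos, neg = scores[y], scores[~y]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        v = np.concatenate([ps, ns])
        lab = np.zeros(len(v), dtype=bool)
        lab[: len(ps)] = True
        aucs[b] = _mann_whitney_auc(v, lab)
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def roc_points_table(results: list[ROCResult]) -> pd.DataFrame:
    frames = []
    for r in results:
        frames.append(
            pd.DataFrame(
                {
                    "model_name": r.model_name,
                    "index_name": r.index_name,
                    "threshold": r.thresholds,
                    "fpr": r.fpr,
                    "tpr": r.tpr,
                    "auc": r.auc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_roc(results: list[ROCResult], path) -> None:
    """One ROC panel per index, models overlaid, AUC in the legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indices = sorted({r.index_name for r in results})
    fig, axes = plt.subplots(1, len(indices), figsize=(5 * len(indices), 4.5), squeeze=False)
    for ax, index in zip(axes[0], indices):
        for r in sorted((r for r in results if r.index_name == index), key=lambda r: r.model_name):
            ax.plot(r.fpr, r.tpr, label=f"{r.model_name} (AUC = {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.set_title(f"TAPVC screening by {index}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
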