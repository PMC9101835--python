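"""Evaluation statistics: overlap metrics, lesion-level detection, bootstrap
confidence intervals, ROC analysis with the DeLong test, and survival
comparison.

Conventions (configurable where noted):

* lesion matching uses 8-connected components; a ground-truth lesion counts
  as detected when predicted foreground covers at least ``match_frac`` of
  its area, and a predicted component is a false positive when less than
  ``match_frac`` of its own area touches ground-truth foreground;
* the false-positive ratio is false-positive components over all predicted
  components (a per-prediction false-discovery fraction);
* two empty masks have Dice 1.0 (perfect-agreement convention);
* patient-level metrics are unweighted means over patients, with
  zero-denominator patients excluded from that metric's mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "SurvivalRecord", "MetricsReport", "dice_coefficient", "pixel_metrics",
    "lesion_level_metrics", "bootstrap_ci", "roc_auc", "delong_test",
    "km_logrank", "subgroup_report",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class SurvivalRecord:
    pfs_months: float
    event: bool  # True = progressed or died, False = censored
    group: str   # "responder" | "non_responder"

    def __post_init__(self):
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be nonnegative")


@dataclass
class MetricsReport:
    """Point estimates (percent where applicable) with bootstrap 95% CIs."""

    dice: float
    n_patients: int
    n_lesions: int
    metrics: dict = field(default_factory=dict)   # name -> (point, lo, hi)


def _check_binary_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    return pred.astype(bool), gt.astype(bool)


def dice_coefficient(pred, gt) -> float:
    """2|P∩G| / (|P|+|G|); both-empty pairs score 1.0."""
    pred, gt = _check_binary_pair(pred, gt)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / denom)


def pixel_metrics(pred, gt) -> dict[str, float | None]:
    """Per-patient confusion-matrix metrics, in percent.

    Zero-denominator ratios return None so callers can exclude them from
    cohort averages.
    """
    pred, gt = _check_binary_pair(pred, gt)
    tp = int(np.logical_and(pred, gt).sum())
    fp = int(np.logical_and(pred, ~gt).sum())
    fn = int(np.logical_and(~pred, gt).sum())
    tn = int(np.logical_and(~pred, ~gt).sum())

    def ratio(num, den):
        return 100.0 * num / den if den else None

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def lesion_level_metrics(pred, gt, match_frac: float = 0.10
                         ) -> dict[str, float | int]:
    """Connected-component detection metrics, in percent."""
    pred, gt = _check_binary_pair(pred, gt)
    gt_lab, n_gt = ndimage.label(gt, structure=EIGHT_CONN)
    pr_lab, n_pr = ndimage.label(pred, structure=EIGHT_CONN)

    detected = 0
    for i in range(1, n_gt + 1):
        comp = gt_lab == i
        if np.logical_and(comp, pred).sum() >= match_frac * comp.sum():
            detected += 1
    false_pos = 0
    for j in range(1, n_pr + 1):
        comp = pr_lab == j
        if np.logical_and(comp, gt).sum() < match_frac * comp.sum():
            false_pos += 1

    return {
        "lesion_sensitivity": 100.0 * detected / n_gt if n_gt else None,
        "fpr": 100.0 * false_pos / n_pr if n_pr else 0.0,
        "n_gt_lesions": n_gt,
        "n_pred_components": n_pr,
    }


def bootstrap_ci(stat_fn, per_patient_data, reps: int = 1000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval resampling patients with replacement."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    data = list(per_patient_data)
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 patients to bootstrap")
    rng = np.random.default_rng(seed)
    samples = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        samples[r] = stat_fn([data[i] for i in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann–Whitney U statistic (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the per-case structural components V10 (positives) and V01
    (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    greater = (pos[:, None] > neg[None, :]).astype(float)
    equal = (pos[:, None] == neg[None, :]).astype(float)
    psi = greater + 0.5 * equal
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(auc), v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired comparison of two correlated AUCs; returns (auc_a, auc_b, p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("scores and labels must be paired")
    if labels.min() == labels.max():
        raise ValueError("delong_test requires both classes present")

    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(p)


def km_logrank(records: list[SurvivalRecord]) -> dict:
    """Kaplan–Meier curves per group plus the two-group log-rank test.

    Returns a dict with per-group step functions (``times``, ``survival``)
    and ``chi2``/``p`` for the 1-df log-rank statistic.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    by_group = {g: [r for r in records if r.group == g] for g in groups}
    for g, rs in by_group.items():
        if not rs:
            raise ValueError(f"empty group {g}")
    if not any(r.event for r in records):
        raise ValueError("log-rank test undefined without any event")

    curves = {}
    for g, rs in by_group.items():
        kmf = KaplanMeierFitter()
        kmf.fit([r.pfs_months for r in rs], [r.event for r in rs], label=g)
        sf = kmf.survival_function_
        curves[g] = {
            "times": sf.index.to_numpy(dtype=float),
            "survival": sf[g].to_numpy(dtype=float),
        }
    ga, gb = groups
    res = logrank_test(
        [r.pfs_months for r in by_group[ga]],
        [r.pfs_months for r in by_group[gb]],
        event_observed_A=[r.event for r in by_group[ga]],
        event_observed_B=[r.event for r in by_group[gb]],
    )
    return {
        "curves": curves,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
    }


def subgroup_report(truths: list[dict], dices: list[float],
                    size_bins: tuple[float, float] = (3.0, 5.0)) -> dict:
    """Dice stratified by lesion size, multiplicity, and field of view.

    ``truths`` carry per-patient generator truth: ``diameters_cm`` (list),
    ``lesion_count`` and ``fov_scale``.  Empty strata are reported absent.
    """
    lo, hi = size_bins
    strata: dict[str, list[float]] = {}

    def add(key, d):
        strata.setdefault(key, []).append(d)

    for t, d in zip(truths, dices):
        dmax = max(t["diameters_cm"]) if t["diameters_cm"] else 0.0
        if dmax < lo:
            add(f"size<{lo:g}", d)
        elif dmax < hi:
            add(f"size{lo:g}-{hi:g}", d)
        else:
            add(f"size>={hi:g}", d)
        add("multiplicity1" if t["lesion_count"] <= 1 else "multiplicity>=2", d)
        add("fov_native" if t.get("fov_scale", 1.0) <= 1.0 else "fov_amplified", d)

    return {
        k: {"n": len(v), "dice": float(np.mean(v))}
        for k, v in sorted(strata.items())
    }


def summarize_segmentation(per_patient: list[dict], reps: int = 1000,
                           seed: int = 0) -> MetricsReport:
    """Aggregate per-patient segmentation metrics with bootstrap 95% CIs.

    Each entry must carry ``dice`` plus the outputs of
    :func:`pixel_metrics` and :func:`lesion_level_metrics`.
    """
    def mean_of(key):
        def f(rows):
            vals = [r[key] for r in rows if r.get(key) is not None]
            return float(np.mean(vals)) if vals else float("nan")
        return f

    metrics = {}
    names = ["dice", "accuracy", "sensitivity", "specificity", "ppv", "npv",
             "lesion_sensitivity", "fpr"]
    for i, name in enumerate(names):
        fn = mean_of(name)
        point = fn(per_patient)
        lo, hi = bootstrap_ci(fn, per_patient, reps=reps, seed=seed + i)
        metrics[name] = (point, lo, hi)
    return MetricsReport(
        dice=metrics["dice"][0],
        n_patients=len(per_patient),
        n_lesions=int(sum(r.get("n_gt_lesions", 0) for r in per_patient)),
        metrics=metrics,
    )
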