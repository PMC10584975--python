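"""Sensitivity and robustness scoring of attribution maps.

Sensitivity compares a method's relevance map with the simulation ground
truth: relevance mass accuracy (RMA — the fraction of total absolute
relevance inside the ground-truth support mask) for the temporal and
spectral conditions, and cosine similarity between channel topographies
for the spatial condition (volume conduction makes every channel's ground
truth non-zero, so a support mask is uninformative there).

Robustness compares the original explanation with the explanation from a
label-randomized (retrained on permuted labels) or weight-randomized
(re-initialized, untrained) model, via absolute Pearson correlation and
SSIM.  High similarity after randomization means the explanation is not
class- or model-specific.

Results are tidy records (method, condition, snr_db, fold, metric, value)
and a summary table with the traffic-light flags: a method is "sensitive"
if its mean sensitivity exceeds 0.55; label-robustness above 0.5 flags it
"not class-specific" (red; 0.3-0.5 orange), and weight-robustness above
0.5 / 0.3 earns "**" / "*" ("not model-specific").
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "SENSITIVE_THRESHOLD",
    "ROBUSTNESS_RED",
    "ROBUSTNESS_ORANGE",
    "relevance_mass_accuracy",
    "cosine_similarity",
    "abs_pearson",
    "ssim",
    "sensitivity_suite",
    "robustness_suite",
    "summarize",
]

SENSITIVE_THRESHOLD = 0.55
ROBUSTNESS_RED = 0.5
ROBUSTNESS_ORANGE = 0.3


def relevance_mass_accuracy(attribution: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of total |relevance| inside the binary ground-truth mask."""
    attribution = np.abs(np.asarray(attribution, dtype=float))
    mask = np.asarray(mask)
    if attribution.shape != mask.shape:
        raise ValueError("attribution and mask shapes differ")
    total = attribution.sum()
    if total == 0:
        return 0.0
    return float(attribution[mask.astype(bool)].sum() / total)


def cosine_similarity(v: np.ndarray, gt_topo: np.ndarray) -> float:
    v = np.asarray(v, dtype=float).ravel()
    gt_topo = np.asarray(gt_topo, dtype=float).ravel()
    nv = np.linalg.norm(v)
    ng = np.linalg.norm(gt_topo)
    if nv == 0 or ng == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(v @ gt_topo / (nv * ng))


def abs_pearson(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """|Pearson r| between flattened maps; NaN if either is constant."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def ssim(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Mean structural similarity after joint min-max scaling to [0, 1].

    Gaussian weighting (sigma = 1.5) with the standard stability constants,
    as in the reference SSIM formulation.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = hi - lo
    if span == 0:
        return 1.0  # two identical constant images
    a = (a - lo) / span
    b = (b - lo) / span
    return float(
        structural_similarity(
            a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
    )


def _records(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["method", "condition", "snr_db", "fold", "metric", "value"])


def sensitivity_suite(
    attributions: np.ndarray,
    gt_mask: np.ndarray,
    gt_topo: np.ndarray,
    condition: str,
    method: str,
    snr_db: float,
    fold: int,
    correct: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-fold sensitivity records for one method.

    Temporal/spectral: mean per-trial RMA against the ground-truth mask.
    Spatial: mean cosine similarity between the time-collapsed channel
    vector of each map and the ground-truth topography.  Trials flagged
    incorrect (misclassified) are excluded — an explanation of a wrong
    prediction has no ground-truth class.
    """
    from .attribution import reduce_to_channels

    attributions = np.asarray(attributions)
    n = attributions.shape[0]
    keep = np.ones(n, dtype=bool) if correct is None else np.asarray(correct, dtype=bool)
    vals = []
    for i in range(n):
        if not keep[i]:
            continue
        if condition == "spatial":
            v = reduce_to_channels(attributions[i])
            if v.max() == 0:
                continue
            vals.append(cosine_similarity(v, gt_topo[i]))
        else:
            vals.append(relevance_mass_accuracy(attributions[i], gt_mask[i]))
    metric = "cosine" if condition == "spatial" else "RMA"
    value = float(np.mean(vals)) if vals else float("nan")
    return _records([{
        "method": method, "condition": condition, "snr_db": snr_db,
        "fold": fold, "metric": metric, "value": value,
    }])


def robustness_suite(
    original_maps: np.ndarray,
    label_rand_maps: np.ndarray | None,
    weight_rand_maps: np.ndarray | None,
    condition: str,
    method: str,
    snr_db: float,
    fold: int,
) -> pd.DataFrame:
    """Per-fold similarity of original vs randomized-control explanations."""
    original_maps = np.asarray(original_maps)
    rows = []
    for tag, ctrl in (("label", label_rand_maps), ("weight", weight_rand_maps)):
        if ctrl is None:
            continue
        ctrl = np.asarray(ctrl)
        if ctrl.shape != original_maps.shape:
            raise ValueError(f"{tag}-randomized maps misaligned with originals")
        rs, ss = [], []
        for a, b in zip(original_maps, ctrl):
            r = abs_pearson(a, b)
            if np.isfinite(r):
                rs.append(r)
            ss.append(ssim(a, b))
        rows.append({"method": method, "condition": condition, "snr_db": snr_db,
                     "fold": fold, "metric": f"r_{tag}", "value": float(np.mean(rs)) if rs else float("nan")})
        rows.append({"method": method, "condition": condition, "snr_db": snr_db,
                     "fold": fold, "metric": f"ssim_{tag}", "value": float(np.mean(ss)) if ss else float("nan")})
    return _records(rows)


def summarize(records: pd.DataFrame) -> dict:
    """Aggregate tidy records into per-(method, condition) flags.

    Sensitivity is the mean of the condition's sensitivity metric over
    folds and SNR levels; each robustness score is the mean of the |r| and
    SSIM similarities for that control.  Flags follow the 0.55 / 0.5 / 0.3
    thresholds.
    """
    out: dict = {}
    for (method, condition), grp in records.groupby(["method", "condition"], sort=True):
        sens = grp[grp.metric.isin(["RMA", "cosine"])].value.mean()
        rob_label = grp[grp.metric.isin(["r_label", "ssim_label"])].value.mean()
        rob_weight = grp[grp.metric.isin(["r_weight", "ssim_weight"])].value.mean()
        entry = {
            "sensitivity": None if pd.isna(sens) else float(sens),
            "robustness_label": None if pd.isna(rob_label) else float(rob_label),
            "robustness_weight": None if pd.isna(rob_weight) else float(rob_weight),
            "incomplete": bool(pd.isna(sens) or pd.isna(rob_label) or pd.isna(rob_weight)),
        }
        entry["sensitive"] = bool(sens > SENSITIVE_THRESHOLD) if not pd.isna(sens) else None
        if pd.isna(rob_label):
            entry["not_class_specific"] = None
        elif rob_label > ROBUSTNESS_RED:
            entry["not_class_specific"] = "red"
        elif rob_label > ROBUSTNESS_ORANGE:
            entry["not_class_specific"] = "orange"
        else:
            entry["not_class_specific"] = "none"
        if pd.isna(rob_weight):
            entry["not_model_specific"] = None
        elif rob_weight > ROBUSTNESS_RED:
            entry["not_model_specific"] = "**"
        elif rob_weight > ROBUSTNESS_ORANGE:
            entry["not_model_specific"] = "*"
        else:
            entry["not_model_specific"] = ""
        out.setdefault(method, {})[condition] = entry
    return out
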