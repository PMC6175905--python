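"""Per-residue classification metrics, ROC analysis and cutoff policies.

The evaluation unit is the residue: a predicted score track is compared
against the per-residue truth mask built from experimentally (or
synthetically) annotated epitope regions, over the whole protein.  Residues
outside any annotated region count as negatives.

Three cutoff policies are supported for the metric table:

* ``default``       — the method's configured operating cutoff;
* ``max_precision`` — the swept cutoff maximizing precision (ties broken by
  higher specificity, then lower cutoff);
* ``max_auc_point`` — the Youden-optimal point, maximizing J = TPR - FPR
  (the natural operating point of the ROC curve; AUC itself is cutoff-free).

AUC is computed by trapezoidal integration of the swept ROC curve and is
identical to the pairwise-ranking probability with ties counted 1/2.
Multi-antigen results are averaged per antigen by default (``pool=True``
concatenates residues instead).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ScoreTrack

POLICIES = ("default", "max_precision", "max_auc_point")


@dataclasses.dataclass(frozen=True)
class MetricsRow:
    method: str
    policy: str
    cutoff: float
    auc: float
    accuracy: float
    tpr: float
    fpr: float
    precision: float
    specificity: float
    kappa: float

    def as_dict(self) -> dict[str, float | str]:
        return dataclasses.asdict(self)


def confusion(
    track: ScoreTrack | Sequence[float],
    truth: Sequence[bool],
    cutoff: float,
) -> tuple[int, int, int, int]:
    """Residue-level (TP, FP, TN, FN) at a cutoff; predicted = score >= cutoff."""
    scores = np.asarray(track.scores if isinstance(track, ScoreTrack) else track, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if len(scores) != len(truth):
        raise ValueError(f"track length {len(scores)} != truth length {len(truth)}")
    pred = scores >= cutoff
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return tp, fp, tn, fn


def rates(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    total = tp + fp + tn + fn
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return {
        "accuracy": (tp + tn) / total if total else 0.0,
        "tpr": tpr,
        "fpr": fpr,
        "precision": precision,
        "specificity": 1.0 - fpr,
        "kappa": kappa(tp, fp, tn, fn),
    }


def kappa(tp: int, fp: int, tn: int, fn: int) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e), with marginal expectation."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def roc_curve(
    track: ScoreTrack | Sequence[float], truth: Sequence[bool]
) -> list[tuple[float, float, float]]:
    """(fpr, tpr, cutoff) points swept over all distinct scores, (0,0)->(1,1)."""
    scores = np.asarray(track.scores if isinstance(track, ScoreTrack) else track, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative residue")
    points: list[tuple[float, float, float]] = [(0.0, 0.0, np.inf)]
    for cut in np.unique(scores)[::-1]:
        tp, fp, tn, fn = confusion(scores, truth, cut)
        points.append((fp / n_neg, tp / n_pos, float(cut)))
    if points[-1][:2] != (1.0, 1.0):
        points.append((1.0, 1.0, -np.inf))
    return points


def roc_auc(track: ScoreTrack | Sequence[float], truth: Sequence[bool]) -> float:
    """Trapezoidal AUC of the swept ROC curve."""
    pts = roc_curve(track, truth)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def select_cutoff(
    track: ScoreTrack | Sequence[float],
    truth: Sequence[bool],
    policy: str,
    default_cutoff: float = 0.2,
) -> float:
    """Operating cutoff under one of the three policies."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "default":
        return default_cutoff
    scores = np.asarray(track.scores if isinstance(track, ScoreTrack) else track, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    candidates = np.unique(scores)
    best_cut, best_key = None, None
    for cut in candidates:
        tp, fp, tn, fn = confusion(scores, truth, float(cut))
        r = rates(tp, fp, tn, fn)
        if policy == "max_precision":
            key = (r["precision"], r["specificity"], -cut)
        else:  # max_auc_point: Youden's J
            key = (r["tpr"] - r["fpr"], -cut)
        if best_key is None or key > best_key:
            best_key, best_cut = key, float(cut)
    return best_cut


def evaluate_track(
    track: ScoreTrack | Sequence[float],
    truth: Sequence[bool],
    method: str = "epiclass",
    policy: str = "default",
    default_cutoff: float = 0.2,
) -> MetricsRow:
    cut = select_cutoff(track, truth, policy, default_cutoff)
    tp, fp, tn, fn = confusion(track, truth, cut)
    r = rates(tp, fp, tn, fn)
    return MetricsRow(
        method=method,
        policy=policy,
        cutoff=cut,
        auc=roc_auc(track, truth),
        **r,
    )


def compare_methods(
    tracks: Mapping[str, Sequence[ScoreTrack | Sequence[float]]],
    truths: Sequence[Sequence[bool]],
    policies: Sequence[str] = POLICIES,
    default_cutoffs: Mapping[str, float] | None = None,
    pool: bool = False,
) -> pd.DataFrame:
    """One metric row per method x policy, averaged across antigens.

    ``tracks`` maps a method name to its per-antigen score tracks, aligned
    with ``truths``.  With ``pool=True`` residues are concatenated into one
    long track per method instead of averaging per-antigen metrics.
    """
    rows: list[dict] = []
    for method, method_tracks in tracks.items():
        if len(method_tracks) != len(truths):
            raise ValueError(f"method {method!r}: {len(method_tracks)} tracks for {len(truths)} truths")
        cutoff = (default_cutoffs or {}).get(method, 0.2)
        for policy in policies:
            if pool:
                scores = np.concatenate(
                    [np.asarray(t.scores if isinstance(t, ScoreTrack) else t) for t in method_tracks]
                )
                truth = np.concatenate([np.asarray(t, dtype=bool) for t in truths])
                rows.append(
                    evaluate_track(scores, truth, method, policy, cutoff).as_dict()
                )
            else:
                per_antigen = [
                    evaluate_track(t, truth, method, policy, cutoff).as_dict()
                    for t, truth in zip(method_tracks, truths)
                ]
                df = pd.DataFrame(per_antigen)
                mean = df.drop(columns=["method", "policy"]).mean()
                rows.append({"method": method, "policy": policy, **mean.to_dict()})
    cols = ["method", "policy", "cutoff", "auc", "accuracy", "tpr", "fpr", "precision", "specificity", "kappa"]
    return pd.DataFrame(rows)[cols]
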