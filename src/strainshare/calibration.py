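"""Species-specific strain-identity thresholds on nGD.

For species with enough longitudinal data (>= 50 same-individual sample
pairs), the threshold maximizes Youden's index J = sensitivity + specificity
- 1 for separating same-individual (same strain) from unrelated-individual
(different strain) nGD values, under the constraint that at most 5% of
unrelated pairs fall at/below the threshold (a bound on the false-discovery
rate). Species without enough longitudinal pairs, and all oral species, use
the 3rd percentile of the unrelated nGD distribution instead — the 3rd
percentile being the median unrelated-percentile achieved by the
Youden-calibrated species.

The strain-identity comparison is inclusive throughout: nGD <= threshold
means same strain, so a threshold equal to an observed value captures it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FP_BOUND = 0.05
DEFAULT_MIN_SAME_PAIRS = 50
DEFAULT_FALLBACK_PERCENTILE = 3.0
# 3rd percentile needs at least one order statistic below it: ceil(100/3) = 34
DEFAULT_FALLBACK_MIN_N = 34


@dataclass
class StrainThreshold:
    """A calibrated per-SGB strain-identity cutoff on nGD."""

    sgb_id: str
    threshold_ngd: float
    method: str  # "youden" | "fallback"
    n_same_pairs: int
    n_unrelated_pairs: int
    fp_fraction: float
    youden_j: float | None
    unrelated_percentile: float


@dataclass
class FMTValidation:
    """Precision/recall of a threshold on FMT donor-recipient positives."""

    sgb_id: str
    tp: int
    fp: int
    tn: int
    fn: int
    recall: float | None
    precision: float | None
    f_score: float | None


def _candidate_grid(pooled: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique pooled values, plus one
    candidate strictly below the minimum.

    Thresholds between observed values form equivalence classes; midpoints
    make the choice insensitive to float noise. The below-minimum candidate
    (half the minimum when positive, else a tiny negative value) classifies
    nothing as shared and guarantees a feasible candidate under any FP bound.
    """
    uniq = np.unique(pooled)
    below = uniq[0] / 2.0 if uniq[0] > 0 else -1e-12
    if len(uniq) == 1:
        return np.array([below])
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[below], mids])


def youden_threshold(
    same_dists,
    unrelated_dists,
    fp_bound: float = DEFAULT_FP_BOUND,
    sgb_id: str = "",
) -> StrainThreshold:
    """Constrained Youden's-index threshold.

    Among candidate thresholds with fraction(unrelated <= t) <= ``fp_bound``,
    returns the one maximizing J = TPR + TNR - 1, where TPR is the fraction
    of same-individual distances at/below t and TNR the fraction of unrelated
    distances above t. Ties are broken toward the smallest threshold
    (conservative against false positives).
    """
    same = np.asarray(same_dists, dtype=float)
    unrel = np.asarray(unrelated_dists, dtype=float)
    if same.size == 0 or unrel.size == 0:
        raise ValueError("youden_threshold requires non-empty distributions")
    if (same < 0).any() or (unrel < 0).any():
        raise ValueError("distances must be non-negative")
    cands = _candidate_grid(np.concatenate([same, unrel]))
    same_s = np.sort(same)
    unrel_s = np.sort(unrel)
    tpr = np.searchsorted(same_s, cands, side="right") / same.size
    fp = np.searchsorted(unrel_s, cands, side="right") / unrel.size
    feasible = fp <= fp_bound + 1e-12
    if not feasible.any():
        raise ValueError(f"{sgb_id or 'SGB'}: no candidate satisfies FP bound {fp_bound}")
    j = tpr - fp  # TPR + (1 - fp) - 1
    j_f = np.where(feasible, j, -np.inf)
    # candidates ascend; argmax returns the first (= smallest) maximizer
    k = int(np.argmax(j_f))
    return StrainThreshold(
        sgb_id=sgb_id,
        threshold_ngd=float(cands[k]),
        method="youden",
        n_same_pairs=int(same.size),
        n_unrelated_pairs=int(unrel.size),
        fp_fraction=float(fp[k]),
        youden_j=float(j[k]),
        unrelated_percentile=float(100.0 * fp[k]),
    )


def fallback_threshold(
    unrelated_dists,
    percentile: float = DEFAULT_FALLBACK_PERCENTILE,
    min_n: int = DEFAULT_FALLBACK_MIN_N,
    sgb_id: str = "",
) -> StrainThreshold:
    """Percentile threshold on the unrelated nGD distribution (linear
    interpolation between closest ranks)."""
    unrel = np.asarray(unrelated_dists, dtype=float)
    if unrel.size < min_n:
        raise ValueError(
            f"{sgb_id or 'SGB'}: {unrel.size} unrelated distances, "
            f"need at least {min_n} for the percentile fallback"
        )
    t = float(np.percentile(unrel, percentile, method="linear"))
    fp = float(np.mean(unrel <= t))
    return StrainThreshold(
        sgb_id=sgb_id,
        threshold_ngd=t,
        method="fallback",
        n_same_pairs=0,
        n_unrelated_pairs=int(unrel.size),
        fp_fraction=fp,
        youden_j=None,
        unrelated_percentile=float(percentile),
    )


def calibrate_all(
    sgb_sets,
    pairsets: dict,
    body_sites: dict | None = None,
    min_same_pairs: int = DEFAULT_MIN_SAME_PAIRS,
    fp_bound: float = DEFAULT_FP_BOUND,
    fallback_percentile: float = DEFAULT_FALLBACK_PERCENTILE,
    fallback_min_n: int = DEFAULT_FALLBACK_MIN_N,
) -> list[StrainThreshold]:
    """Calibrate every SGB: Youden when >= ``min_same_pairs`` same-individual
    pairs exist and the SGB is not oral; the percentile fallback otherwise.

    ``pairsets`` maps sgb_id -> {"same_individual": PairSet, "unrelated":
    PairSet}. SGBs with no (or too few) unrelated pairs are skipped with a
    logged warning.
    """
    body_sites = body_sites or {}
    out: list[StrainThreshold] = []
    for dset in sgb_sets:
        sets = pairsets.get(dset.sgb_id)
        if sets is None or len(sets["unrelated"]) == 0:
            logger.warning("%s: no unrelated pairs, skipped", dset.sgb_id)
            continue
        unrel = dset.pair_distances(sets["unrelated"].pairs)
        same_pairs = sets.get("same_individual")
        same = (
            dset.pair_distances(same_pairs.pairs)
            if same_pairs is not None and len(same_pairs)
            else np.array([])
        )
        oral = body_sites.get(dset.sgb_id) == "oral"
        if same.size >= min_same_pairs and not oral:
            out.append(
                youden_threshold(same, unrel, fp_bound=fp_bound, sgb_id=dset.sgb_id)
            )
        else:
            if unrel.size < fallback_min_n:
                logger.warning(
                    "%s: only %d unrelated pairs (< %d), skipped",
                    dset.sgb_id,
                    unrel.size,
                    fallback_min_n,
                )
                continue
            out.append(
                fallback_threshold(
                    unrel,
                    percentile=fallback_percentile,
                    min_n=fallback_min_n,
                    sgb_id=dset.sgb_id,
                )
            )
    return out


def derive_fallback_percentile(thresholds) -> float:
    """Median unrelated-percentile over Youden-calibrated SGBs: the
    data-driven replacement for the default 3rd percentile."""
    pcts = [t.unrelated_percentile for t in thresholds if t.method == "youden"]
    if not pcts:
        raise ValueError("no Youden-calibrated SGBs to derive a percentile from")
    return float(np.median(pcts))


def fmt_validate(ngd, threshold: StrainThreshold, triad_of: dict) -> FMTValidation:
    """Score a threshold against FMT triads.

    Leaf pairs mapped to the same triad are positives (expected same strain:
    same individual, or donor and recipient after transplant); pairs across
    triads are negatives. Leaves absent from ``triad_of`` (for example
    pre-transplant recipient samples, whose strain relation to the donor is
    undefined) are excluded.
    """
    leaves = [l for l in ngd.leaves if l in triad_of]
    tp = fp = tn = fn = 0
    t = threshold.threshold_ngd
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            a, b = leaves[i], leaves[j]
            shared = ngd.distance(a, b) <= t
            if triad_of[a] == triad_of[b]:
                tp += shared
                fn += not shared
            else:
                fp += shared
                tn += not shared
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if recall is None:
        logger.warning("%s: no within-triad pairs, recall undefined", ngd.sgb_id)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if recall is not None and precision is not None and (recall + precision) > 0:
        f_score = 2 * recall * precision / (recall + precision)
    else:
        f_score = None
    return FMTValidation(
        sgb_id=ngd.sgb_id,
        tp=int(tp),
        fp=int(fp),
        tn=int(tn),
        fn=int(fn),
        recall=recall,
        precision=precision,
        f_score=f_score,
    )


def thresholds_to_frame(thresholds) -> pd.DataFrame:
    """Tidy thresholds table, ready for TSV output."""
    return pd.DataFrame(
        [
            {
                "sgb_id": t.sgb_id,
                "threshold_ngd": t.threshold_ngd,
                "method": t.method,
                "n_same_pairs": t.n_same_pairs,
                "n_unrelated_pairs": t.n_unrelated_pairs,
                "fp_fraction": t.fp_fraction,
                "youden_j": t.youden_j,
                "unrelated_percentile": t.unrelated_percentile,
            }
            for t in thresholds
        ]
    )
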