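"""Calibration pair sets: same-individual longitudinal and unrelated pairs.

Strain-identity thresholds are calibrated by contrasting the nGD distribution
of pairs of samples from the same individual taken close in time (strains
persist within a host for months) against pairs from unrelated individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAME_INDIVIDUAL = "same_individual"
UNRELATED = "unrelated"

DEFAULT_MAX_GAP_DAYS = 183  # "no more than 6 months apart"


@dataclass
class PairSet:
    """Sample pairs with a calibration role."""

    pairs: list[tuple[str, str]]
    role: str
    max_gap_days: int | None = None

    def __len__(self) -> int:
        return len(self.pairs)


def select_longitudinal_pairs(
    samples: pd.DataFrame,
    sgb_leaves,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
) -> PairSet:
    """At most one same-individual pair per subject: the closest-in-time pair
    of strain-profiled samples with gap <= ``max_gap_days``.

    ``sgb_leaves`` identifies the samples with a strain profile for the SGB.
    Subjects with fewer than two profiled samples, or whose closest pair is
    further apart than the gap, are omitted.
    """
    leaves = set(sgb_leaves)
    prof = samples[samples["sample_id"].isin(leaves)].copy()
    prof = prof.dropna(subset=["collection_day"])
    pairs: list[tuple[str, str]] = []
    for _, grp in prof.groupby("subject_id", sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values(["collection_day", "sample_id"])
        days = grp["collection_day"].to_numpy(dtype=float)
        ids = grp["sample_id"].to_list()
        gaps = np.diff(days)
        k = int(np.argmin(gaps))  # ties -> earliest pair
        if gaps[k] <= max_gap_days:
            pairs.append((ids[k], ids[k + 1]))
    return PairSet(pairs=pairs, role=SAME_INDIVIDUAL, max_gap_days=max_gap_days)


def enumerate_unrelated_pairs(
    samples: pd.DataFrame,
    sgb_leaves,
    scope: str = "pooled",
    seed: int = 0,
) -> PairSet:
    """All cross-subject sample pairs with no household or parent/child link.

    One sample per subject is chosen at random (seeded) among that subject's
    strain-profiled samples, to avoid pseudo-replication of individuals in
    the unrelated distribution. ``scope="within_dataset"`` restricts pairs to
    the same ``dataset_id``; ``"pooled"`` allows cross-dataset pairs.
    """
    if scope not in ("pooled", "within_dataset"):
        raise ValueError(f"unknown scope {scope!r}")
    leaves = set(sgb_leaves)
    prof = samples[samples["sample_id"].isin(leaves)]
    rng = np.random.default_rng(seed)
    chosen = []
    for _, grp in prof.sort_values("sample_id").groupby("subject_id", sort=True):
        ids = grp["sample_id"].to_list()
        chosen.append(grp.iloc[rng.integers(len(ids))])
    if not chosen:
        return PairSet(pairs=[], role=UNRELATED)
    sub = pd.DataFrame(chosen)
    rows = list(sub.itertuples(index=False))
    pairs: list[tuple[str, str]] = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i]._asdict(), rows[j]._asdict()
            if a["subject_id"] == b["subject_id"]:
                continue
            if scope == "within_dataset" and a["dataset_id"] != b["dataset_id"]:
                continue
            ha, hb = a.get("household_id"), b.get("household_id")
            if pd.notna(ha) and pd.notna(hb) and ha == hb:
                continue
            if _parent_link(a, b):
                continue
            pairs.append((a["sample_id"], b["sample_id"]))
    return PairSet(pairs=pairs, role=UNRELATED)


def _parent_link(a: dict, b: dict) -> bool:
    """True when one subject is a recorded parent of the other."""
    for x, y in ((a, b), (b, a)):
        for col in ("mother_id", "father_id"):
            v = x.get(col)
            if pd.notna(v) and v == y["subject_id"]:
                return True
    return False
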