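"""Per-SGB transmissibility across transmission modes.

Transmissibility of a species (SGB) in a transmission mode is the number of
strain-sharing events divided by the number of potential events — pairs of
mode-eligible subjects that both carry a strain-level profile of the SGB.
Modes: mother-infant (mother and her offspring up to one year of age),
household (cohabiting individuals) and intra-population (non-cohabiting
individuals of one population with no evidence of kinship). An SGB is
"highly transmitted" in a mode when its transmissibility exceeds 0.5 AND the
within-group event proportion significantly exceeds that of a matched
among-group (unrelated) comparison set (chi-squared, Benjamini-Hochberg
adjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MODES = ("mother_infant", "household", "intra_population")
MIN_POTENTIAL_POOLED = 10
MIN_POTENTIAL_SINGLE_DATASET = 3
DEFAULT_ALPHA = 0.05
DEFAULT_T_MIN = 0.5


@dataclass
class TransmissibilityRecord:
    sgb_id: str
    mode: str
    scope: str  # dataset_id or "all"
    n_events: int
    n_potential: int
    transmissibility: float | None
    chi2_stat: float | None = None
    p_value: float | None = None
    p_adj: float | None = None
    highly_transmitted: bool | None = None


def mode_eligible_pairs(
    classified: pd.DataFrame, subjects: pd.DataFrame, mode: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-group and among-group subject pairs for a transmission mode.

    The among group matches the mode's social structure but removes the
    relationship: unrelated mother x infant pairs of the same dataset for
    mother_infant; different-household same-dataset pairs for household;
    cross-dataset pairs for intra_population.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    df = classified
    if mode == "mother_infant":
        within = df[
            (df["category"] == "mother_offspring")
            & (df["offspring_age_bin"] == "<=1y")
        ]
        mothers = set()
        for _, row in subjects.iterrows():
            if pd.notna(row["mother_id"]):
                mothers.add(row["mother_id"])
        infants = set(
            subjects.loc[subjects["age_years"] <= 1.0, "subject_id"].dropna()
        )

        def unrelated_mother_infant(row):
            a, b = row["subject_a"], row["subject_b"]
            cross = (a in mothers and b in infants) or (b in mothers and a in infants)
            return cross and row["same_dataset"] and not row["same_household"]

        among = df[
            (df["category"].isin(["same_village", "same_population"]))
            & df.apply(unrelated_mother_infant, axis=1)
        ]
        return within, among
    if mode == "household":
        within = df[df["same_household"]]
        among = df[df["same_dataset"] & ~df["same_household"]]
        return within, among
    # intra_population: same dataset, different household, no kinship
    within = df[df["category"].isin(["same_village", "same_population"])]
    among = df[df["category"] == "inter_population"]
    return within, among


def potential_events(
    sgb_id: str, pairs: pd.DataFrame, per_sgb_calls: dict
) -> tuple[int, int]:
    """(events, potential) for one SGB over a set of eligible subject pairs.

    Potential events are eligible pairs where both subjects have a strain
    profile for the SGB — exactly the pairs present in the subject-level
    call table; events are those called shared.
    """
    calls = per_sgb_calls.get(sgb_id)
    if calls is None or calls.empty or pairs.empty:
        return 0, 0
    sel = calls.merge(
        pairs[["subject_a", "subject_b"]].drop_duplicates(),
        on=["subject_a", "subject_b"],
        how="inner",
    )
    return int(sel["shared"].sum()), int(len(sel))


def compute_transmissibility(
    n_events: int, n_potential: int, min_potential: int
) -> float | None:
    """events / potential, or missing below the scope's minimum."""
    if n_events > n_potential:
        raise ValueError(f"events ({n_events}) exceed potential ({n_potential})")
    if n_potential < min_potential:
        return None
    return n_events / n_potential


def chi2_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = True
) -> tuple[float | None, float | None]:
    """Pearson chi-squared on [[a, b], [c, d]] with optional Yates
    continuity correction, 1 degree of freedom.

    Rows are within/among group; columns events/non-events. A zero margin
    makes the statistic undefined (missing, logged).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("chi2_2x2: zero margin in table %s", table.tolist())
        return None, None
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


def transmissibility_table(
    sgb_ids,
    per_sgb_calls: dict,
    within_pairs: pd.DataFrame,
    among_pairs: pd.DataFrame,
    mode: str,
    scope: str = "all",
    min_potential: int | None = None,
) -> pd.DataFrame:
    """Per-SGB event/potential counts and transmissibility for one mode and
    scope, with the among-group (unrelated) counts alongside."""
    if min_potential is None:
        min_potential = (
            MIN_POTENTIAL_POOLED if scope == "all" else MIN_POTENTIAL_SINGLE_DATASET
        )
    rows = []
    for sgb in sgb_ids:
        e_w, n_w = potential_events(sgb, within_pairs, per_sgb_calls)
        e_a, n_a = potential_events(sgb, among_pairs, per_sgb_calls)
        rows.append(
            {
                "sgb_id": sgb,
                "mode": mode,
                "scope": scope,
                "n_events": e_w,
                "n_potential": n_w,
                "transmissibility": compute_transmissibility(e_w, n_w, min_potential),
                "n_events_among": e_a,
                "n_potential_among": n_a,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["transmissibility"] = pd.to_numeric(out["transmissibility"])
    return out


def flag_highly_transmitted(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    t_min: float = DEFAULT_T_MIN,
    continuity: bool = True,
) -> pd.DataFrame:
    """Flag SGBs with transmissibility > ``t_min`` whose within-group event
    proportion significantly exceeds the among-group proportion.

    Chi-squared p-values are Benjamini-Hochberg adjusted across all SGBs
    tested in the mode (those with assessed transmissibility and a usable
    among-group table); the flag additionally requires the within proportion
    to exceed the among proportion (direction check).
    """
    out = table.copy()
    stats_, pvals, testable = [], [], []
    for _, row in out.iterrows():
        ok = row["transmissibility"] is not None and not pd.isna(
            row["transmissibility"]
        )
        if ok and row["n_potential_among"] > 0:
            s, p = chi2_2x2(
                int(row["n_events"]),
                int(row["n_potential"] - row["n_events"]),
                int(row["n_events_among"]),
                int(row["n_potential_among"] - row["n_events_among"]),
                continuity=continuity,
            )
        else:
            if ok:
                logger.warning(
                    "%s: no among-group pairs, significance undefined", row["sgb_id"]
                )
            s = p = None
        stats_.append(s)
        pvals.append(p)
        testable.append(p is not None)
    out["chi2_stat"] = pd.array(stats_, dtype="float64")
    out["p_value"] = pd.array(pvals, dtype="float64")
    out["p_adj"] = np.nan
    mask = np.array(testable)
    if mask.any():
        _, p_adj, _, _ = multipletests(
            np.array(pvals, dtype=object)[mask].astype(float), method="fdr_bh"
        )
        out.loc[mask, "p_adj"] = p_adj
    within_prop = out["n_events"] / out["n_potential"].replace(0, np.nan)
    among_prop = out["n_events_among"] / out["n_potential_among"].replace(0, np.nan)
    transm = pd.to_numeric(out["transmissibility"], errors="coerce")
    flags = (
        (transm > t_min)
        & (within_prop > among_prop)
        & (out["p_adj"] < alpha)
    )
    out["highly_transmitted"] = flags.astype(object)
    out.loc[~mask, "highly_transmitted"] = None
    return out


def dataset_concordance(
    per_dataset: pd.DataFrame, min_sgbs: int = 10
) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-dataset transmissibility.

    ``per_dataset`` is a wide table (rows = SGBs, columns = datasets) of
    transmissibility values; dataset pairs with fewer than ``min_sgbs`` SGBs
    assessed in both are omitted, and constant vectors give a missing rho.
    """
    cols = list(per_dataset.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            sub = per_dataset[[cols[i], cols[j]]].dropna()
            if len(sub) < min_sgbs:
                continue
            x, y = sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                logger.warning(
                    "constant transmissibility vector for %s/%s", cols[i], cols[j]
                )
                rho, p = None, None
            else:
                res = stats.spearmanr(x, y)
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "dataset_a": cols[i],
                    "dataset_b": cols[j],
                    "n_sgbs": len(sub),
                    "rho": rho,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["dataset_a", "dataset_b", "n_sgbs", "rho", "p"])
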