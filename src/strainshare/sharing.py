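"""Strain-sharing events, rates and networks.

A strain-sharing event is a pair of samples whose nGD for one SGB lies
at/below that SGB's strain-identity threshold. Events are collapsed to the
subject level (shared at any time point = shared), and summarized as
person-to-person strain-sharing rates: shared strains / shared strain-profiled
SGBs x 100%, assessed only for pairs sharing at least ten SGBs. Strains
closely matching genomes from commercial fermented foods are excluded first,
so that co-acquisition from diet is not mistaken for person-to-person
transmission.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_SHARED_SGBS = 10
DEFAULT_FOOD_MAX_SNV = 0.0015
DEFAULT_NETWORK_MIN_STRAINS = 5
DEFAULT_NETWORK_MIN_SPECIES = 50

CATEGORIES = [
    "same_individual",
    "mother_offspring",
    "father_offspring",
    "twins",
    "partners",
    "siblings",
    "household",
    "same_village",
    "same_population",
    "inter_population",
]

AGE_BINS = [
    ("<=1y", 0.0, 1.0),
    ("1-3y", 1.0, 3.0),
    ("3-18y", 3.0, 18.0),
    ("18-30y", 18.0, 30.0),
    ("50-85y", 50.0, 85.0),
]


def select_sgbs_for_profiling(
    detection: pd.DataFrame,
    dataset_sizes: dict,
    min_samples: int = 20,
    min_fraction: float = 0.10,
) -> list[str]:
    """SGBs detected in >= ``min_samples`` samples AND >= ``min_fraction`` of
    samples in at least one dataset.

    ``detection`` has columns sgb_id, dataset_id, n_detected.
    """
    unknown = set(detection["dataset_id"]) - set(dataset_sizes)
    if unknown:
        raise ValueError(f"detection table names unknown datasets: {sorted(unknown)}")
    sizes = detection["dataset_id"].map(dataset_sizes).astype(float)
    ok = (detection["n_detected"] >= min_samples) & (
        detection["n_detected"] / sizes >= min_fraction
    )
    return sorted(detection.loc[ok, "sgb_id"].unique())


def flag_food_strains(
    snv_rate: pd.DataFrame | None,
    food_refs,
    max_snv: float = DEFAULT_FOOD_MAX_SNV,
) -> set[str]:
    """Samples whose minimum SNV rate to any food-reference genome is
    <= ``max_snv`` (inclusive). Returns the excluded sample ids.

    ``snv_rate`` is long-format with columns id_a, id_b, snv_rate.
    """
    food = set(food_refs or [])
    if not food or snv_rate is None or snv_rate.empty:
        logger.info("no food references supplied; nothing excluded")
        return set()
    a_food = snv_rate["id_a"].isin(food)
    b_food = snv_rate["id_b"].isin(food)
    rows = snv_rate[a_food ^ b_food]
    sample = np.where(rows["id_a"].isin(food), rows["id_b"], rows["id_a"])
    mins = pd.Series(rows["snv_rate"].to_numpy(), index=sample).groupby(level=0).min()
    return set(mins.index[mins <= max_snv])


def call_sharing_events(
    dset,
    threshold,
    excluded=frozenset(),
    sample_ids=None,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-sample-pair sharing calls for one SGB.

    The comparison is inclusive by default (nGD <= threshold -> shared);
    ``strict=True`` switches to nGD < threshold. Pairs involving excluded
    samples (food-origin strains) or non-sample leaves (food-reference
    genomes) are not formed.
    """
    if threshold.sgb_id and threshold.sgb_id != dset.sgb_id:
        raise ValueError(
            f"threshold for {threshold.sgb_id!r} applied to {dset.sgb_id!r}"
        )
    keep_idx = [
        k
        for k, l in enumerate(dset.leaves)
        if l not in excluded and (sample_ids is None or l in sample_ids)
    ]
    keep = np.array([dset.leaves[k] for k in keep_idx], dtype=object)
    sub = dset.ngd[np.ix_(keep_idx, keep_idx)]
    iu = np.triu_indices(len(keep_idx), k=1)
    vals = sub[iu]
    shared = vals < threshold.threshold_ngd if strict else vals <= threshold.threshold_ngd
    return pd.DataFrame(
        {
            "sgb_id": dset.sgb_id,
            "sample_a": keep[iu[0]],
            "sample_b": keep[iu[1]],
            "ngd": vals,
            "shared": shared,
        }
    )


def collapse_to_subjects(calls: pd.DataFrame, sample_to_subject: dict) -> pd.DataFrame:
    """Collapse sample-pair calls to subject pairs.

    A subject pair shares the strain if ANY cross-subject sample pair is
    called shared (sharing at any time point counts); ``min_ngd`` is the
    minimum over contributing sample pairs. Subject pairs appear whenever
    both subjects have at least one profiled sample, i.e. they share the
    SGB profile.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["sgb_id", "subject_a", "subject_b", "shared", "min_ngd"]
        )
    df = calls.copy()
    df["sub_a"] = df["sample_a"].map(sample_to_subject)
    df["sub_b"] = df["sample_b"].map(sample_to_subject)
    if df["sub_a"].isna().any() or df["sub_b"].isna().any():
        raise ValueError("some samples are not mapped to a subject")
    df = df[df["sub_a"] != df["sub_b"]]
    lo = np.minimum(df["sub_a"], df["sub_b"])
    hi = np.maximum(df["sub_a"], df["sub_b"])
    df = df.assign(subject_a=lo, subject_b=hi)
    out = (
        df.groupby(["sgb_id", "subject_a", "subject_b"], as_index=False)
        .agg(shared=("shared", "any"), min_ngd=("ngd", "min"))
        .sort_values(["sgb_id", "subject_a", "subject_b"], ignore_index=True)
    )
    return out


def aggregate_subject_pairs(per_sgb_calls: dict) -> pd.DataFrame:
    """Count shared SGBs and shared strains per subject pair across SGBs."""
    frames = [df for df in per_sgb_calls.values() if not df.empty]
    if not frames:
        return pd.DataFrame(
            columns=["subject_a", "subject_b", "n_shared_sgbs", "n_shared_strains"]
        )
    allc = pd.concat(frames, ignore_index=True)
    out = (
        allc.groupby(["subject_a", "subject_b"], as_index=False)
        .agg(n_shared_sgbs=("sgb_id", "nunique"), n_shared_strains=("shared", "sum"))
        .sort_values(["subject_a", "subject_b"], ignore_index=True)
    )
    out["n_shared_strains"] = out["n_shared_strains"].astype(int)
    if (out["n_shared_strains"] > out["n_shared_sgbs"]).any():
        raise RuntimeError("shared strains exceed shared SGBs (internal error)")
    return out


def sharing_rate(
    pair_counts: pd.DataFrame, min_shared_sgbs: int = DEFAULT_MIN_SHARED_SGBS
) -> pd.DataFrame:
    """Add ``sharing_rate_pct`` = 100 x shared strains / shared SGBs; missing
    (NaN) for pairs sharing fewer than ``min_shared_sgbs`` SGBs."""
    out = pair_counts.copy()
    rate = 100.0 * out["n_shared_strains"] / out["n_shared_sgbs"]
    rate[out["n_shared_sgbs"] < min_shared_sgbs] = np.nan
    out["sharing_rate_pct"] = rate
    return out


def subject_profiles(dset, sample_to_subject: dict, excluded=frozenset()) -> set:
    """Subjects with at least one non-excluded strain-profiled sample."""
    return {
        sample_to_subject[l]
        for l in dset.leaves
        if l in sample_to_subject and l not in excluded
    }


def acquisition_rate(
    offspring_subject: str,
    mother_subject: str,
    per_sgb_calls: dict,
    per_sgb_profiles: dict,
    min_shared_sgbs: int = DEFAULT_MIN_SHARED_SGBS,
) -> float | None:
    """Proportion of the offspring's strain-profiled SGBs whose strain is
    shared with the mother (putative maternal origin).

    Missing when mother and offspring share fewer than ``min_shared_sgbs``
    strain-profiled SGBs, or the offspring has no strain profiles.
    """
    a, b = sorted((offspring_subject, mother_subject))
    offspring_sgbs = [
        sgb for sgb, profs in per_sgb_profiles.items() if offspring_subject in profs
    ]
    if not offspring_sgbs:
        logger.warning("%s: no strain profiles, acquisition rate undefined",
                       offspring_subject)
        return None
    n_common = 0
    n_shared = 0
    for sgb in offspring_sgbs:
        if mother_subject not in per_sgb_profiles[sgb]:
            continue
        n_common += 1
        calls = per_sgb_calls.get(sgb)
        if calls is None or calls.empty:
            continue
        row = calls[(calls["subject_a"] == a) & (calls["subject_b"] == b)]
        if not row.empty and bool(row["shared"].iloc[0]):
            n_shared += 1
    if n_common < min_shared_sgbs:
        return None
    return n_shared / len(offspring_sgbs)


def _age_bin(age) -> str | None:
    if age is None or pd.isna(age):
        return None
    for label, lo, hi in AGE_BINS:
        if (lo < age <= hi) or (label == "<=1y" and age <= hi) or (
            label == "50-85y" and lo <= age <= hi
        ):
            return label
    return None


def classify_pair(subject_a: str, subject_b: str, subjects: pd.DataFrame):
    """Relationship category for one subject pair, with the offspring age bin
    for parent-offspring pairs.

    Precedence: mother_offspring > father_offspring > twins > partners >
    siblings > household > same_village > same_population > inter_population.
    Subjects with missing household default to non-cohabiting.
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    try:
        ra, rb = sub.loc[subject_a], sub.loc[subject_b]
    except KeyError as exc:
        raise ValueError(f"unknown subject: {exc}") from exc
    return _classify_rows(subject_a, subject_b, ra, rb, _children_index(sub))


def _children_index(subjects: pd.DataFrame) -> dict:
    """subject_id -> set of recorded children (via mother_id/father_id)."""
    children: dict[str, set] = {}
    frame = subjects.reset_index() if "subject_id" not in subjects.columns else subjects
    for _, row in frame.iterrows():
        for col in ("mother_id", "father_id"):
            v = row[col]
            if pd.notna(v):
                children.setdefault(v, set()).add(row["subject_id"])
    return children


def _classify_rows(sa, sb, ra, rb, children):
    def is_parent(child_row, parent_id, col):
        v = child_row[col]
        return pd.notna(v) and v == parent_id

    # parent-offspring (either direction)
    if is_parent(rb, sa, "mother_id"):
        return "mother_offspring", _age_bin(rb["age_years"])
    if is_parent(ra, sb, "mother_id"):
        return "mother_offspring", _age_bin(ra["age_years"])
    if is_parent(rb, sa, "father_id"):
        return "father_offspring", _age_bin(rb["age_years"])
    if is_parent(ra, sb, "father_id"):
        return "father_offspring", _age_bin(ra["age_years"])
    shared_mother = (
        pd.notna(ra["mother_id"]) and pd.notna(rb["mother_id"])
        and ra["mother_id"] == rb["mother_id"]
    )
    shared_father = (
        pd.notna(ra["father_id"]) and pd.notna(rb["father_id"])
        and ra["father_id"] == rb["father_id"]
    )
    same_age = (
        pd.notna(ra["age_years"]) and pd.notna(rb["age_years"])
        and abs(float(ra["age_years"]) - float(rb["age_years"])) <= 0.25
    )
    if shared_mother and shared_father and same_age:
        return "twins", None
    cohabiting = (
        pd.notna(ra["household_id"]) and pd.notna(rb["household_id"])
        and ra["household_id"] == rb["household_id"]
    )
    if cohabiting and children.get(sa, set()) & children.get(sb, set()):
        return "partners", None
    if shared_mother or shared_father:
        return "siblings", None
    if cohabiting:
        return "household", None
    same_village = (
        pd.notna(ra["village_id"]) and pd.notna(rb["village_id"])
        and ra["village_id"] == rb["village_id"]
    )
    if ra["dataset_id"] == rb["dataset_id"]:
        return ("same_village" if same_village else "same_population"), None
    return "inter_population", None


def classify_pairs(subjects: pd.DataFrame) -> pd.DataFrame:
    """Classify every subject pair (vectorized).

    Returns one row per unordered pair (subject_a < subject_b) with the
    relationship category, the offspring age bin where applicable, and
    cohabitation / dataset context columns used by the transmissibility
    mode definitions. Agrees with :func:`classify_pair` pair-by-pair.
    """
    sub = subjects.sort_values("subject_id").reset_index(drop=True)
    n = len(sub)

    def _col(name):
        arr = sub[name].to_numpy(dtype=object)
        return np.where(pd.isna(arr), None, arr)

    ids = _col("subject_id")
    mother = _col("mother_id")
    father = _col("father_id")
    household = _col("household_id")
    village = _col("village_id")
    dataset = _col("dataset_id")
    age = pd.to_numeric(sub["age_years"]).to_numpy(dtype=float)
    ii, jj = np.triu_indices(n, k=1)

    def _eq(arr, a, b):
        x, y = arr[a], arr[b]
        return (x == y) & pd.notna(x) & pd.notna(y)

    a_mother_of_b = (mother[jj] == ids[ii]) & pd.notna(mother[jj])
    b_mother_of_a = (mother[ii] == ids[jj]) & pd.notna(mother[ii])
    a_father_of_b = (father[jj] == ids[ii]) & pd.notna(father[jj])
    b_father_of_a = (father[ii] == ids[jj]) & pd.notna(father[ii])
    shared_mother = _eq(mother, ii, jj)
    shared_father = _eq(father, ii, jj)
    same_age = (
        pd.notna(age[ii]) & pd.notna(age[jj]) & (np.abs(age[ii] - age[jj]) <= 0.25)
    )
    cohab = _eq(household, ii, jj)
    couples = {
        tuple(sorted((m, f)))
        for m, f in zip(mother, father)
        if pd.notna(m) and pd.notna(f)
    }
    partners = cohab & np.fromiter(
        (
            (a, b) in couples
            for a, b in zip(ids[ii], ids[jj])
        ),
        dtype=bool,
        count=len(ii),
    )
    same_village = _eq(village, ii, jj)
    same_dataset = dataset[ii] == dataset[jj]
    mother_off = a_mother_of_b | b_mother_of_a
    father_off = a_father_of_b | b_father_of_a
    category = np.select(
        [
            mother_off,
            father_off,
            shared_mother & shared_father & same_age,
            partners,
            shared_mother | shared_father,
            cohab,
            same_village,
            same_dataset,
        ],
        [
            "mother_offspring",
            "father_offspring",
            "twins",
            "partners",
            "siblings",
            "household",
            "same_village",
            "same_population",
        ],
        default="inter_population",
    )
    # offspring age for parent-offspring pairs: the child's side
    child_age = np.where(a_mother_of_b | a_father_of_b, age[jj], age[ii])
    bins = np.array(
        [_age_bin(a) for a in child_age], dtype=object
    )
    offspring_bin = np.where(
        np.isin(category, ["mother_offspring", "father_offspring"]), bins, None
    )
    return pd.DataFrame(
        {
            "subject_a": ids[ii],
            "subject_b": ids[jj],
            "category": category,
            "offspring_age_bin": offspring_bin,
            "same_household": cohab,
            "same_dataset": same_dataset,
            "dataset_id": np.where(same_dataset, dataset[ii], None),
        }
    )


def rate_by_relationship(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-category median and IQR of sharing rates, plus the percentage of
    pairs with no strain-sharing event, over pairs with a defined rate."""
    df = summaries.dropna(subset=["sharing_rate_pct"])
    rows = []
    for cat, grp in df.groupby("category"):
        rows.append(
            {
                "category": cat,
                "n_pairs": len(grp),
                "median_rate_pct": float(grp["sharing_rate_pct"].median()),
                "q1_rate_pct": float(grp["sharing_rate_pct"].quantile(0.25)),
                "q3_rate_pct": float(grp["sharing_rate_pct"].quantile(0.75)),
                "zero_sharing_pct": float(
                    100.0 * (grp["n_shared_strains"] == 0).mean()
                ),
            }
        )
    order = {c: k for k, c in enumerate(CATEGORIES)}
    rows.sort(key=lambda r: order.get(r["category"], 99))
    return pd.DataFrame(rows)


def build_sharing_network(
    summaries: pd.DataFrame,
    min_shared_strains: int = DEFAULT_NETWORK_MIN_STRAINS,
    kind: str = "strains",
) -> pd.DataFrame:
    """Undirected edge list of subject pairs sharing >= ``min_shared_strains``
    strains (``kind="strains"``) or that many SGB profiles in common
    (``kind="species"``, conventionally with a >= 50 cutoff)."""
    col = {"strains": "n_shared_strains", "species": "n_shared_sgbs"}[kind]
    edges = summaries[summaries[col] >= min_shared_strains]
    edges = edges[edges["subject_a"] != edges["subject_b"]]
    out = edges[["subject_a", "subject_b", col]].sort_values(
        ["subject_a", "subject_b"], ignore_index=True
    )
    return out


def network_graph(edges: pd.DataFrame) -> nx.Graph:
    """networkx view of an edge list (weight = shared count column)."""
    g = nx.Graph()
    weight_col = [c for c in edges.columns if c.startswith("n_shared")][0]
    for _, row in edges.iterrows():
        g.add_edge(row["subject_a"], row["subject_b"], weight=int(row[weight_col]))
    return g
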