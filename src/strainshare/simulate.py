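"""Synthetic cohorts with planted strain sharing and ground truth.

The generator emulates the structure of multi-population strain-transmission
studies: datasets (populations) split into villages and households, with
mothers, fathers, offspring (including twins), longitudinal sampling of a
configured fraction of subjects, per-SGB phylogenies with a bimodal nGD
structure (a tight same-strain peak near zero against a broad unrelated
bulk), food-origin strains sitting at <= 0.0015 SNV rate from food-reference
genomes, and FMT triads (donor / recipient-pre / recipient-post).

Strain identity is planted as a partition of samples per SGB: union-find
over planted sharing edges between subjects (so "same strain" is transitive
by construction), plus longitudinal retention within subjects. Same-strain
leaves attach to a shared backbone tip with short pendants
(``same_strain_scale``); the backbone over strain classes uses much longer
branches (``backbone_scale``), which guarantees the bimodal separation.

Trees are the primary emission (exercising the Newick reader end to end);
the matching nGD matrices, computed during construction, are the fast
secondary emission used for large parameter-recovery runs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from strainshare.cohort import METADATA_COLUMNS, subject_table
from strainshare.phylo import SGBDistanceSet
from strainshare.sharing import classify_pairs

logger = logging.getLogger(__name__)

DEFAULT_SHARING_PROBS = {
    "mother_offspring": 0.19,  # offspring beyond infancy
    "father_offspring": 0.12,
    "twins": 0.08,
    "partners": 0.13,
    "siblings": 0.12,
    "household": 0.12,
    "same_village": 0.08,
    "same_population": 0.02,
    "inter_population": 0.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_datasets: int = 2
    villages_per_dataset: int = 4
    households_per_dataset: int = 20
    min_subjects_per_household: int = 2
    max_subjects_per_household: int = 5
    longitudinal_fraction: float = 0.8
    infant_first_prob: float = 0.6
    max_gap_days: int = 183
    n_sgbs: int = 20
    carriage_prob: float = 0.65
    retention_prob: float = 0.87
    sharing_probs: dict = field(default_factory=lambda: dict(DEFAULT_SHARING_PROBS))
    sgb_transmissibility: list | None = None  # mother-infant, per SGB
    same_strain_scale: float = 0.005
    backbone_scale: float = 1.0
    food_fraction: float = 0.05
    food_sgb_prob: float = 0.3
    n_food_refs: int = 2
    fmt_triads: int = 10
    fmt_engraftment: float = 0.9
    fmt_sgbs: int = 3

    def __post_init__(self) -> None:
        if self.households_per_dataset < 1 or self.n_datasets < 1:
            raise ValueError("need at least one dataset and one household")
        if self.same_strain_scale / self.backbone_scale > 0.01:
            raise ValueError(
                "same_strain_scale must be <= 1% of backbone_scale "
                "to guarantee same-strain / unrelated separation"
            )
        for k, v in self.sharing_probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"sharing prob {k}={v} outside [0, 1]")
        if self.sgb_transmissibility is None:
            self.sgb_transmissibility = list(
                np.linspace(0.05, 0.95, self.n_sgbs)
            )
        if len(self.sgb_transmissibility) != self.n_sgbs:
            raise ValueError("sgb_transmissibility length must equal n_sgbs")


@dataclass
class GroundTruth:
    """Planted truth for one simulated suite."""

    sample_classes: dict  # sgb_id -> {sample_id: class index}
    food_samples: dict  # sgb_id -> set of sample_ids
    food_refs: dict  # sgb_id -> list of food-reference leaf ids
    planted_transmissibility: dict  # sgb_id -> mother-infant probability

    def pair_shared(self, sgb_id: str, sample_a: str, sample_b: str) -> bool:
        classes = self.sample_classes[sgb_id]
        return classes[sample_a] == classes[sample_b]

    def pair_table(self, sgb_id: str) -> pd.DataFrame:
        """All unordered sample pairs of one SGB with the planted truth."""
        classes = self.sample_classes[sgb_id]
        ids = sorted(classes)
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    (
                        sgb_id,
                        ids[i],
                        ids[j],
                        classes[ids[i]] == classes[ids[j]],
                    )
                )
        return pd.DataFrame(
            rows, columns=["sgb_id", "sample_a", "sample_b", "shared"]
        )


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata table for a synthetic cohort (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for d in range(config.n_datasets):
        dataset = f"D{d + 1}"
        westernized = d % 2 == 0
        for h in range(config.households_per_dataset):
            household = f"{dataset}_H{h + 1:03d}"
            village = f"{dataset}_V{h % config.villages_per_dataset + 1}"
            n_subj = int(
                rng.integers(
                    config.min_subjects_per_household,
                    config.max_subjects_per_household + 1,
                )
            )
            mother = f"{household}_S1"
            rows.append(
                _subject(mother, dataset, household, village,
                         float(rng.uniform(22, 42)), None, None, westernized)
            )
            father = None
            if n_subj >= 3:
                father = f"{household}_S2"
                rows.append(
                    _subject(father, dataset, household, village,
                             float(rng.uniform(24, 48)), None, None, westernized)
                )
            n_offspring = n_subj - (2 if father else 1)
            twin_household = n_offspring >= 2 and rng.random() < 0.2
            offspring_ages = []
            for k in range(n_offspring):
                if k == 0:
                    # first child is an infant in a configured share of homes
                    age = (
                        float(rng.uniform(0.05, 1.0))
                        if rng.random() < config.infant_first_prob
                        else float(rng.uniform(1.0, 18.0))
                    )
                elif twin_household and k == 1:
                    age = offspring_ages[0]
                else:
                    age = float(rng.uniform(1.0, 18.0))
                offspring_ages.append(age)
                sid = f"{household}_S{k + (3 if father else 2)}"
                rows.append(
                    _subject(sid, dataset, household, village, age,
                             mother, father, westernized)
                )
    subjects = pd.DataFrame(rows)
    # exact quota of longitudinally sampled subjects
    n_long = int(round(config.longitudinal_fraction * len(subjects)))
    long_idx = set(
        rng.choice(len(subjects), size=n_long, replace=False).tolist()
    )
    samples = []
    for i, row in subjects.iterrows():
        day0 = int(rng.integers(0, 365))
        samples.append(_sample(row, f"{row['subject_id']}_T0", day0))
        if i in long_idx:
            gap = int(rng.integers(30, config.max_gap_days + 1))
            samples.append(_sample(row, f"{row['subject_id']}_T1", day0 + gap))
    df = pd.DataFrame(samples, columns=METADATA_COLUMNS)
    return df


def _subject(sid, dataset, household, village, age, mother, father, westernized):
    return {
        "subject_id": sid,
        "dataset_id": dataset,
        "household_id": household,
        "village_id": village,
        "age_years": round(age, 2),
        "mother_id": mother,
        "father_id": father,
        "westernized": westernized,
    }


def _sample(subject_row, sample_id, day):
    return {
        "sample_id": sample_id,
        "subject_id": subject_row["subject_id"],
        "dataset_id": subject_row["dataset_id"],
        "body_site": "gut",
        "collection_day": day,
        "age_years": subject_row["age_years"],
        "household_id": subject_row["household_id"],
        "village_id": subject_row["village_id"],
        "mother_id": subject_row["mother_id"],
        "father_id": subject_row["father_id"],
        "westernized": subject_row["westernized"],
    }


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _plant_classes(
    carriers: list[str],
    carrier_subjects: pd.DataFrame,
    classified: pd.DataFrame,
    mother_infant_p: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Planted strain classes over the carrier samples of one SGB.

    Close relationships (parent-offspring, twins, partners, siblings,
    cohabitants) share dyadically with their configured pairwise
    probability. Village- and population-level sharing is modelled as a
    circulating strain: each eligible subject independently adopts the
    village (or population) strain with probability sqrt(p), so that any
    two of them share it with probability ~p without the transitive
    percolation a dense pairwise random graph would produce.
    """
    subjects = set(carrier_subjects["subject_id"])
    uf = _UnionFind(subjects)
    probs = config.sharing_probs
    dyadic = {
        "mother_offspring",
        "father_offspring",
        "twins",
        "partners",
        "siblings",
        "household",
        "inter_population",
    }
    active = {c for c in dyadic if probs.get(c, 0.0) > 0}
    if mother_infant_p > 0:
        active.add("mother_offspring")
    pair_view = classified[
        classified["category"].isin(active)
        & classified["subject_a"].isin(subjects)
        & classified["subject_b"].isin(subjects)
    ]
    for row in pair_view.itertuples(index=False):
        if row.category == "mother_offspring" and row.offspring_age_bin == "<=1y":
            p = mother_infant_p
        elif row.category in dyadic:
            p = probs.get(row.category, 0.0)
        else:
            continue
        if p > 0 and rng.random() < p:
            uf.union(row.subject_a, row.subject_b)
    for level, prob_key in (("village_id", "same_village"), ("dataset_id", "same_population")):
        q = float(np.sqrt(probs.get(prob_key, 0.0)))
        if q == 0:
            continue
        for _, members in carrier_subjects.sort_values("subject_id").groupby(level):
            ids = members["subject_id"].to_list()
            joiners = [s for s in ids if rng.random() < q]
            for a, b in zip(joiners, joiners[1:]):
                uf.union(a, b)
    # subject class -> integer labels
    roots = {}
    next_class = 0
    subject_class = {}
    for s in sorted(subjects):
        r = uf.find(s)
        if r not in roots:
            roots[r] = next_class
            next_class += 1
        subject_class[s] = roots[r]
    # sample classes: longitudinal retention within subjects
    sample_class = {}
    by_subject: dict[str, list[str]] = {}
    for sid in carriers:
        by_subject.setdefault(_subject_of(sid), []).append(sid)
    for subj in sorted(by_subject):
        sids = sorted(by_subject[subj])
        sample_class[sids[0]] = subject_class[subj]
        for extra in sids[1:]:
            if rng.random() < config.retention_prob:
                sample_class[extra] = subject_class[subj]
            else:
                sample_class[extra] = next_class
                next_class += 1
    return sample_class


def _subject_of(sample_id: str) -> str:
    return sample_id.rsplit("_T", 1)[0]


def _class_tree(
    class_ids: list[int], rng: np.random.Generator, scale: float
) -> tuple[dict[int, int], np.ndarray, float, str]:
    """Random binary backbone over strain classes.

    Returns the class -> matrix-index mapping, the class-to-class patristic
    matrix, the summed backbone branch length, and a newick skeleton whose
    tips are ``C<class>`` placeholders. Branch lengths are
    ``scale * (0.5 + Exp(1))``: the 0.5 floor keeps every between-class path
    at least one ``scale`` long, which (with short same-strain pendants)
    guarantees the bimodal separation.
    """
    n = len(class_ids)
    idx = {c: i for i, c in enumerate(class_ids)}
    D = np.zeros((n, n))
    # clusters: list of (member indices, depth-from-cluster-root array, newick)
    clusters = [([i], np.zeros(1), f"C{class_ids[i]}") for i in range(n)]
    total = 0.0
    while len(clusters) > 1:
        j = int(rng.integers(1, len(clusters)))
        i = int(rng.integers(0, j))
        mi, di, ni = clusters.pop(j)
        mj, dj, nj = clusters.pop(i)
        ei = scale * (0.5 + rng.exponential())
        ej = scale * (0.5 + rng.exponential())
        total += ei + ej
        for a, da in zip(mi, di):
            for b, db in zip(mj, dj):
                D[a, b] = D[b, a] = da + ei + db + ej
        clusters.append(
            (
                mj + mi,
                np.concatenate([dj + ej, di + ei]),
                f"({nj}:{ej:.12g},{ni}:{ei:.12g})",
            )
        )
    _, _, newick = clusters[0]
    return idx, D, total, newick


def build_sgb_tree(
    sgb_id: str,
    sample_class: dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    food_class: int | None = None,
    food_refs: list[str] | None = None,
) -> tuple[str, SGBDistanceSet]:
    """Newick string and matching nGD matrix for one SGB.

    Samples of the same strain class attach to one backbone tip with
    pendant lengths ~ Exp(``same_strain_scale``); food-reference leaves
    attach to the designated food class tip.
    """
    leaves = sorted(sample_class)
    extra = list(food_refs or [])
    classes = sorted(set(sample_class.values()) | ({food_class} if food_class is not None else set()))
    leaf_class = dict(sample_class)
    for ref in extra:
        leaf_class[ref] = food_class
    all_leaves = leaves + extra
    pend = rng.exponential(config.same_strain_scale, size=len(all_leaves))
    pend = np.maximum(pend, 1e-9)
    if len(classes) > 1:
        idx, Dc, backbone_total, backbone_newick = _class_tree(
            classes, rng, config.backbone_scale
        )
    else:
        idx, Dc, backbone_total = {classes[0]: 0}, np.zeros((1, 1)), 0.0
        backbone_newick = f"C{classes[0]}"
    ci = np.array([idx[leaf_class[l]] for l in all_leaves])
    mat = pend[:, None] + pend[None, :] + Dc[np.ix_(ci, ci)]
    np.fill_diagonal(mat, 0.0)
    total = backbone_total + float(pend.sum())
    # swap each class placeholder label for its leaf fan
    fans = {}
    for c in classes:
        members = [
            (l, pend[k]) for k, l in enumerate(all_leaves) if leaf_class[l] == c
        ]
        fan = ",".join(f"{l}:{p:.12g}" for l, p in members)
        fans[f"C{c}"] = f"({fan})"
    newick = _substitute_labels(backbone_newick, fans) + ";"
    ngd = mat / total
    dset = SGBDistanceSet(
        sgb_id=sgb_id,
        leaves=all_leaves,
        ngd=ngd,
        total_branch_length=total,
    )
    return newick, dset


def _substitute_labels(newick: str, fans: dict[str, str]) -> str:
    """Replace ``C<class>`` placeholder tips with their leaf-fan subtrees."""
    return re.sub(r"C\d+", lambda m: fans[m.group(0)], newick)


def generate_sgb_trees(
    cohort: pd.DataFrame, config: SimulationConfig, out_dir=None
) -> tuple[list[str], list[SGBDistanceSet], GroundTruth, pd.DataFrame | None]:
    """Per-SGB Newick trees (and matrices) with planted sharing.

    Returns (newick strings, distance sets, ground truth, snv-rate table).
    When ``out_dir`` is given, writes ``<sgb>.nwk`` files and the SNV table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    subjects = subject_table(cohort)
    classified = classify_pairs(subjects)
    newicks, dsets = [], []
    truth = GroundTruth({}, {}, {}, {})
    snv_rows = []
    for g in range(config.n_sgbs):
        sgb = f"SGB{g + 1:03d}"
        p_mi = float(config.sgb_transmissibility[g])
        carrier_subjects = subjects[
            rng.random(len(subjects)) < config.carriage_prob
        ]
        carriers = cohort[
            cohort["subject_id"].isin(carrier_subjects["subject_id"])
        ]["sample_id"].to_list()
        if len(carriers) < 3:
            logger.warning("%s: fewer than 3 carrier samples, skipped", sgb)
            continue
        sample_class = _plant_classes(
            carriers, carrier_subjects, classified, p_mi, config, rng
        )
        food_class = None
        food_refs: list[str] = []
        food_samples: set[str] = set()
        if rng.random() < config.food_sgb_prob:
            food_class = max(sample_class.values()) + 1
            food_refs = [f"FOODREF_{sgb}_{k + 1}" for k in range(config.n_food_refs)]
            food_subjects = [
                s
                for s in sorted({_subject_of(x) for x in carriers})
                if rng.random() < config.food_fraction
            ]
            for sid in carriers:
                if _subject_of(sid) in food_subjects:
                    sample_class[sid] = food_class
                    food_samples.add(sid)
            for sid in sorted(sample_class):
                origin = sid in food_samples
                for ref in food_refs:
                    rate = (
                        float(rng.uniform(0.0003, 0.0015))
                        if origin
                        else float(rng.uniform(0.005, 0.05))
                    )
                    snv_rows.append(
                        {"sgb_id": sgb, "id_a": sid, "id_b": ref, "snv_rate": rate}
                    )
        newick, dset = build_sgb_tree(
            sgb, sample_class, config, rng, food_class, food_refs
        )
        newicks.append(newick)
        dsets.append(dset)
        truth.sample_classes[sgb] = sample_class
        truth.food_samples[sgb] = food_samples
        truth.food_refs[sgb] = food_refs
        truth.planted_transmissibility[sgb] = p_mi
    snv = pd.DataFrame(snv_rows, columns=["sgb_id", "id_a", "id_b", "snv_rate"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for dset, nwk in zip(dsets, newicks):
            (out_dir / f"{dset.sgb_id}.nwk").write_text(nwk + "\n")
        snv.to_csv(out_dir / "snv_rates.tsv", sep="\t", index=False)
    return newicks, dsets, truth, snv


def bimodal_distance_suite(
    n_sgbs: int = 20,
    n_same: int = 60,
    n_unrelated: int = 600,
    seed: int = 0,
    same_scale: float = 0.004,
    overlap_fraction: float = 0.03,
):
    """Per-SGB synthetic nGD draws with overlapping bimodal structure.

    Same-individual values come from a tight exponential component near
    zero (longitudinal strain retention); unrelated values from a broad
    Beta(2, 3) bulk with a small fraction drawn from the same near-zero
    component (unrelated individuals who genuinely share a strain). Yields
    ``(sgb_id, same, unrelated)`` triples; clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    for g in range(n_sgbs):
        same = np.clip(rng.exponential(same_scale, size=n_same), 0.0, 1.0)
        overlap = rng.random(n_unrelated) < overlap_fraction
        unrelated = np.where(
            overlap,
            rng.exponential(same_scale, size=n_unrelated),
            rng.beta(2.0, 3.0, size=n_unrelated),
        )
        yield f"SGB{g + 1:03d}", same, np.clip(unrelated, 0.0, 1.0)


def generate_fmt_triads(
    config: SimulationConfig, out_dir=None
) -> tuple[pd.DataFrame, list[SGBDistanceSet], dict]:
    """FMT triads: donor (sampled twice), recipient pre-FMT and recipient
    post-FMT samples.

    Donor and post-FMT samples share a strain class with probability
    ``fmt_engraftment``; pre-FMT samples always carry their own strain; the
    two donor samples always share (longitudinal persistence), providing
    same-individual pairs from which a threshold can be calibrated
    independently of the donor/post validation pairs. The returned
    ``triad_of`` mapping covers donor and post samples only (the pre-FMT
    strain has no expected relation to the donor), ready for
    :func:`strainshare.calibration.fmt_validate`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    dsets = []
    triad_of: dict[str, str] = {}
    for g in range(config.fmt_sgbs):
        sgb = f"FMT_SGB{g + 1:03d}"
        sample_class = {}
        next_class = 0
        for t in range(config.fmt_triads):
            triad = f"T{t + 1:03d}"
            donor0 = f"{triad}_DONOR_T0"
            donor1 = f"{triad}_DONOR_T1"
            pre = f"{triad}_PRE"
            post = f"{triad}_POST"
            donor_class = next_class
            next_class += 1
            sample_class[donor0] = donor_class
            sample_class[donor1] = donor_class
            sample_class[pre] = next_class
            next_class += 1
            if rng.random() < config.fmt_engraftment:
                sample_class[post] = donor_class
            else:
                sample_class[post] = next_class
                next_class += 1
            triad_of[donor0] = triad
            triad_of[donor1] = triad
            triad_of[post] = triad
            if g == 0:
                rows.extend(
                    {"sample_id": s, "triad_id": triad, "role": r}
                    for s, r in (
                        (donor0, "donor"),
                        (donor1, "donor"),
                        (pre, "pre"),
                        (post, "post"),
                    )
                )
        if not sample_class:
            continue
        newick, dset = build_sgb_tree(sgb, sample_class, config, rng)
        dsets.append(dset)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / f"{sgb}.nwk").write_text(newick + "\n")
    return pd.DataFrame(rows), dsets, triad_of


def export_truth(truth: GroundTruth, path) -> None:
    """Write machine-readable planted truth (consumed only by tests)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    classes = pd.DataFrame(
        [
            {"sgb_id": sgb, "sample_id": sid, "strain_class": cls}
            for sgb, mapping in sorted(truth.sample_classes.items())
            for sid, cls in sorted(mapping.items())
        ]
    )
    classes.to_csv(path / "strain_classes.tsv", sep="\t", index=False)
    food = pd.DataFrame(
        [
            {"sgb_id": sgb, "sample_id": sid}
            for sgb, ids in sorted(truth.food_samples.items())
            for sid in sorted(ids)
        ],
        columns=["sgb_id", "sample_id"],
    )
    food.to_csv(path / "food_strains.tsv", sep="\t", index=False)
    transm = pd.DataFrame(
        sorted(truth.planted_transmissibility.items()),
        columns=["sgb_id", "planted_mother_infant_transmissibility"],
    )
    transm.to_csv(path / "planted_transmissibility.tsv", sep="\t", index=False)
    pairs = pd.concat(
        [truth.pair_table(sgb) for sgb in sorted(truth.sample_classes)],
        ignore_index=True,
    )
    pairs.to_csv(path / "pair_sharing.tsv", sep="\t", index=False)


def simulate_all(config: SimulationConfig, out_dir):
    """Generate a full suite (metadata, trees, SNV table, triads, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    cohort.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    newicks, dsets, truth, snv = generate_sgb_trees(
        cohort, config, out_dir=out_dir / "trees"
    )
    triads, fmt_dsets, triad_of = generate_fmt_triads(
        config, out_dir=out_dir / "fmt_trees"
    )
    triads.to_csv(out_dir / "fmt_triads.tsv", sep="\t", index=False)
    export_truth(truth, out_dir / "truth")
    with open(out_dir / "config.tsv", "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k}\t{v}\n")
    return cohort, dsets, truth, snv, triads, fmt_dsets, triad_of
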