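"""Stage orchestration: trees + metadata in, tidy TSV tables out.

Each stage is a plain function over in-memory objects plus a file-writing
wrapper; the CLI and the analysis scripts are thin shells over these. All
numeric defaults live in :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from strainshare import __version__
from strainshare.cohort import load_metadata, subject_table
from strainshare.phylo import NewickError, ngd_from_tree, scan_tree_directory
from strainshare.pairs import enumerate_unrelated_pairs, select_longitudinal_pairs
from strainshare import calibration, sharing, transmission

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, with their standard values."""

    trees_dir: str | None = None
    metadata: str | None = None
    snv_table: str | None = None
    out_dir: str = "strainshare_out"
    # calibration
    fp_bound: float = 0.05
    fallback_percentile: float = 3.0
    min_same_pairs: int = 50
    max_gap_days: int = 183
    unrelated_scope: str = "pooled"
    # sharing
    min_shared_sgbs: int = 10
    food_max_snv: float = 0.0015
    network_min_strains: int = 5
    network_min_species: int = 50
    # transmissibility
    min_potential_pooled: int = 10
    min_potential_dataset: int = 3
    alpha: float = 0.05
    t_min: float = 0.5
    seed: int = 0


def load_distance_sets(trees_dir, snv_table=None) -> list:
    """Read every ``<sgb>.nwk`` in a directory into nGD matrices; attach
    SNV-rate rows (long format, per SGB) when a table is supplied."""
    paths = scan_tree_directory(trees_dir)
    if not paths:
        raise FileNotFoundError(f"no .nwk trees found in {trees_dir}")
    snv = pd.read_csv(snv_table, sep="\t") if snv_table else None
    dsets = []
    for sgb, path in paths.items():
        try:
            dset = ngd_from_tree(path, sgb_id=sgb)
        except NewickError as exc:
            logger.warning("skipping %s: %s", sgb, exc)
            continue
        if snv is not None:
            sub = snv[snv["sgb_id"] == sgb][["id_a", "id_b", "snv_rate"]]
            dset.snv_rate = sub.reset_index(drop=True) if not sub.empty else None
        dsets.append(dset)
    return dsets


def build_pairsets(dsets, samples: pd.DataFrame, cfg: RunConfig) -> dict:
    """Per-SGB same-individual and unrelated calibration pair sets."""
    out = {}
    for dset in dsets:
        sample_leaves = [l for l in dset.leaves if not l.startswith("FOODREF_")]
        out[dset.sgb_id] = {
            "same_individual": select_longitudinal_pairs(
                samples, sample_leaves, max_gap_days=cfg.max_gap_days
            ),
            "unrelated": enumerate_unrelated_pairs(
                samples, sample_leaves, scope=cfg.unrelated_scope, seed=cfg.seed
            ),
        }
    return out


def stage_ngd(dsets, out_dir: Path) -> Path:
    """Write long-format nGD (and centred nGD) tables for all SGBs."""
    frames = []
    for dset in dsets:
        long = dset.to_long(centred=True)
        long.insert(0, "sgb_id", dset.sgb_id)
        frames.append(long)
    table = pd.concat(frames, ignore_index=True)
    path = out_dir / "ngd_long.tsv"
    table.to_csv(path, sep="\t", index=False)
    return path


def stage_calibrate(dsets, samples: pd.DataFrame, cfg: RunConfig):
    """Calibrate per-SGB thresholds from longitudinal vs unrelated pairs."""
    pairsets = build_pairsets(dsets, samples, cfg)
    body_sites = _sgb_body_sites(dsets, samples)
    thresholds = calibration.calibrate_all(
        dsets,
        pairsets,
        body_sites=body_sites,
        min_same_pairs=cfg.min_same_pairs,
        fp_bound=cfg.fp_bound,
        fallback_percentile=cfg.fallback_percentile,
    )
    return thresholds


def _sgb_body_sites(dsets, samples: pd.DataFrame) -> dict:
    site_of = dict(zip(samples["sample_id"], samples["body_site"]))
    out = {}
    for dset in dsets:
        sites = {site_of[l] for l in dset.leaves if l in site_of}
        out[dset.sgb_id] = "oral" if sites == {"oral"} else "gut"
    return out


def stage_share(dsets, thresholds, samples: pd.DataFrame, cfg: RunConfig):
    """Food exclusion, sharing calls, subject collapse, rates and networks."""
    thr_by_sgb = {t.sgb_id: t for t in thresholds}
    sample_ids = set(samples["sample_id"])
    sample_to_subject = dict(zip(samples["sample_id"], samples["subject_id"]))
    per_sgb_calls = {}
    per_sgb_profiles = {}
    excluded_by_sgb = {}
    for dset in dsets:
        thr = thr_by_sgb.get(dset.sgb_id)
        if thr is None:
            continue
        food_refs = [l for l in dset.leaves if l.startswith("FOODREF_")]
        excluded = sharing.flag_food_strains(
            dset.snv_rate, food_refs, max_snv=cfg.food_max_snv
        )
        excluded_by_sgb[dset.sgb_id] = excluded
        calls = sharing.call_sharing_events(
            dset, thr, excluded=excluded, sample_ids=sample_ids
        )
        per_sgb_calls[dset.sgb_id] = sharing.collapse_to_subjects(
            calls, sample_to_subject
        )
        per_sgb_profiles[dset.sgb_id] = sharing.subject_profiles(
            dset, sample_to_subject, excluded=excluded
        )
    counts = sharing.aggregate_subject_pairs(per_sgb_calls)
    counts = sharing.sharing_rate(counts, min_shared_sgbs=cfg.min_shared_sgbs)
    subjects = subject_table(samples)
    classified = sharing.classify_pairs(subjects)
    summaries = counts.merge(classified, on=["subject_a", "subject_b"], how="left")
    grouped = sharing.rate_by_relationship(summaries)
    network = sharing.build_sharing_network(
        counts, min_shared_strains=cfg.network_min_strains
    )
    return {
        "per_sgb_calls": per_sgb_calls,
        "per_sgb_profiles": per_sgb_profiles,
        "excluded": excluded_by_sgb,
        "pair_summaries": summaries,
        "grouped_rates": grouped,
        "network": network,
        "classified": classified,
        "subjects": subjects,
    }


def stage_transmissibility(share_out: dict, samples: pd.DataFrame, cfg: RunConfig):
    """Per-mode transmissibility with highly-transmitted flags and
    cross-dataset concordance."""
    classified = share_out["classified"]
    subjects = share_out["subjects"]
    per_sgb_calls = share_out["per_sgb_calls"]
    sgb_ids = sorted(per_sgb_calls)
    tables = []
    for mode in transmission.MODES:
        within, among = transmission.mode_eligible_pairs(classified, subjects, mode)
        pooled = transmission.transmissibility_table(
            sgb_ids, per_sgb_calls, within, among, mode, scope="all",
            min_potential=cfg.min_potential_pooled,
        )
        pooled = transmission.flag_highly_transmitted(
            pooled, alpha=cfg.alpha, t_min=cfg.t_min
        )
        tables.append(pooled)
        for dataset, _ in samples.groupby("dataset_id"):
            w = within[within["dataset_id"] == dataset]
            a = among[among["dataset_id"] == dataset] if "dataset_id" in among else among
            per_ds = transmission.transmissibility_table(
                sgb_ids, per_sgb_calls, w, a, mode, scope=str(dataset),
                min_potential=cfg.min_potential_dataset,
            )
            tables.append(per_ds)
    tables = [t for t in tables if not t.empty]
    table = pd.concat(tables, ignore_index=True)
    # concordance on mother-infant per-dataset transmissibility
    per_ds = table[(table["mode"] == "mother_infant") & (table["scope"] != "all")]
    wide = per_ds.pivot_table(
        index="sgb_id", columns="scope", values="transmissibility", aggfunc="first",
        dropna=False,
    )
    concordance = transmission.dataset_concordance(wide, min_sgbs=cfg.min_potential_pooled)
    return table, concordance


def stage_validate_fmt(fmt_dsets, triads: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Calibrate a threshold per FMT SGB from donor longitudinal pairs vs
    cross-triad pairs, then score donor/post engraftment detection."""
    donor = triads[triads["role"] == "donor"]
    triad_of_all = dict(zip(triads["sample_id"], triads["triad_id"]))
    validation_map = dict(
        zip(
            triads.loc[triads["role"] != "pre", "sample_id"],
            triads.loc[triads["role"] != "pre", "triad_id"],
        )
    )
    rows = []
    for dset in fmt_dsets:
        same, unrel = [], []
        donor_ids = [l for l in dset.leaves if l in set(donor["sample_id"])]
        by_triad: dict[str, list] = {}
        for d in donor_ids:
            by_triad.setdefault(triad_of_all[d], []).append(d)
        firsts = {t: sorted(ds)[0] for t, ds in by_triad.items()}
        for t, ds in by_triad.items():
            ds = sorted(ds)
            for i in range(len(ds)):
                for j in range(i + 1, len(ds)):
                    same.append(dset.distance(ds[i], ds[j]))
        f = sorted(firsts.values())
        for i in range(len(f)):
            for j in range(i + 1, len(f)):
                unrel.append(dset.distance(f[i], f[j]))
        thr = calibration.youden_threshold(
            same, unrel, fp_bound=cfg.fp_bound, sgb_id=dset.sgb_id
        )
        val = calibration.fmt_validate(dset, thr, validation_map)
        rows.append(
            {
                "sgb_id": dset.sgb_id,
                "threshold_ngd": thr.threshold_ngd,
                "tp": val.tp,
                "fp": val.fp,
                "tn": val.tn,
                "fn": val.fn,
                "recall": val.recall,
                "precision": val.precision,
                "f_score": val.f_score,
            }
        )
    out = pd.DataFrame(rows)
    for col in ("recall", "precision", "f_score"):
        vals = out[col].dropna()
        logger.info(
            "FMT %s: median %.3f IQR [%.3f, %.3f]",
            col,
            vals.median() if len(vals) else float("nan"),
            vals.quantile(0.25) if len(vals) else float("nan"),
            vals.quantile(0.75) if len(vals) else float("nan"),
        )
    return out


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(cfg: RunConfig, out_dir: Path, inputs: list) -> Path:
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {str(p): _hash_file(p) for p in inputs if p and Path(p).is_file()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_all(cfg: RunConfig) -> dict:
    """Chain ngd -> calibrate -> share -> transmissibility on files; write
    every output TSV plus a run manifest under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        samples = load_metadata(cfg.metadata)
        dsets = load_distance_sets(cfg.trees_dir, cfg.snv_table)
        written.append(stage_ngd(dsets, out_dir))
        thresholds = stage_calibrate(dsets, samples, cfg)
        thr_frame = calibration.thresholds_to_frame(thresholds)
        p = out_dir / "thresholds.tsv"
        thr_frame.to_csv(p, sep="\t", index=False)
        written.append(p)
        share_out = stage_share(dsets, thresholds, samples, cfg)
        events = pd.concat(
            [df for df in share_out["per_sgb_calls"].values()], ignore_index=True
        )
        for name, frame in (
            ("sharing_events.tsv", events),
            ("pair_summaries.tsv", share_out["pair_summaries"]),
            ("grouped_rates.tsv", share_out["grouped_rates"]),
            ("network_edges.tsv", share_out["network"]),
        ):
            p = out_dir / name
            frame.to_csv(p, sep="\t", index=False)
            written.append(p)
        transm, concord = stage_transmissibility(share_out, samples, cfg)
        for name, frame in (
            ("transmissibility.tsv", transm),
            ("concordance.tsv", concord),
        ):
            p = out_dir / name
            frame.to_csv(p, sep="\t", index=False)
            written.append(p)
        written.append(
            write_manifest(cfg, out_dir, [cfg.metadata, cfg.snv_table])
        )
    except Exception:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
    return {
        "thresholds": thresholds,
        "share": share_out,
        "transmissibility": transm,
        "concordance": concord,
        "outputs": written,
    }
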