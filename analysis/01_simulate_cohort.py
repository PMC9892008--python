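#!/usr/bin/env python
"""Generate the default synthetic cohort used by the downstream analyses.

Two populations (datasets) of 20 households across 4 villages each, with
mothers, fathers, offspring (including infants and the occasional twin
pair), longitudinal resampling of 80% of subjects within 183 days, 20 SGBs
with planted strain sharing, food-origin strains and FMT triads. Writes the
suite (metadata, per-SGB Newick trees, SNV-rate table, triad labels,
planted truth) under results/sim/.
"""

from pathlib import Path

from strainshare.simulate import SimulationConfig, simulate_all

OUT = Path("results/sim")
SEED = 17


def main() -> None:
    config = SimulationConfig(seed=SEED)
    cohort, dsets, truth, snv, triads, fmt_dsets, triad_of = simulate_all(
        config, OUT
    )
    n_subj = cohort["subject_id"].nunique()
    print(f"cohort: {len(cohort)} samples from {n_subj} subjects "
          f"in {cohort['dataset_id'].nunique()} datasets")
    print(f"trees: {len(dsets)} SGBs under {OUT/'trees'}; "
          f"{sum(bool(v) for v in truth.food_samples.values())} SGBs with "
          f"planted food-origin strains")
    print(f"FMT: {triads['triad_id'].nunique() if not triads.empty else 0} triads, "
          f"{len(fmt_dsets)} SGBs under {OUT/'fmt_trees'}")


if __name__ == "__main__":
    main()
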