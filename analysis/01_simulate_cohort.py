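#!/usr/bin/env python
"""Simulate the study-scale cohort the downstream analyses run on.

Emits, under results/cohort/: CNV segment calls for 70 sporadic cases
(51 male / 19 female) and 605 controls (382 / 223), three two-affected
families with a shared chr21 duplication, the genome model, and the planted
truth.  Planted structure: a male-case X enrichment of large CNVs
(odds multiplier 2.5), a case-enriched deletion at the GSTM locus on 1p13.3,
and a case-enriched duplication at the TRPM2 locus on 21q22.3.
"""

from pathlib import Path

from coacnv.io import write_genome, write_json, write_samples, write_segments
from coacnv.model import Direction, GenomeModel
from coacnv.simulate import (
    FamilySpec,
    PlantedLocus,
    SimulationConfig,
    simulate_cohort,
    simulate_families,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20260922

cfg = SimulationConfig(
    seed=SEED,
    x_large_enrichment_or=2.5,
    outlier_fraction=0.02,
    planted_loci=[
        # deletion carried by ~60% of cases vs ~17% of controls (1p13.3 scale)
        PlantedLocus("chr1", 110_224_383, 110_242_952, Direction.loss, 0.61, 0.17),
        # duplication carried by ~9% of cases vs ~0.2% of controls (21q22.3 scale)
        PlantedLocus("chr21", 45_827_392, 45_840_419, Direction.gain, 0.09, 0.002),
    ],
)

fam_cfg = SimulationConfig(
    seed=SEED + 1,
    count_model=(8.0, 8.0),
    families=[
        FamilySpec(f"F{i + 1}", n_affected=2, n_unaffected=2,
                   shared_segments=(("chr21", 45_812_754, 45_827_392, Direction.gain),))
        for i in range(3)
    ],
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = GenomeModel()
    segments, samples, truth = simulate_cohort(cfg, genome)
    fam_segments, fam_samples, fam_truth = simulate_families(fam_cfg, genome)

    write_segments(segments + fam_segments, OUT / "segments.tsv")
    write_samples(samples + fam_samples, OUT / "samples.tsv")
    write_genome(genome, OUT / "genome.yaml")
    write_json(
        {
            "seed": SEED,
            "theta": truth.theta,
            "outliers": truth.outlier_ids,
            "planted_carriers": truth.planted_carriers,
            "family_shared_cores": fam_truth.shared_cores,
        },
        OUT / "truth.json",
    )
    n_case_carriers = {
        k: sum(1 for s in v if s.startswith("CA"))
        for k, v in truth.planted_carriers.items()
    }
    print(f"cohort: {len(samples)} sporadic samples, {len(segments)} segments")
    print(f"families: {len(fam_samples)} members, {len(fam_segments)} segments")
    print(f"planted case carriers: {n_case_carriers}")
    print(f"count outliers planted: {len(truth.outlier_ids)}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
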