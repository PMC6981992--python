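#!/usr/bin/env python
"""Simulate a study-shaped accident dataset from a known ground truth.

The original 287-case matrix was never published, so every downstream
analysis here runs on a synthetic dataset whose marginals mirror the study
shape: 287 cases split ~191/39/33/24 across fall (F), collapse (C),
struck-by (S) and lifting (L), 37 binary unsafe-behavior indicators with
sparse background occurrence, and planted per-type signature behaviors.
Writes cases.csv (Yes/No matrix), chains.csv (time-ordered code sequences)
and truth.json (the generating model + planted sets) under
results/simulated/.
"""
from pathlib import Path

from accident_bn.catalog_io import AccidentCase, write_cases
from accident_bn.synthetic_data import GeneratorConfig, build_ground_truth, sample_cases, sample_chains

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "simulated"
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(seed=SEED)
    truth = build_ground_truth(config)
    matrix = sample_cases(truth, config.n_cases, seed=SEED + 1)
    chains = sample_chains(matrix, seed=SEED + 2)

    matrix.to_csv(OUT / "cases.csv")
    truth.save(OUT / "truth.json")
    write_cases(
        OUT / "chains.csv",
        [AccidentCase(c.case_id, c.accident_type, c.codes) for c in chains],
    )

    counts = matrix.class_counts()
    print(f"sampled {matrix.n_cases} cases, class counts {counts}")
    print(f"{len(chains)} chains (cases with >= 2 behaviors)")
    print(f"planted signature sets: {dict(truth.planted_sets)}")
    print(f"wrote cases.csv, chains.csv, truth.json to {OUT}")


if __name__ == "__main__":
    main()
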