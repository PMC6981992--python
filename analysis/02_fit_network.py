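#!/usr/bin/env python
"""Fit the tree-augmented naive Bayes network to the simulated chains.

Replays the modelling steps on the simulated data: load the case file,
drop single-behavior cases, extract directed chains, binarize them over the
behaviors actually in use, score all behavior pairs by class-conditional
mutual information, keep the maximum-weight spanning tree, and estimate
CPTs with the 0.5-pseudocount small-cell adjustment.  Also prints the
re-rooted accident-type conditional for one root behavior (the normalized
analog of the study's root-node CPT report).  Writes model.json and
structure.csv under results/.
"""
from pathlib import Path

import pandas as pd

from accident_bn.catalog_io import (
    behaviors_in_use,
    chains_to_matrix,
    default_catalog,
    extract_chains,
    filter_cases,
    load_cases,
)
from accident_bn.inference import class_posterior
from accident_bn.tan_model import SmoothingPolicy, fit_tan, reroot

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"


def main() -> None:
    cases = load_cases(SIM / "chains.csv", default_catalog())
    retained, excluded = filter_cases(cases)
    chains = extract_chains(retained)
    in_use = behaviors_in_use(chains)
    matrix = chains_to_matrix(chains, in_use)
    print(
        f"{len(chains)} chains over {len(in_use)} behaviors in use "
        f"({len(excluded)} case(s) excluded)"
    )

    model = fit_tan(matrix, SmoothingPolicy(0.5))
    model.save(OUT / "model.json")
    edges = pd.DataFrame(
        [(u, v, w) for (u, v), w in model.structure.edge_weights.items()],
        columns=["behavior_a", "behavior_b", "cmi_nats"],
    ).sort_values("cmi_nats", ascending=False)
    edges.to_csv(OUT / "structure.csv", index=False)

    prior = (class_posterior(model, {}) * 100).round(1)
    print(f"no-evidence accident posteriors (%): {prior.to_dict()}")
    print(f"strongest tree edges:\n{edges.head(5).to_string(index=False)}")

    root = "B2" if "B2" in model.features else model.features[0]
    view = reroot(model, root)
    print(f"P(accident type | {root}), rows normalized:")
    print(view.class_given_root.round(3).to_string())
    view.class_given_root.to_csv(OUT / f"class_given_{root}.csv", index_label="root_state")
    print(f"wrote model.json, structure.csv to {OUT}")


if __name__ == "__main__":
    main()
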