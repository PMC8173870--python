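#!/usr/bin/env python
"""Infer RBP regulators of the AS clusters from expression profiles.

Filters the simulated RBP cpm table (cpm ≥ 5 in ≥ 1/3 of samples,
CV ≥ 0.2), scores each surviving profile against every cluster
centroid and its negative, and calls regulators at membership ≥ 0.3.
Scores calls against the planted regulator truth.
"""

import json
import os

import numpy as np
import pandas as pd

import splicedyn.synthetic_data as sd
from splicedyn.core_io import read_expr_table, read_sample_map
from splicedyn.regulator_inference import (
    filter_expressed_variable,
    infer_regulators,
)
from splicedyn.temporal_clustering import ClusterModel, scale_profiles

HERE = os.path.dirname(__file__)
DATA = os.path.join(HERE, "..", "results", "data")
OUT = os.path.join(HERE, "..", "results")


def main() -> None:
    samples = read_sample_map(f"{DATA}/timecourse_samples.tsv")
    expr = read_expr_table(f"{DATA}/rbp_cpm.tsv", samples, unit="cpm")
    truth = pd.read_csv(f"{DATA}/rbp_truth.tsv", sep="\t", index_col=0)

    with open(f"{OUT}/cluster_model.json") as fh:
        saved = json.load(fh)
    model = ClusterModel(
        k=saved["k"], m=saved["m"],
        centroids=np.array(saved["centroids"]),
        memberships=np.zeros((1, saved["k"])),
        iterations=saved["iterations"], objective=saved["objective"])

    filtered = filter_expressed_variable(expr)
    scaled, _ = scale_profiles(filtered.values)
    calls = infer_regulators(scaled, model)

    mapping = sd.match_centroids(model.centroids,
                                 sd.default_trajectory_specs())
    rows = [{"rbp_id": c.rbp_id, "cluster": c.cluster_id,
             "matched_planted_cluster": mapping.get(c.cluster_id, ""),
             "polarity": c.polarity, "membership": round(c.membership, 4)}
            for c in calls]
    pd.DataFrame(rows).to_csv(f"{OUT}/regulator_calls.tsv", sep="\t",
                              index=False)

    pred = {(c.rbp_id, mapping.get(c.cluster_id, ""), c.polarity)
            for c in calls}
    want = {(r, row["cluster_id"], row["role"])
            for r, row in truth.iterrows()
            if row["role"] in ("positive", "negative")}
    tp = len(pred & want)
    print(f"{filtered.values.shape[0]} of {expr.values.shape[0]} RBPs pass "
          f"the expression/variation filters; {len(calls)} regulator calls")
    print(f"precision {tp / len(pred):.3f}, recall {tp / len(want):.3f} "
          f"vs {len(want)} planted regulators")


if __name__ == "__main__":
    main()
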