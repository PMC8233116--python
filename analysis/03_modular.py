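"""Modular-network study: within- vs between-group false positives and
modularity fidelity (scaled-down: 5 groups of 10 with out-degree 5, so 50% initial
within-group density, T = 10,000).

Finding: spurious links concentrate *within* modules at low between-group
density for bivariate methods (clustered motifs inflate pairwise TE/MI),
while multivariate TE keeps false positives negligible and tracks the
linearly decreasing modularity of the planted partition.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tenet import dynamics, infer, netgen, netmetrics
from tenet.infer import InferenceConfig, derive_seed

OUT = Path(__file__).resolve().parents[1] / "results" / "modular"


def main() -> None:
    rows = []
    for between in (0, 2, 5):
        for rep in range(3):
            net = netgen.make_modular(
                50, 5, 5, between, rng_seed=derive_seed(3, "net", between, rep)
            )
            coupling = netgen.assign_weights(
                net, cross_weight=0.08, self_weight=0.08
            )
            ts = dynamics.simulate_var(
                coupling, 10000, rng_seed=derive_seed(3, "sim", between, rep)
            )
            q_true = netmetrics.modularity(net, net.partition)
            for algo in ("biv_mi", "biv_te", "multi_te"):
                inferred = infer.infer(
                    ts,
                    InferenceConfig(
                        algorithm=algo,
                        seed=derive_seed(3, "inf", between, rep, algo),
                    ),
                )
                fp = netmetrics.within_between_fp(inferred, net, net.partition)
                rows.append(
                    {
                        "links_between_per_node": between,
                        "repetition": rep,
                        "algorithm": algo,
                        "q_true": q_true,
                        "q_inferred": netmetrics.modularity(
                            inferred, net.partition
                        ),
                        **fp,
                    }
                )
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "results.tsv", sep="\t", index=False)
    summary = (
        table.groupby(["links_between_per_node", "algorithm"])
        .mean(numeric_only=True)
        .drop(columns="repetition")
        .reset_index()
    )
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote {OUT}/results.tsv and {OUT}/summary.tsv")


if __name__ == "__main__":
    main()
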