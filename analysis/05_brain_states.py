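"""Brain-state clustering of windowed connectivity and state metrics.

Pools all subjects' windowed Fisher-z patterns (cached by step 04),
selects the number of states k by the elbow of the within/between cluster
validity index over k = 2..6, fits L1 (Manhattan-distance) k-means with
multiple restarts, and computes the four per-subject metrics (frequency,
mean dwell time, number of transitions, mean intertransition time).
Compares them between groups (nonparametric MANOVA for the per-state
metrics, Kruskal-Wallis for the scalar ones). Writes tables under
results/states/.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dynconn import io as dio
from dynconn.group_stats import kruskal_wallis, nonparametric_manova
from dynconn.states import cohort_state_analysis
from dynconn.windows import WindowedConnectivityStack


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--design", default="results/data/design.tsv")
    ap.add_argument("--cache", default="scratch/window_stacks")
    ap.add_argument("--out", default="results/states")
    ap.add_argument("--length", type=int, default=22)
    ap.add_argument("--k", type=int, default=None)
    ap.add_argument("--restarts", type=int, default=500)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    design = dio.read_design(args.design)
    vecs, ids = [], []
    for sid in design.subject_id:
        z = np.load(pathlib.Path(args.cache) / f"{sid}_L{args.length}.npy")
        stack = WindowedConnectivityStack(z, np.arange(z.shape[0]), sid)
        vecs.append(stack.upper_triangle_vectors())
        ids.append(sid)

    model, metrics, indices = cohort_state_analysis(
        vecs, ids, k_range=(2, 6), k=args.k,
        n_restarts=args.restarts, seed=args.seed,
    )
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(out / f"state_metrics_L{args.length}.tsv", sep="\t", index=False)
    np.savetxt(out / f"state_centroids_L{args.length}.tsv", model.centroids,
               delimiter="\t")
    if indices:
        pd.DataFrame(
            {"k": list(indices), "validity_index": list(indices.values())}
        ).to_csv(out / "validity_by_k.tsv", sep="\t", index=False)

    groups = design.set_index("subject_id").group
    freq = metrics.pivot(index="subject_id", columns="state", values="frequency")
    stat, p = nonparametric_manova(freq.to_numpy(), groups.loc[freq.index].to_numpy(),
                                   n_permutations=5000, seed=args.seed)
    ntr = metrics.groupby("subject_id").n_transitions.first()
    H, p_kw = kruskal_wallis(ntr.to_numpy(float), groups.loc[ntr.index].to_numpy())

    print(f"selected k={model.k}"
          + (f" by elbow over {{2..6}}: {indices}" if indices else " (fixed)"))
    print(f"state frequencies (pooled): "
          f"{np.round(np.bincount(model.labels)[1:] / len(model.labels), 3)}")
    print(f"group test, state frequency profile (rank MANOVA): "
          f"pillai={stat:.3f}, p={p:.4f}")
    print(f"group test, n transitions (Kruskal-Wallis): H={H:.3f}, p={p_kw:.4f}")


if __name__ == "__main__":
    main()
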