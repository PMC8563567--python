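"""Group comparisons of variability, state and LEiDA measures.

Collects the scalar dynamic-connectivity measures produced by the earlier
steps and runs the nonparametric battery: Kruskal-Wallis across the three
groups per measure, and (when a medication flag is present in the design)
Mann-Whitney U comparisons within the MCI-LB group. Writes a combined
table under results/stats/.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dynconn import io as dio
from dynconn.group_stats import kruskal_wallis, medication_subgroup_compare


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--design", default="results/data/design.tsv")
    ap.add_argument("--results", default="results")
    ap.add_argument("--length", type=int, default=22)
    args = ap.parse_args()

    res = pathlib.Path(args.results)
    design = dio.read_design(args.design)
    groups = design.set_index("subject_id").group

    measures = {}
    var_path = res / "sliding_window" / f"variability_L{args.length}.tsv"
    if var_path.exists():
        var = pd.read_csv(var_path, sep="\t").set_index("subject_id")
        measures["global_mean_sd"] = var.global_mean_sd
    fcd_path = res / "leida" / "fcd_similarity.tsv"
    if fcd_path.exists():
        fcd = pd.read_csv(fcd_path, sep="\t").set_index("subject_id")
        measures["mean_fcd_similarity"] = fcd.mean_fcd_similarity
    sm_path = res / "states" / f"state_metrics_L{args.length}.tsv"
    if sm_path.exists():
        sm = pd.read_csv(sm_path, sep="\t")
        measures["n_transitions"] = sm.groupby("subject_id").n_transitions.first()
        measures["mean_intertransition_time"] = (
            sm.groupby("subject_id").mean_intertransition_time.first()
        )

    rows = []
    for name, series in measures.items():
        vals = series.dropna()
        H, p = kruskal_wallis(vals.to_numpy(float), groups.loc[vals.index].to_numpy())
        rows.append({"measure": name, "test": "kruskal_wallis", "stat": H, "p": p})
    table = pd.DataFrame(rows)

    out = res / "stats"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "group_statistics.tsv", sep="\t", index=False)
    print(table.round(4).to_string(index=False))

    if "medication" in design.columns:
        metrics = pd.DataFrame(measures).reset_index()
        lb = design[design.group == "MCI-LB"]
        med = medication_subgroup_compare(
            metrics[metrics.subject_id.isin(lb.subject_id)], lb
        )
        med.to_csv(out / "medication_subgroup.tsv", sep="\t", index=False)
        print("\nmedication subgroup (Mann-Whitney U):")
        print(med.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
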