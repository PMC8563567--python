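"""Post-process the simulated time courses: detrend and despike.

Removes polynomial trends up to cubic order and replaces spike outliers by
cubic-spline interpolation, mirroring the post-extraction cleanup applied
to network time courses before connectivity analysis. Writes prepared
matrices and an outlier report under results/prepared/.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dynconn import io as dio
from dynconn.prep import despike, detrend_polynomial


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/prepared")
    ap.add_argument("--tr", type=float, default=2.072)
    args = ap.parse_args()

    data = pathlib.Path(args.data)
    out = pathlib.Path(args.out)
    (out / "timecourses").mkdir(parents=True, exist_ok=True)
    design = dio.read_design(data / "design.tsv")

    spikes = []
    for sid in design.subject_id:
        tc = dio.read_timecourses(data / "timecourses" / f"{sid}.txt", args.tr, sid)
        tc = detrend_polynomial(tc, max_order=3)
        tc, mask = despike(tc)
        dio.write_timecourses(tc, out / "timecourses" / f"{sid}.txt")
        for t, c in zip(*mask.nonzero()):
            spikes.append({"subject_id": sid, "column": c + 1, "volume_index": t + 1})

    report = pd.DataFrame(spikes, columns=["subject_id", "column", "volume_index"])
    report.to_csv(out / "outlier_report.tsv", sep="\t", index=False)
    print(f"prepared {len(design)} subjects; {len(report)} spike samples interpolated")


if __name__ == "__main__":
    main()
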