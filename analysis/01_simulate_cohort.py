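"""Simulate a three-group synthetic cohort of network time courses.

Generates BOLD-like signals for HC / MCI-AD / MCI-LB groups (12 subjects
each by default) with three planted covariance states switching as a
Markov chain at TR resolution, and a planted slowing of state-2 dynamics
in the MCI-LB group. Writes one delimited matrix per subject plus the
design and ground-truth tables under results/data/.
"""

import argparse
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dynconn import io as dio
from dynconn.synthetic import SyntheticSpec, generate_cohort


def block_covariance(n, blocks, r=0.6):
    C = np.eye(n)
    for start, end in blocks:
        block = slice(start, end)
        C[block, block] = r
        np.fill_diagonal(C[block, block], 1.0)
    return C


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/data")
    ap.add_argument("--subjects-per-group", type=int, default=12)
    ap.add_argument("--volumes", type=int, default=290)
    ap.add_argument("--networks", type=int, default=10)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    n = args.networks
    covs = [
        block_covariance(n, [(0, n // 2)]),
        block_covariance(n, [(n // 2, n)]),
        block_covariance(n, [(n // 5, n - n // 5)]),
    ]
    P = np.full((3, 3), 0.025)
    np.fill_diagonal(P, 0.95)
    # MCI-LB dwells longer in state 2
    P_lb = P.copy()
    P_lb[1] = [0.01, 0.98, 0.01]

    spec = SyntheticSpec(
        n_subjects_per_group=args.subjects_per_group,
        state_covariances=covs,
        transition_matrix=P,
        groups=("HC", "MCI-AD", "MCI-LB"),
        n_volumes=args.volumes,
        observation_noise_sd=0.2,
        group_effects={"MCI-LB": {"transition_matrix": P_lb}},
        seed=args.seed,
    )
    subjects, design, truths = generate_cohort(spec)

    out = pathlib.Path(args.out)
    (out / "timecourses").mkdir(parents=True, exist_ok=True)
    for tc in subjects:
        dio.write_timecourses(tc, out / "timecourses" / f"{tc.subject_id}.txt")
    dio.write_design(design, out / "design.tsv")
    dio.write_truth(truths, out / "truth.tsv")

    counts = {g: int(c) for g, c in design.group.value_counts().items()}
    print(f"wrote {len(subjects)} subjects ({counts}) to {out}")
    print(f"volumes={args.volumes}, networks={n}, TR={spec.tr_seconds}s, seed={args.seed}")


if __name__ == "__main__":
    main()
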