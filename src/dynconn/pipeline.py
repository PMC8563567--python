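"""End-to-end pipeline driver over a directory of time-course files.

Stage order mirrors the analysis flow: preparation -> static netmats ->
sliding-window connectivity -> brain states -> LEiDA -> group statistics.
Each run writes a manifest (JSON) listing every output file with its
checksum, the full configuration snapshot and all seeds, so any run can be
reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from dynconn import io as dio
from dynconn.group_stats import kruskal_wallis, nonparametric_manova
from dynconn.leida import leida_cohort_analysis
from dynconn.prep import despike, detrend_polynomial
from dynconn.states import cohort_state_analysis
from dynconn.static_conn import permutation_group_test, subject_netmat
from dynconn.windows import (
    TaperSpec,
    connectivity_variability,
    residualize_edges,
    subject_connectivity_stack,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a pipeline run needs, recorded verbatim in the manifest."""

    timecourse_dir: str
    design_file: str
    output_dir: str
    tr_seconds: float = 2.072
    window_length_tr: int = 22
    gaussian_sigma_tr: float = 3.0
    step_tr: int = 1
    glasso_lambda: float | str = "cv"
    cv_folds: int = 20
    k: int | None = None
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 500
    drop_edges: int = 1
    n_permutations: int = 500
    seed: int = 0
    stages: tuple[str, ...] = ("prep", "netmats", "windows", "states", "leida", "stats")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the results manifest."""
    os.makedirs(config.output_dir, exist_ok=True)
    outputs: list[str] = []
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages_completed": [],
    }

    def _save_df(df: pd.DataFrame, name: str) -> str:
        path = os.path.join(config.output_dir, name)
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        return path

    design = dio.read_design(config.design_file)
    files = sorted(
        f for f in os.listdir(config.timecourse_dir) if f.endswith((".txt", ".tsv", ".csv"))
    )
    subjects = {}
    for sid in design["subject_id"]:
        match = [f for f in files if os.path.splitext(f)[0] == sid]
        if not match:
            raise FileNotFoundError(f"no time-course file for subject {sid}")
        subjects[sid] = dio.read_timecourses(
            os.path.join(config.timecourse_dir, match[0]), config.tr_seconds, sid
        )
    ids = list(design["subject_id"])
    tcs = [subjects[s] for s in ids]
    age = design["age"].to_numpy(dtype=float)
    sex = (design["sex"].to_numpy() == design["sex"].iloc[0]).astype(float)
    groups = design["group"].to_numpy()

    try:
        if "prep" in config.stages:
            prepared = []
            spikes = []
            for tc in tcs:
                d = detrend_polynomial(tc, max_order=3)
                d, mask = despike(d)
                prepared.append(d)
                for t_idx, c_idx in zip(*np.nonzero(mask)):
                    spikes.append(
                        {"subject_id": tc.subject_id, "column": c_idx + 1, "volume_index": t_idx + 1}
                    )
            tcs = prepared
            _save_df(pd.DataFrame(spikes, columns=["subject_id", "column", "volume_index"]),
                     "outlier_report.tsv")
            manifest["stages_completed"].append("prep")

        if "netmats" in config.stages:
            netmats = [subject_netmat(tc) for tc in tcs]
            if len(pd.unique(groups)) >= 2:
                nm_table = permutation_group_test(
                    netmats, design, n_permutations=config.n_permutations, seed=config.seed
                )
                _save_df(nm_table, "netmat_group_tests.tsv")
            manifest["stages_completed"].append("netmats")

        taper = TaperSpec(config.window_length_tr, config.gaussian_sigma_tr, config.step_tr)
        stacks = None
        if "windows" in config.stages:
            stacks = [
                subject_connectivity_stack(
                    tc, taper, lam=config.glasso_lambda, n_folds=config.cv_folds
                )
                for tc in tcs
            ]
            var_rows = []
            global_sds = []
            for st in stacks:
                v = connectivity_variability(st)
                global_sds.append(v.global_mean_sd)
                iu = np.triu_indices(st.n_networks, k=1)
                for i, j in zip(*iu):
                    var_rows.append(
                        {
                            "subject_id": st.subject_id,
                            "edge_i": i + 1,
                            "edge_j": j + 1,
                            "sd": v.per_edge_sd[i, j],
                        }
                    )
            var_df = pd.DataFrame(var_rows)
            var_df["sd"] = residualize_edges(
                var_df.pivot(index="subject_id", columns=["edge_i", "edge_j"], values="sd")
                .loc[ids]
                .to_numpy(),
                age,
                sex,
            ).ravel() if len(ids) > 2 else var_df["sd"]
            _save_df(var_df, f"variability_L{config.window_length_tr}.tsv")
            _save_df(
                pd.DataFrame({"subject_id": ids, "global_mean_sd": global_sds}),
                f"variability_global_L{config.window_length_tr}.tsv",
            )
            manifest["stages_completed"].append("windows")

        if "states" in config.stages and stacks is not None:
            vecs = [st.upper_triangle_vectors() for st in stacks]
            model, metrics, _ = cohort_state_analysis(
                vecs, ids, k_range=(config.k_min, config.k_max), k=config.k,
                n_restarts=config.n_restarts, seed=config.seed,
            )
            metrics = metrics.rename(columns={"mean_dwell_time": "mean_dwell_tr",
                                              "mean_intertransition_time": "mean_intertransition_tr"})
            _save_df(metrics, f"state_metrics_L{config.window_length_tr}.tsv")
            np.savetxt(os.path.join(config.output_dir, "state_centroids.tsv"),
                       model.centroids, delimiter="\t")
            outputs.append(os.path.join(config.output_dir, "state_centroids.tsv"))
            manifest["k_selected_windows"] = model.k
            manifest["stages_completed"].append("states")

        if "leida" in config.stages:
            lmodel, lmetrics, fcd_means = leida_cohort_analysis(
                tcs, k_range=(config.k_min, config.k_max), k=config.k,
                drop_edges=config.drop_edges, n_restarts=config.n_restarts, seed=config.seed,
            )
            _save_df(lmetrics, "leida_state_metrics.tsv")
            _save_df(fcd_means, "leida_fcd_similarity.tsv")
            manifest["k_selected_leida"] = lmodel.k
            manifest["stages_completed"].append("leida")

        if "stats" in config.stages and len(pd.unique(groups)) >= 2:
            stat_rows = []
            gsd_path = os.path.join(
                config.output_dir, f"variability_global_L{config.window_length_tr}.tsv"
            )
            if os.path.exists(gsd_path):
                gsd = pd.read_csv(gsd_path, sep="\t").set_index("subject_id").loc[ids]
                H, p = kruskal_wallis(gsd["global_mean_sd"].to_numpy(), groups)
                stat_rows.append({"measure": "global_mean_sd", "test": "kruskal_wallis",
                                  "stat": H, "p": p})
            fcd_path = os.path.join(config.output_dir, "leida_fcd_similarity.tsv")
            if os.path.exists(fcd_path):
                fcd = pd.read_csv(fcd_path, sep="\t").set_index("subject_id").loc[ids]
                H, p = kruskal_wallis(fcd["mean_fcd_similarity"].to_numpy(), groups)
                stat_rows.append({"measure": "mean_fcd_similarity", "test": "kruskal_wallis",
                                  "stat": H, "p": p})
            sm_path = os.path.join(
                config.output_dir, f"state_metrics_L{config.window_length_tr}.tsv"
            )
            if os.path.exists(sm_path):
                sm = pd.read_csv(sm_path, sep="\t")
                freq = sm.pivot(index="subject_id", columns="state", values="frequency").loc[ids]
                stat, p = nonparametric_manova(
                    freq.to_numpy(), groups, n_permutations=min(config.n_permutations, 5000),
                    seed=config.seed,
                )
                stat_rows.append({"measure": "state_frequency", "test": "rank_manova",
                                  "stat": stat, "p": p})
                ntr = sm.groupby("subject_id")["n_transitions"].first().loc[ids]
                H, p = kruskal_wallis(ntr.to_numpy(dtype=float), groups)
                stat_rows.append({"measure": "n_transitions", "test": "kruskal_wallis",
                                  "stat": H, "p": p})
            _save_df(pd.DataFrame(stat_rows), "group_statistics.tsv")
            manifest["stages_completed"].append("stats")
    except Exception as exc:
        manifest["error"] = f"stage failure: {exc}"
        manifest["outputs"] = [
            {"path": p, "sha256": _sha256(p), "partial": True} for p in outputs
        ]
        _write_manifest(manifest, config.output_dir)
        raise

    manifest["outputs"] = [{"path": p, "sha256": _sha256(p)} for p in outputs]
    manifest["input_checksums"] = {
        sid: _sha256(os.path.join(config.timecourse_dir,
                                  next(f for f in files if os.path.splitext(f)[0] == sid)))
        for sid in ids
    }
    _write_manifest(manifest, config.output_dir)
    return manifest


def _write_manifest(manifest: dict, output_dir: str) -> None:
    from dynconn import __version__

    manifest["version"] = __version__
    with open(os.path.join(output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
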