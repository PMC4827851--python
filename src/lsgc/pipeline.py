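"""End-to-end simulation study: simulate, estimate, dichotomize, evaluate.

``run_benchmark`` orchestrates the full module-recoverability study: for
each realization it generates a ground-truth network and its MVAR time
series, computes lsGCI matrices at the requested variance-explanation
targets, dichotomizes them at the Cohen's-kappa-optimal cutoff, runs every
module-detection algorithm on both the ground-truth and the dichotomized
networks, and tabulates ROC/AUC edge-recovery results together with the
complete battery of partition-quality measures.  All outputs are tidy
DataFrames carrying (seed, D, var_target, algorithm) provenance; the whole
study is reconstructible from the configuration and the master seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lsgc_io
from . import metrics
from .communities import ALGORITHMS, detect_modules
from .lsgci import lsgc_matrix
from .mvar import feasible_order
from .simulate import benchmark_system
from .threshold import (
    binarize,
    check_connectedness,
    kappa_optimal_threshold,
    percentile_threshold,
    roc_curve,
)

__all__ = ["StudyConfig", "run_benchmark", "run_connectivity"]

logger = logging.getLogger("lsgc")

#: partition-comparison columns computed between the partition detected on
#: the ground-truth network and the one detected on the lsGCI network
_COMPARISON_METRICS = (
    "correct_ratio_vs_truth",
    "rand",
    "adjusted_rand",
    "mutual_information",
    "variation_of_information",
    "split_join",
    "edit_distance",
)


@dataclass
class StudyConfig:
    """Benchmark study settings (defaults mirror the simulation study:
    N = 1000 samples, model order p = 1, variance targets 70-100%)."""

    dims: tuple = (100,)
    n_samples: int = 1000
    realizations: int = 100
    var_targets: tuple = (0.7, 0.8, 0.9, 1.0)
    p: int = 1
    percentiles: tuple = (90.0, 95.0, 98.0)
    algorithms: tuple = ALGORITHMS
    master_seed: int = 0
    burn_in: int = 500
    scale: float = 1.0

    @property
    def n_realizations(self) -> int:
        """Realization count after applying the desk-scale factor."""
        return max(1, int(round(self.realizations * self.scale)))

    def validate(self) -> None:
        for D in self.dims:
            # var_target = 1.0 retains up to D components
            C_max = max(D, 1)
            if not feasible_order(C_max, self.n_samples, self.p):
                raise ValueError(
                    f"infeasible config: D={D}, N={self.n_samples}, p={self.p} "
                    f"violates N - p >= C * p at full variance retention"
                )
        for v in self.var_targets:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"variance target {v} outside (0, 1]")


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] >> 1)


def run_benchmark(config: StudyConfig) -> dict:
    """Run the benchmark study; returns {'auc': ..., 'modules': ...,
    'failures': ...} tidy DataFrames.

    Failed realization cells are logged and excluded; their counts appear
    in the ``failures`` table.
    """
    config.validate()
    auc_rows, module_rows, failures = [], [], []
    master = np.random.SeedSequence(config.master_seed)
    dim_streams = master.spawn(len(config.dims))
    for D, dim_ss in zip(config.dims, dim_streams):
        real_streams = dim_ss.spawn(config.n_realizations)
        for r, r_ss in enumerate(real_streams):
            sim_ss, detect_ss = r_ss.spawn(2)
            sim_seed = _spawn_seed(sim_ss)
            try:
                net, _, ts = benchmark_system(
                    D, N=config.n_samples, seed=sim_seed, burn_in=config.burn_in
                )
            except Exception as err:  # noqa: BLE001 - partial-failure tolerant
                logger.warning("realization %d (D=%d) failed: %s", r, D, err)
                failures.append(
                    {"D": D, "realization": r, "stage": "simulate", "error": str(err)}
                )
                continue

            truth_parts = {}
            for a, alg in enumerate(config.algorithms):
                seed_alg = _spawn_seed(detect_ss.spawn(1)[0])
                try:
                    part = detect_modules(net, alg, seed=seed_alg)
                except Exception as err:  # noqa: BLE001
                    failures.append(
                        {"D": D, "realization": r, "stage": f"detect_truth:{alg}",
                         "error": str(err)}
                    )
                    continue
                truth_parts[alg] = part
                module_rows.append(
                    {
                        "D": D, "realization": r, "seed": sim_seed,
                        "network": "ground_truth", "var_target": np.nan,
                        "algorithm": alg, "k": part.k,
                        "modularity": part.modularity_at_selection,
                        "correct_ratio": metrics.correct_ratio(net.labels, part.labels),
                        "coverage": metrics.coverage(net, part),
                        "performance": metrics.performance(net, part),
                        **{m: np.nan for m in _COMPARISON_METRICS},
                    }
                )

            for v in config.var_targets:
                try:
                    conn = lsgc_matrix(ts, config.p, v)
                    roc = roc_curve(conn, net)
                    thr = kappa_optimal_threshold(conn, net)
                    bnet = binarize(conn, thr)
                except Exception as err:  # noqa: BLE001
                    failures.append(
                        {"D": D, "realization": r, "stage": f"lsgc:{v}",
                         "error": str(err)}
                    )
                    continue
                auc_rows.append(
                    {
                        "D": D, "realization": r, "seed": sim_seed, "var_target": v,
                        "estimator": conn.estimator, "C": conn.n_components,
                        "var_explained": conn.var_explained, "auc": roc.auc,
                        "kappa_threshold": thr,
                        "edge_density": bnet.sum() / (D * (D - 1)),
                        "connected": check_connectedness(bnet),
                    }
                )
                for alg in config.algorithms:
                    seed_alg = _spawn_seed(detect_ss.spawn(1)[0])
                    try:
                        part = detect_modules(bnet, alg, seed=seed_alg)
                    except Exception as err:  # noqa: BLE001
                        failures.append(
                            {"D": D, "realization": r,
                             "stage": f"detect_lsgc:{alg}:{v}", "error": str(err)}
                        )
                        continue
                    row = {
                        "D": D, "realization": r, "seed": sim_seed,
                        "network": "lsgc", "var_target": v,
                        "algorithm": alg, "k": part.k,
                        "modularity": part.modularity_at_selection,
                        "correct_ratio": metrics.correct_ratio(net.labels, part.labels),
                        "coverage": metrics.coverage(bnet, part),
                        "performance": metrics.performance(bnet, part),
                    }
                    tp = truth_parts.get(alg)
                    if tp is not None:
                        matching = metrics.match_modules(tp, part)
                        row.update(
                            correct_ratio_vs_truth=metrics.correct_ratio(
                                tp, part, matching
                            ),
                            rand=metrics.rand_index(tp, part),
                            adjusted_rand=metrics.adjusted_rand(tp, part),
                            mutual_information=metrics.mutual_information(tp, part),
                            variation_of_information=metrics.variation_of_information(
                                tp, part
                            ),
                            split_join=metrics.split_join_distance(tp, part),
                            edit_distance=metrics.partition_edit_distance(
                                net, bnet, tp, part, matching
                            ),
                        )
                    else:
                        row.update({m: np.nan for m in _COMPARISON_METRICS})
                    module_rows.append(row)

    return {
        "auc": pd.DataFrame(auc_rows),
        "modules": pd.DataFrame(module_rows),
        "failures": pd.DataFrame(
            failures, columns=["D", "realization", "stage", "error"]
        ),
    }


def run_connectivity(
    matrix_file,
    p: int,
    var_target: float,
    percentile: float,
    algorithm: str,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Real-data entry point: matrix file in, connectivity products out.

    Reads a delimited time-series matrix (rows = series), computes the
    lsGCI matrix, dichotomizes it at the given edge-weight percentile,
    reports connectedness, detects modules, and (optionally) writes the
    connectivity matrix, binarized edge list, partition, and a summary to
    ``out_dir``.
    """
    y = lsgc_io.read_matrix(matrix_file)
    conn = lsgc_matrix(y, p, var_target)
    thr = percentile_threshold(conn, percentile)
    bnet = binarize(conn, thr)
    connected = check_connectedness(bnet)
    part = detect_modules(bnet, algorithm, seed=seed)
    summary = {
        "D": conn.D,
        "p": p,
        "var_target": var_target,
        "C": conn.n_components,
        "var_explained": conn.var_explained,
        "percentile": percentile,
        "threshold": thr,
        "edge_density": float(bnet.sum() / (conn.D * (conn.D - 1))),
        "connected": bool(connected),
        "algorithm": algorithm,
        "k": part.k,
        "modularity": part.modularity_at_selection,
        "seed": seed,
    }
    result = {"connectivity": conn, "network": bnet, "partition": part,
              "summary": summary}
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lsgc_io.write_matrix(out / "lsgci_matrix.tsv", conn.gamma)
        lsgc_io.write_edge_list(out / "network_edges.tsv", bnet)
        lsgc_io.write_partition(out / "partition.tsv", part.labels)
        lsgc_io.write_metadata(out / "summary.json", summary)
    return result
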