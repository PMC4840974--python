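"""Evaluation frameworks: Monte-Carlo benchmark and progression PPV.

Two ways of scoring a DV algorithm:

* **Monte-Carlo benchmark** -- repeatedly simulate datasets with known
  ground truth and record, per run, five measures: overall sensitivity at
  the estimated FDR < threshold, the true (realized) FDR at that threshold,
  and the per-type sensitivities (type-1a, type-1b, type-2).  The FDR, not
  the FPR, is reported because the FDR is what relates to the positive
  predictive value (FDR = 1 - PPV).
* **Progression PPV** -- given a ranked discovery result and an independent
  validation dataset representing a more advanced disease stage, the PPV is
  the fraction of the top-k ranked features whose validation t-statistic
  exceeds 1.96 with the same direction of change as in discovery; no
  multiple-testing correction is applied at validation, to keep the false
  negative rate in check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MethylationDataset
from .dv_tests import ALGORITHMS, DVResultTable, _t_matrix
from .simulator import SimConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "BenchmarkMetrics",
    "PPVReport",
    "simulation_metrics",
    "run_benchmark",
    "progression_ppv",
    "MEASURES",
]

logger = logging.getLogger(__name__)

MEASURES = ("sensitivity_overall", "sensitivity_type1a", "sensitivity_type1b",
            "sensitivity_type2", "true_fdr")


@dataclass
class BenchmarkMetrics:
    """Benchmark measures for one algorithm, aggregated over runs.

    ``per_run`` keeps one row per Monte-Carlo run; the scalar fields hold
    the across-run means.  ``sd`` maps measure name -> across-run standard
    deviation.
    """

    algorithm: str
    sensitivity_overall: float
    sensitivity_type1a: float
    sensitivity_type1b: float
    sensitivity_type2: float
    true_fdr: float
    n_runs: int
    sd: dict = field(default_factory=dict)
    per_run: pd.DataFrame | None = None


@dataclass
class PPVReport:
    """Validation summary for a ranked discovery list."""

    top_k: int
    direction: str
    t_threshold: float
    feature_ids: np.ndarray
    t_statistics: np.ndarray
    ppv: float


def simulation_metrics(result: DVResultTable, truth: SimulatedDataset,
                       fdr: float | None = None) -> BenchmarkMetrics:
    """Sensitivity and true FDR of one result table against ground truth.

    The significant set is the table's ``significant`` column (q < FDR for
    most algorithms; either-q rule for GAMLSS).  ``true_fdr`` is the
    fraction of called features that are ground-truth nulls, 0 by
    convention when nothing is called.
    """
    ds = truth.dataset
    tbl = result.table
    if not np.array_equal(tbl["feature_id"].to_numpy(), ds.feature_ids):
        raise ValueError("result and truth feature ids do not match")
    if fdr is not None and fdr != result.significance_threshold:
        raise ValueError(
            f"result was produced at FDR {result.significance_threshold}, "
            f"requested {fdr}"
        )
    called = tbl["significant"].to_numpy(bool)
    labels = truth.truth
    is_null = labels == "null"
    n_called = int(called.sum())
    true_fdr = float((called & is_null).sum() / n_called) if n_called else 0.0

    sens = {}
    for t in ("type1a", "type1b", "type2"):
        mask = labels == t
        sens[t] = float((called & mask).sum() / mask.sum()) if mask.any() else np.nan
    any_true = ~is_null
    overall = (float((called & any_true).sum() / any_true.sum())
               if any_true.any() else np.nan)
    return BenchmarkMetrics(
        algorithm=result.algorithm,
        sensitivity_overall=overall,
        sensitivity_type1a=sens["type1a"],
        sensitivity_type1b=sens["type1b"],
        sensitivity_type2=sens["type2"],
        true_fdr=true_fdr,
        n_runs=1,
    )


def run_benchmark(config: SimConfig, algorithms=("bt", "ievora", "diffvar",
                                                 "jdmdv", "gamlss"),
                  n_runs: int = 100, base_seed: int = 0,
                  fdr: float = 0.05) -> dict[str, BenchmarkMetrics]:
    """Monte-Carlo benchmark: ``n_runs`` simulations, all algorithms on each.

    Run r uses seed ``base_seed + r``; results are bit-reproducible given
    ``base_seed``.  Per-run algorithm failures are logged and excluded from
    that algorithm's aggregation.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithms: {unknown}")
    rows: dict[str, list] = {a: [] for a in algorithms}
    for r in range(n_runs):
        sim = simulate_dataset(replace(config, seed=base_seed + r))
        for a in algorithms:
            try:
                res = ALGORITHMS[a](sim.dataset, fdr)
                m = simulation_metrics(res, sim)
            except Exception:
                logger.exception("run %d: algorithm %s failed; recorded as "
                                 "missing", r, a)
                continue
            rows[a].append({"run": r, "seed": base_seed + r,
                            **{k: getattr(m, k) for k in MEASURES}})
    out = {}
    for a in algorithms:
        per_run = pd.DataFrame(rows[a])
        if per_run.empty:
            raise RuntimeError(f"algorithm {a} failed in every run")
        means = per_run[list(MEASURES)].mean()
        sds = per_run[list(MEASURES)].std(ddof=1) if len(per_run) > 1 else \
            per_run[list(MEASURES)].iloc[0] * 0.0
        out[a] = BenchmarkMetrics(
            algorithm=a, n_runs=len(per_run), per_run=per_run,
            sd={k: float(sds[k]) for k in MEASURES},
            **{k: float(means[k]) for k in MEASURES},
        )
    return out


def benchmark_frame(metrics: dict[str, BenchmarkMetrics]) -> pd.DataFrame:
    """Long-format summary: one row per algorithm x measure with mean and sd."""
    rows = []
    for a, m in metrics.items():
        for k in MEASURES:
            rows.append({"algorithm": a, "measure": k,
                         "mean": getattr(m, k), "sd": m.sd.get(k, np.nan),
                         "n_runs": m.n_runs})
    return pd.DataFrame(rows)


def progression_ppv(discovery: DVResultTable, validation: MethylationDataset,
                    top_k: int, direction: str = "hyper",
                    t_threshold: float = 1.96,
                    t_variant: str = "welch") -> PPVReport:
    """Positive predictive value of the top-k discovery features at validation.

    Takes the discovery table's top ``top_k`` ranked features (restricted to
    the requested discovery direction unless ``direction="both"``), computes
    a two-sample t-statistic (validation group 1 vs 0) per feature on beta
    values, and reports the fraction whose t exceeds ``t_threshold`` in the
    discovery direction.  Features absent from the validation matrix are
    excluded (logged).
    """
    if direction not in ("hyper", "hypo", "both"):
        raise ValueError("direction must be 'hyper', 'hypo' or 'both'")
    tbl = discovery.table
    ranked = tbl.dropna(subset=["rank"]).sort_values("rank")
    if direction != "both":
        ranked = ranked[ranked["direction"] == direction]
    if ranked.empty:
        logger.warning("empty ranked set; PPV undefined")
        return PPVReport(top_k=0, direction=direction, t_threshold=t_threshold,
                         feature_ids=np.array([]), t_statistics=np.array([]),
                         ppv=np.nan)
    if top_k > len(ranked):
        logger.warning("top_k=%d exceeds ranked set of %d; using all",
                       top_k, len(ranked))
        top_k = len(ranked)
    top = ranked.head(top_k)

    val_index = {f: i for i, f in enumerate(validation.feature_ids)}
    present = top["feature_id"].map(lambda f: f in val_index)
    if (~present).any():
        logger.warning("%d top-ranked features absent from validation matrix",
                       int((~present).sum()))
    top = top[present]
    if top.empty:
        return PPVReport(top_k=0, direction=direction, t_threshold=t_threshold,
                         feature_ids=np.array([]), t_statistics=np.array([]),
                         ppv=np.nan)
    rows = [val_index[f] for f in top["feature_id"]]
    t_stat, _, _ = _t_matrix(validation.values[rows, :], validation.group,
                             t_variant)
    disc_dir = top["direction"].to_numpy()
    hits = np.where(disc_dir == "hyper", t_stat > t_threshold,
                    t_stat < -t_threshold)
    return PPVReport(
        top_k=len(top), direction=direction, t_threshold=t_threshold,
        feature_ids=top["feature_id"].to_numpy(), t_statistics=t_stat,
        ppv=float(np.nanmean(hits.astype(float))),
    )
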