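"""Compare the five DV algorithms on simulated data with known truth.

A scaled-down Monte-Carlo benchmark (5 runs; the full study uses 100)
recording per-type sensitivity and the realized false discovery rate at the
estimated FDR < 0.05 threshold.  The headline contrast: Bartlett-based
tests (BT/iEVORA) and GAMLSS keep near-full power for outlier-driven
type-2 DV, while the Levene-type DiffVar loses it almost entirely in
exchange for tighter FDR control.
"""

from dvmeth import SimConfig, run_benchmark
from dvmeth.evaluation import benchmark_frame

metrics = run_benchmark(
    SimConfig(),
    algorithms=("bt", "ievora", "diffvar", "jdmdv", "gamlss"),
    n_runs=5,
    base_seed=0,
)
frame = benchmark_frame(metrics).pivot(index="algorithm", columns="measure",
                                       values="mean")
print(frame.round(3).to_string())
print("\nsensitivity_* = fraction of true DVCs of each type called at "
      "FDR < 0.05;\ntrue_fdr = fraction of calls that are ground-truth null.")
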