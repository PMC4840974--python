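"""Two-stage discovery/validation design: estimate the PPV of a DVC list.

Discovery: find DVCs between two phenotypes with subtle differences.
Validation: an independent dataset representing a more advanced disease
stage (more altered samples per true CpG).  The PPV is the fraction of the
top-ranked discovery CpGs whose validation t-statistic exceeds 1.96 in the
same direction — biologically meaningful DVCs should show progression.
"""

import numpy as np

from dvmeth import SimConfig, progression_ppv, run_ievora, simulate_dataset
from dvmeth.dv_tests import _t_matrix

disc_sim = simulate_dataset(SimConfig(seed=1))
val_sim = simulate_dataset(
    SimConfig(n_altered_type1b=35, n_altered_type2=10, seed=1001)
)

discovery = run_ievora(disc_sim.dataset, bt_fdr=0.05)
report = progression_ppv(discovery, val_sim.dataset, top_k=200,
                         direction="hyper")
print(f"iEVORA top-{report.top_k} PPV at validation: {report.ppv:.3f}")

rng = np.random.default_rng(1)
rows = rng.choice(disc_sim.dataset.n_features, size=200, replace=False)
t_stat, _, _ = _t_matrix(val_sim.dataset.values[rows, :], val_sim.dataset.group,
                         "welch")
print(f"random-200-CpG baseline PPV:    {np.mean(t_stat > 1.96):.3f}")
print("\nranked discoveries validate at a far higher rate than chance,")
print("as expected if the detected DVCs mark genuinely progressing loci.")
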