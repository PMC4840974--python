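"""Classification of significant DVCs into differential-variability types.

A CpG called differentially variable (Bartlett q-value below the FDR
threshold) is typed by comparing its differential-mean t-test P-value with
its Bartlett P-value:

* **type-2**  -- the t-test is not significant (``t_p > t_alpha``): variance
  change driven by a few outliers, no mean shift.
* **type-1a** -- the t-test is significant and more significant than
  Bartlett's test (``t_p < bt_p``): mean-dominated change.
* **type-1b** -- the t-test is significant but Bartlett's test is at least
  as significant: variance-dominated change with a real mean shift.

Boundary conventions: ``t_p == t_alpha`` is type-1 (the type-2 rule requires
strictly non-significant); ``t_p == bt_p`` is type-1b ("more significant"
read strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dv_tests import DVResultTable

__all__ = ["DVTypeCall", "classify_dv_type", "classify_results", "taxonomy_summary"]

DV_TYPES = ("type1a", "type1b", "type2")


@dataclass
class DVTypeCall:
    feature_id: str
    dv_type: str  # type1a | type1b | type2 | not_dvc
    bt_p: float
    bt_q: float
    t_p: float


def classify_dv_type(bt_p: float, bt_q: float, t_p: float,
                     fdr: float = 0.05, t_alpha: float = 0.05) -> str:
    """Type of one DVC from its Bartlett P/q-values and t-test P-value."""
    for name, v in (("bt_p", bt_p), ("bt_q", bt_q), ("t_p", t_p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if bt_q >= fdr:
        return "not_dvc"
    if t_p > t_alpha:
        return "type2"
    return "type1a" if t_p < bt_p else "type1b"


def classify_results(result: DVResultTable, fdr: float = 0.05,
                     t_alpha: float = 0.05) -> list[DVTypeCall]:
    """Classify every feature of an iEVORA result table.

    The table must carry the ``t_p`` auxiliary column (as produced by
    ``run_ievora``).  Features with missing Bartlett or t results are
    reported as ``not_dvc``.
    """
    if "t_p" not in result.table.columns:
        raise ValueError("result table lacks the t_p column; run iEVORA first")
    calls = []
    for row in result.table.itertuples(index=False):
        if np.isnan(row.p_value) or np.isnan(row.q_value) or np.isnan(row.t_p):
            dv_type = "not_dvc"
        else:
            dv_type = classify_dv_type(row.p_value, row.q_value, row.t_p,
                                       fdr=fdr, t_alpha=t_alpha)
        calls.append(DVTypeCall(feature_id=row.feature_id, dv_type=dv_type,
                                bt_p=row.p_value, bt_q=row.q_value, t_p=row.t_p))
    return calls


def taxonomy_summary(calls: list[DVTypeCall]) -> dict:
    """Relative fractions of type-1a / type-1b / type-2 among called DVCs.

    Returns ``{"n_dvc": count, "fractions": {type: fraction} or None}``;
    with zero DVCs the fractions are None (undefined).
    """
    if not calls:
        raise ValueError("empty call list")
    labels = np.array([c.dv_type for c in calls], dtype=object)
    dvc = labels[labels != "not_dvc"]
    if dvc.size == 0:
        return {"n_dvc": 0, "fractions": None}
    fractions = {t: float((dvc == t).sum()) / dvc.size for t in DV_TYPES}
    return {"n_dvc": int(dvc.size), "fractions": fractions}


def calls_to_frame(calls: list[DVTypeCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
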