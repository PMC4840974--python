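"""Data model for DNA methylation beta-value matrices.

A methylation dataset is a features x samples matrix of beta values
(the fraction of methylated signal at a CpG, in [0, 1]) together with a
binary phenotype: group 0 is the reference (normal/healthy) phenotype and
group 1 the at-risk/disease phenotype.  All direction conventions in this
package (hyper/hypo) refer to group 1 relative to group 0.

Missing entries are represented as NaN; the TSV dialect uses the token
``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "MValueMatrix",
    "beta_to_m",
    "m_to_beta",
    "to_mvalues",
    "load_dataset",
    "write_dataset",
    "DEFAULT_CLIP_EPSILON",
]

#: Default bound keeping beta away from {0, 1} before the logit2 transform.
#: Caps M-values at roughly +/- 9.97 and avoids infinities from saturated probes.
DEFAULT_CLIP_EPSILON = 0.001

MISSING_TOKEN = "NA"


class ValidationError(ValueError):
    """Raised when a dataset violates its invariants."""


@dataclass
class MethylationDataset:
    """Beta-value matrix with sample/feature identifiers and binary phenotype.

    Parameters
    ----------
    values
        Array of shape ``(n_features, n_samples)`` with entries in [0, 1];
        NaN marks a missing measurement.
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    group
        Integer array of per-sample labels in {0, 1}; both labels must be
        present.  0 = reference/normal, 1 = disease/at-risk.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.group = np.asarray(self.group, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValidationError("feature_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samp:
            raise ValidationError("sample_ids length does not match matrix columns")
        if len(self.group) != n_samp:
            raise ValidationError("group length does not match number of samples")
        if len(set(self.feature_ids)) != n_feat:
            raise ValidationError("feature_ids are not unique")
        if len(set(self.sample_ids)) != n_samp:
            raise ValidationError("sample_ids are not unique")
        if not set(np.unique(self.group)) <= {0, 1}:
            raise ValidationError("group labels must be 0 or 1")
        if len(np.unique(self.group)) < 2:
            raise ValidationError("both group labels (0 and 1) must be present")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.where(np.nan_to_num(self.values, nan=0.5) > 1.0)
            bad_lo = np.where(np.nan_to_num(self.values, nan=0.5) < 0.0)
            idx = bad[0] if bad[0].size else bad_lo[0]
            raise ValidationError(
                f"beta values outside [0,1] (first offending feature: "
                f"{self.feature_ids[idx[0]]})"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def group_values(self, g: int) -> np.ndarray:
        """Matrix slice of samples belonging to group ``g`` (view, features x n_g)."""
        return self.values[:, self.group == g]


@dataclass
class MValueMatrix:
    """M-value matrix, M = log2(beta / (1 - beta)), with the clip used."""

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    group: np.ndarray
    clip_epsilon: float = DEFAULT_CLIP_EPSILON

    def group_values(self, g: int) -> np.ndarray:
        return self.values[:, self.group == g]


def beta_to_m(beta, clip_epsilon: float = DEFAULT_CLIP_EPSILON):
    """Logit2 transform of a beta value: ``M = log2(beta/(1-beta))``.

    ``beta`` is clipped to ``[clip_epsilon, 1-clip_epsilon]`` first, so the
    result is finite everywhere.  NaN passes through.  Accepts scalars or
    arrays; raises on beta outside [0, 1].
    """
    if not 0.0 < clip_epsilon < 0.5:
        raise ValueError("clip_epsilon must lie in (0, 0.5)")
    b = np.asarray(beta, dtype=float)
    finite = b[~np.isnan(b)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(b, clip_epsilon, 1.0 - clip_epsilon)
    out = np.log2(clipped / (1.0 - clipped))
    return float(out) if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse logit2: ``beta = 2**M / (1 + 2**M)``; saturates smoothly."""
    m_arr = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large |m|
    out = 1.0 / (1.0 + np.exp2(-m_arr))
    return float(out) if np.isscalar(m) else out


def to_mvalues(ds: MethylationDataset, clip_epsilon: float = DEFAULT_CLIP_EPSILON) -> MValueMatrix:
    """Convert a beta-value dataset to M-values."""
    return MValueMatrix(
        values=beta_to_m(ds.values, clip_epsilon),
        feature_ids=ds.feature_ids,
        sample_ids=ds.sample_ids,
        group=ds.group,
        clip_epsilon=clip_epsilon,
    )


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        comment="#",
        dtype=str,
    )


def load_dataset(matrix_path, phenotype_path) -> MethylationDataset:
    """Load a beta matrix TSV plus a two-column phenotype TSV.

    The matrix file has a header row of sample IDs and a first column of
    feature IDs.  The phenotype file maps sample ID -> group label (0/1);
    it may list extra samples but must cover every matrix sample.  The
    phenotype is reconciled to matrix column order.
    """
    matrix_path, phenotype_path = Path(matrix_path), Path(phenotype_path)
    raw = _read_table(matrix_path)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        # element-wise float() for correctly-rounded (bit-exact) parsing
        try:
            values[:, j] = [
                float(v) if isinstance(v, str) else np.nan for v in raw[col]
            ]
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce")
            row = raw.index[bad.isna() & raw[col].notna()][0]
            raise ValidationError(
                f"non-numeric value at feature {row!r}, sample {col!r} in {matrix_path}"
            ) from None

    pheno = pd.read_csv(
        phenotype_path, sep="\t", header=0, dtype={0: str}, comment="#"
    )
    if pheno.shape[1] < 2:
        raise ValidationError(f"phenotype file {phenotype_path} needs two columns")
    pheno_map = dict(zip(pheno.iloc[:, 0].astype(str), pheno.iloc[:, 1].astype(int)))
    missing = [s for s in raw.columns if s not in pheno_map]
    if missing:
        raise ValidationError(
            f"samples missing from phenotype file: {', '.join(map(str, missing))}"
        )
    group = np.array([pheno_map[s] for s in raw.columns], dtype=int)
    return MethylationDataset(
        values=values,
        feature_ids=raw.index.to_numpy(dtype=object),
        sample_ids=raw.columns.to_numpy(dtype=object),
        group=group,
    )


def write_dataset(ds: MethylationDataset, matrix_path, phenotype_path,
                  header_lines: list[str] | None = None) -> None:
    """Write dataset to the TSV dialect read by :func:`load_dataset`.

    ``header_lines`` are emitted as ``#``-prefixed comments.  Values are
    written with ``repr`` precision so that a write/load round trip is
    bit-exact for finite entries.
    """
    def _open_write(path, frame_writer):
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            frame_writer(fh)

    frame = pd.DataFrame(ds.values, index=ds.feature_ids, columns=ds.sample_ids)
    _open_write(
        matrix_path,
        lambda fh: frame.to_csv(
            fh, sep="\t", na_rep=MISSING_TOKEN, index_label="feature_id",
            float_format="%.17g",  # guarantees bit-exact float64 round trip
        ),
    )
    pheno = pd.DataFrame({"sample_id": ds.sample_ids, "group": ds.group})
    _open_write(phenotype_path, lambda fh: pheno.to_csv(fh, sep="\t", index=False))
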