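"""miRNA signal normalization, expression filtering, and paired differences.

Microarray signal intensities carry per-array scale artifacts (labeling,
hybridization, scanner gain). They are removed by 75th-percentile scaling:
every sample is multiplied by ``median(75th percentiles of all samples) /
(its own 75th percentile)``, after which all samples share the same upper
quartile. Percentiles use linear interpolation between order statistics
(numpy's default convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, PairingError


@dataclass
class NormalizedSignals:
    """Scaled miRNA x sample matrix with the factors that produced it."""

    matrix: pd.DataFrame
    scale_factors: pd.Series
    reference_quantile: float


def scale_normalize(signals: pd.DataFrame) -> NormalizedSignals:
    """75th-percentile scaling normalization of a miRNA x sample matrix."""
    p75 = signals.quantile(0.75, axis=0)
    zero = p75.index[p75 <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"zero 75th percentile for samples: {', '.join(map(str, zero))}"
        )
    reference = float(np.median(p75.to_numpy()))
    factors = reference / p75
    return NormalizedSignals(
        matrix=signals * factors,
        scale_factors=factors,
        reference_quantile=reference,
    )


def expression_filter(signals: pd.DataFrame, normal_sample_ids,
                      min_fraction: float = 0.20) -> list[str]:
    """miRNAs detected in strictly more than ``min_fraction`` of normal samples.

    Detection means a strictly positive signal (no array detection flag is
    carried through this pipeline, so presence of signal stands in for it).
    """
    if not 0 < min_fraction < 1:
        raise ValueError(f"min_fraction must be in (0,1), got {min_fraction}")
    normal_sample_ids = list(normal_sample_ids)
    if not normal_sample_ids:
        raise ValueError("normal_sample_ids is empty")
    missing = set(normal_sample_ids) - set(signals.columns)
    if missing:
        raise KeyError(f"unknown sample ids: {sorted(missing)}")
    detected = (signals[normal_sample_ids] > 0).mean(axis=1)
    return list(signals.index[detected > min_fraction])


def paired_diff(values: pd.Series, sample_map: pd.DataFrame) -> pd.Series:
    """Per-subject (tumor - normal) difference of a per-sample quantity.

    ``sample_map`` is indexed by sample with columns ``subject`` and
    ``tissue``; every subject must contribute both tissues.
    """
    merged = sample_map.copy()
    merged["value"] = values.reindex(sample_map.index)
    if merged["value"].isna().any():
        missing = merged.index[merged["value"].isna()].tolist()
        raise PairingError(f"no value for samples: {missing}")
    wide = merged.pivot_table(index="subject", columns="tissue", values="value",
                              aggfunc="first", sort=False)
    for tissue in ("tumor", "normal"):
        if tissue not in wide.columns or wide[tissue].isna().any():
            bad = list(wide.index[wide[tissue].isna()]) if tissue in wide.columns \
                else list(wide.index)
            raise PairingError(f"subjects missing a {tissue} sample: {bad}")
    return wide["tumor"] - wide["normal"]


def paired_diff_matrix(matrix: pd.DataFrame, sample_map: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`paired_diff`: features x subjects (tumor - normal)."""
    subjects = sample_map["subject"].drop_duplicates()
    tumor = {s: None for s in subjects}
    normal = {s: None for s in subjects}
    for sample, row in sample_map.iterrows():
        (tumor if row["tissue"] == "tumor" else normal)[row["subject"]] = sample
    missing = [s for s in subjects if tumor[s] is None or normal[s] is None]
    if missing:
        raise PairingError(f"subjects missing a tissue: {missing}")
    t = matrix[[tumor[s] for s in subjects]].to_numpy()
    n = matrix[[normal[s] for s in subjects]].to_numpy()
    return pd.DataFrame(t - n, index=matrix.index, columns=list(subjects))
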