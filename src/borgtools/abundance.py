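"""Depth-normalized coverage, abundance correlation and copy ratios.

Per-sample mean coverages are normalized by the total bases sequenced in
the sample and scaled by 1e11, then Borg-host co-occurrence is measured as
the Pearson correlation of normalized profiles across samples; pairs above
r > 0.995 are flagged as candidate host linkages. Copy ratios compare a
Borg's normalized coverage to its putative host's (optionally aggregated
over several elements).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALING_FACTOR = 1e11
DEFAULT_R_THRESHOLD = 0.995


def normalize_coverage(matrix: pd.DataFrame, totals: Mapping[str, float]
                       ) -> pd.DataFrame:
    """Normalize an entities x samples coverage matrix: raw / total_bp * 1e11."""
    missing = [s for s in matrix.columns if s not in totals]
    if missing:
        raise ValueError(f"missing sequencing totals for samples: {missing}")
    t = pd.Series({s: totals[s] for s in matrix.columns}, dtype=float)
    if (t <= 0).any():
        raise ValueError("sample totals must be positive")
    return matrix.div(t, axis=1) * SCALING_FACTOR


def correlate_and_call_hosts(normalized: pd.DataFrame, borg_ids: Sequence[str],
                             host_ids: Sequence[str],
                             threshold: float = DEFAULT_R_THRESHOLD,
                             log_transform: bool = False
                             ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlation over samples for every Borg x host pair.

    Returns the full correlation matrix (borgs x hosts) and the list of
    (borg, host, r) pairs with r strictly above ``threshold``. Constant
    profiles have undefined correlation and are skipped with a warning.
    """
    if normalized.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    data = np.log1p(normalized) if log_transform else normalized
    constant = data.std(axis=1) == 0
    if constant.any():
        warnings.warn("constant coverage profiles skipped: "
                      + ", ".join(data.index[constant]))
    corr = pd.DataFrame(np.nan, index=list(borg_ids), columns=list(host_ids))
    for b in borg_ids:
        if constant.get(b, False):
            continue
        for h in host_ids:
            if constant.get(h, False):
                continue
            r = np.corrcoef(data.loc[b], data.loc[h])[0, 1]
            corr.loc[b, h] = r
    pairs = [(b, h, float(corr.loc[b, h])) for b in borg_ids for h in host_ids
             if corr.loc[b, h] > threshold]
    return corr, pairs


def copy_ratio(borg_cov: float | Iterable[float],
               host_cov: float | Iterable[float]) -> float:
    """Borg : host genome copy ratio from normalized coverages.

    Scalars give a plain ratio; iterables are summed first (aggregate mode,
    e.g. all Borgs vs all hosts in a sample). A zero host coverage is
    undefined and reported as NaN with a warning.
    """
    b = float(np.sum(np.asarray(borg_cov, dtype=float)))
    h = float(np.sum(np.asarray(host_cov, dtype=float)))
    if h == 0:
        warnings.warn("zero host coverage: copy ratio undefined")
        return float("nan")
    return b / h


__all__ = ["SCALING_FACTOR", "DEFAULT_R_THRESHOLD", "normalize_coverage",
           "correlate_and_call_hosts", "copy_ratio"]
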