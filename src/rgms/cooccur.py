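"""Fragment and organ co-occurrence statistics.

Two views of the detected RG set: a pairwise Pearson correlation of
nominal-mass (integer Da) fragment intensities across a species' RG peaks
-- water-loss pairs (nominal difference 18) are flagged, since both the
open and closed macrolactone forms and in-source dehydration produce them
-- and a per-species Pearson correlation of relative leaf vs root peak
areas.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectedRG
from .io import AlignmentTable, SpectrumRecord

__all__ = ["build_fragment_matrix", "fragment_correlations", "organ_correlation"]


def build_fragment_matrix(
    detections: list[DetectedRG],
    spectra: dict[str, SpectrumRecord],
    log10: bool = False,
) -> pd.DataFrame:
    """Rows = RG features, columns = nominal fragment masses (nearest
    integer Da), cells = summed intensity (0 when absent)."""
    rows: dict[str, dict[int, float]] = {}
    for det in detections:
        rec = spectra[det.feature_id]
        binned: dict[int, float] = {}
        for mz, inten in rec.fragments:
            key = int(round(mz))
            binned[key] = binned.get(key, 0.0) + inten
        rows[det.feature_id] = binned
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix = matrix.reindex([d.feature_id for d in detections]).fillna(0.0)
    matrix = matrix.reindex(sorted(matrix.columns), axis=1)
    matrix.index.name = "feature_id"
    if log10:
        matrix = np.log10(matrix + 1.0)
    return matrix


def fragment_correlations(
    matrix: pd.DataFrame, min_obs: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlation between nominal-mass columns.

    Only column pairs with at least ``min_obs`` jointly nonzero rows are
    reported; zero-variance columns yield a missing (NaN) coefficient.
    Pairs whose nominal masses differ by 18 (water) are flagged. Each
    unordered pair appears once, with ``mass_high`` > ``mass_low``.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two RG features")
    records = []
    cols = list(matrix.columns)
    values = matrix.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(len(cols)), 2):
        a, b = values[:, i], values[:, j]
        joint = int(np.sum((a > 0) & (b > 0)))
        if joint < min_obs:
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            pcc = np.nan
        else:
            pcc = float(stats.pearsonr(a, b).statistic)
        hi, lo = max(cols[i], cols[j]), min(cols[i], cols[j])
        records.append({
            "mass_high": hi,
            "mass_low": lo,
            "pcc": pcc,
            "n_joint": joint,
            "delta18": (hi - lo) == 18,
        })
    return pd.DataFrame(
        records, columns=["mass_high", "mass_low", "pcc", "n_joint", "delta18"]
    )


@dataclass
class OrganCorrelation:
    pcc: float | None
    n: int
    note: str = ""


def organ_correlation(
    table: AlignmentTable,
    detections: list[DetectedRG],
    relative: bool = True,
) -> OrganCorrelation:
    """Pearson correlation of leaf vs root peak areas over the detected RGs.

    With ``relative`` (the default) each organ's areas are normalized to
    that organ's total over the detected set, so the statistic compares
    profiles rather than absolute loads. Fewer than 3 usable points is
    reported as insufficient data.
    """
    leaf = np.array([table.leaf_area(d.feature_id) for d in detections])
    root = np.array([table.root_area(d.feature_id) for d in detections])
    n = len(detections)
    if n < 3:
        return OrganCorrelation(pcc=None, n=n, note="insufficient data (<3 RGs)")
    if relative:
        if leaf.sum() == 0 or root.sum() == 0:
            return OrganCorrelation(pcc=None, n=n, note="an organ has zero total area")
        leaf = leaf / leaf.sum()
        root = root / root.sum()
    if np.std(leaf) == 0 or np.std(root) == 0:
        return OrganCorrelation(pcc=None, n=n, note="zero variance in an organ")
    pcc = float(stats.pearsonr(leaf, root).statistic)
    return OrganCorrelation(pcc=pcc, n=n)
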