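"""Paired tumor/normal differential methylation.

No statistical test is fitted: following the profiled design, a peak is
dysregulated when its enrichment changes by at least ``fc_threshold``
(default 1.5-fold) in the same direction in at least ``min_pairs``
(default 4) tumor/normal pairs. Peaks satisfying both directions at once
(possible with 8 pairs and a minimum of 4) are reported as ambiguous and
excluded from the dysregulated denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import EnrichmentMatrix
from .utils import percent

CLASS_INCREASED = "increased"
CLASS_DECREASED = "decreased"
CLASS_UNCHANGED = "unchanged"
CLASS_AMBIGUOUS = "ambiguous"
CLASS_UNDEFINED = "undefined"


def pair_fold_changes(matrix: EnrichmentMatrix) -> pd.DataFrame:
    """Per-peak tumor/normal enrichment ratio for each patient pair.

    Cells where either paired enrichment is masked (NaN) are NaN.
    """
    pairs = matrix.pairs()
    if pairs.isna().any().any():
        raise ValueError("incomplete tumor/normal pairing")
    out = {}
    for patient, row in pairs.iterrows():
        out[patient] = matrix.enrichment[row["tumor"]] / matrix.enrichment[row["normal"]]
    fc = pd.DataFrame(out, index=matrix.enrichment.index)
    fc.columns.name = "patient"
    return fc


def classify_dysregulated(fold_changes: pd.DataFrame, fc_threshold: float = 1.5,
                          min_pairs: int = 4) -> pd.DataFrame:
    """Classify each peak from its per-pair fold-change vector.

    increased: >= ``min_pairs`` pairs with FC >= threshold; decreased:
    >= ``min_pairs`` pairs with FC <= 1/threshold; ambiguous when both
    arms are satisfied; undefined when fewer than ``min_pairs`` pairs
    are unmasked; otherwise unchanged. ``min_pairs`` is an absolute
    count, not a fraction of unmasked pairs.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    n_pairs = fold_changes.shape[1]
    if not 1 <= min_pairs <= n_pairs:
        raise ValueError(f"min_pairs must be in [1, {n_pairs}]")
    vals = fold_changes.to_numpy(dtype=float)
    n_valid = np.sum(~np.isnan(vals), axis=1)
    n_up = np.nansum(vals >= fc_threshold, axis=1).astype(int)
    n_down = np.nansum(vals <= 1.0 / fc_threshold, axis=1).astype(int)
    cls = np.full(len(vals), CLASS_UNCHANGED, dtype=object)
    cls[(n_up >= min_pairs)] = CLASS_INCREASED
    cls[(n_down >= min_pairs)] = CLASS_DECREASED
    cls[(n_up >= min_pairs) & (n_down >= min_pairs)] = CLASS_AMBIGUOUS
    cls[n_valid < min_pairs] = CLASS_UNDEFINED
    return pd.DataFrame({"n_pairs_up": n_up, "n_pairs_down": n_down,
                         "n_pairs_valid": n_valid, "klass": cls},
                        index=fold_changes.index)


def summarize_dysregulation(classes: pd.Series | pd.DataFrame) -> dict:
    """Counts and percentages of increased/decreased among dysregulated
    peaks (ambiguous and undefined reported separately).

    With the counts printed for the profiled cohort (1,392 increased,
    113 decreased) this yields 92.49% / 7.51%.
    """
    if isinstance(classes, pd.DataFrame):
        classes = classes["klass"]
    counts = classes.value_counts()
    n_inc = int(counts.get(CLASS_INCREASED, 0))
    n_dec = int(counts.get(CLASS_DECREASED, 0))
    n_dys = n_inc + n_dec
    return {
        "n_increased": n_inc,
        "n_decreased": n_dec,
        "n_dysregulated": n_dys,
        "n_unchanged": int(counts.get(CLASS_UNCHANGED, 0)),
        "n_ambiguous": int(counts.get(CLASS_AMBIGUOUS, 0)),
        "n_undefined": int(counts.get(CLASS_UNDEFINED, 0)),
        "pct_increased": percent(n_inc, n_dys) if n_dys else None,
        "pct_decreased": percent(n_dec, n_dys) if n_dys else None,
    }


def global_shift(matrix: EnrichmentMatrix, bins=20, mode: str = "difference"):
    """Histogram of per-peak mean tumor vs mean normal enrichment.

    ``mode='difference'`` histograms (mean tumor - mean normal);
    ``mode='ratio'`` histograms log2(mean tumor / mean normal). Returns
    (counts, bin_edges, n_excluded); peaks with an all-masked side are
    excluded and counted.
    """
    if mode not in ("difference", "ratio"):
        raise ValueError("mode must be 'difference' or 'ratio'")
    tumor_cols = matrix.samples.loc[matrix.samples.condition == "tumor", "sample_id"]
    normal_cols = matrix.samples.loc[matrix.samples.condition == "normal", "sample_id"]
    mt = matrix.enrichment[list(tumor_cols)].mean(axis=1, skipna=True)
    mn = matrix.enrichment[list(normal_cols)].mean(axis=1, skipna=True)
    if mode == "difference":
        x = mt - mn
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.log2(mt / mn)
    x = x.to_numpy(dtype=float)
    keep = np.isfinite(x)
    counts, edges = np.histogram(x[keep], bins=bins)
    return counts, edges, int((~keep).sum())
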