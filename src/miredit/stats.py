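"""Shared statistical helpers used by more than one pipeline stage."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values ("q-values").

    Shared by the editing-site detector and the differential-expression
    stage so that both report FDR on an identical footing.

    Parameters
    ----------
    p_values : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray
        Adjusted values clipped to 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
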