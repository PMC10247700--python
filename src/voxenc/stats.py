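"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np


def pearson_columns(a: np.ndarray, b: np.ndarray,
                    return_degenerate: bool = False):
    """Column-wise Pearson correlation of two (N, V) arrays.

    Degenerate columns (zero variance in either input) get ρ = 0; with
    ``return_degenerate`` the boolean flag vector is returned as well.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    na = np.sqrt((a0 * a0).sum(axis=0))
    nb = np.sqrt((b0 * b0).sum(axis=0))
    denom = na * nb
    degenerate = denom <= 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (a0 * b0).sum(axis=0) / denom
    rho = np.where(degenerate, 0.0, np.clip(rho, -1.0, 1.0))
    if return_degenerate:
        return rho, degenerate
    return rho
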