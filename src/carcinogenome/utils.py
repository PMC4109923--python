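"""Small shared numerics: FDR correction and seed derivation."""

from __future__ import annotations

import numpy as np


def bh_q(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values yield NaN q-values and are excluded from the correction.
    Returned q-values are monotone in p and bounded by 1.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def child_seed(master_seed: int, index: int) -> int:
    """Derive a reproducible per-task seed below 2**31 from a master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))
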