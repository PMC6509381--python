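"""Independent oracles used by the test suite.

These deliberately avoid the package's own estimation paths: the Sobol
indices come from a Monte-Carlo pick-freeze scheme, the Ishigami indices
from their closed forms, and the Venn labels from hand-enumerated
truth tables over the 16 possible (CUR, CLC, SLR, CCS) memberships.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Variance-based sensitivity oracles


def sobol_pick_freeze(func, ppfs, n: int = 100_000, seed: int = 0):
    """Monte-Carlo first-order and total Sobol indices (Saltelli/Jansen
    estimators) for a vectorised model over independent inputs given by
    their inverse CDFs."""
    rng = np.random.default_rng(seed)
    m = len(ppfs)
    A = np.column_stack([ppf(rng.uniform(size=n)) for ppf in ppfs])
    B = np.column_stack([ppf(rng.uniform(size=n)) for ppf in ppfs])
    fA, fB = func(A), func(B)
    var = np.var(np.concatenate([fA, fB]))
    s_first = np.empty(m)
    s_total = np.empty(m)
    for i in range(m):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = func(ABi)
        s_first[i] = np.mean(fB * (fABi - fA)) / var
        s_total[i] = 0.5 * np.mean((fA - fABi) ** 2) / var
    return s_first, s_total


def ishigami(X: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    return np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2 + b * X[:, 2] ** 4 * np.sin(X[:, 0])


def ishigami_analytic(a: float = 7.0, b: float = 0.1):
    """Closed-form first-order and total Sobol indices of the Ishigami
    function over uniform(-pi, pi) inputs."""
    v1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
    v2 = a**2 / 8
    v13 = b**2 * np.pi**8 * (1 / 18 - 1 / 50)
    v = v1 + v2 + v13
    s_first = np.array([v1 / v, v2 / v, 0.0])
    s_total = np.array([(v1 + v13) / v, v2 / v, v13 / v])
    return s_first, s_total


# ---------------------------------------------------------------------------
# Venn attribution truth tables, hand-enumerated over membership tuples
# (in_cur, in_clc, in_slr, in_ccs).

GAIN_LOSS_ORACLE_AS_PRINTED = {
    # cur clc slr ccs
    (0, 0, 0, 0): "absent",
    (0, 0, 1, 0): "absent",
    (0, 1, 0, 0): "absent",
    (0, 1, 1, 0): "absent",
    (0, 0, 0, 1): "c_ics_gain",   # gained only when drivers combine
    (0, 1, 0, 1): "p_clc_gain",   # gained under climate change alone
    (0, 0, 1, 1): "p_slr_gain",   # gained under sea-level rise alone
    (0, 1, 1, 1): "s_ics_gain",   # gained under both single drivers
    (1, 0, 0, 1): "unchanged",
    (1, 0, 1, 1): "unchanged",
    (1, 1, 0, 1): "unchanged",
    (1, 1, 1, 1): "unchanged",
    (1, 1, 1, 0): "s_ics_loss",   # retained under both single drivers
    (1, 1, 0, 0): "p_clc_loss",   # retained under climate change only
    (1, 0, 1, 0): "p_slr_loss",   # retained under sea-level rise only
    (1, 0, 0, 0): "c_ics_loss",   # retained under neither
}

GAIN_LOSS_ORACLE_SYMMETRIC = dict(GAIN_LOSS_ORACLE_AS_PRINTED)
GAIN_LOSS_ORACLE_SYMMETRIC.update({
    (1, 0, 0, 0): "s_ics_loss",   # lost under both single drivers
    (1, 0, 1, 0): "p_clc_loss",   # lost under climate change only
    (1, 1, 0, 0): "p_slr_loss",   # lost under sea-level rise only
    (1, 1, 1, 0): "c_ics_loss",   # lost under neither single driver
})


def venn_oracle_codes(cur, clc, slr, ccs, convention: str = "as_printed") -> np.ndarray:
    """Per-cell labels by truth-table lookup (brute force, no set algebra)."""
    from coastniche.venn import LABELS

    table = (GAIN_LOSS_ORACLE_AS_PRINTED if convention == "as_printed"
             else GAIN_LOSS_ORACLE_SYMMETRIC)
    cur, clc, slr, ccs = (np.asarray(a, dtype=int) for a in (cur, clc, slr, ccs))
    out = np.empty(cur.shape, dtype=np.int16)
    for idx in np.ndindex(cur.shape):
        out[idx] = LABELS[table[(cur[idx], clc[idx], slr[idx], ccs[idx])]]
    return out
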