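"""Independent brute-force oracles used to validate the implementation.

These deliberately use explicit Python loops and direct formulas, and
share no code with the package.
"""

from __future__ import annotations

import numpy as np


def axis_symmetry_bruteforce(img: np.ndarray, axis: str) -> float:
    """Weighted reflected-pair symmetry score by explicit enumeration."""
    a = np.asarray(img)
    m, w = a.shape
    num = 0.0
    den = 0.0
    if axis in ("vertical", "horizontal"):
        if axis == "horizontal":
            a = a.T
            m, w = a.shape
        n = w // 2
        for i in range(m):
            for j in range(1, n + 1):  # j=1 at the border, j=n at the axis
                weight = 1.0 if n == 1 else 1.0 + (j - 1) / (n - 1)
                matched = a[i, j - 1] == a[i, w - j]
                num += weight * matched
                den += weight
        return num / den
    assert m == w, "diagonal axes need a square image"
    n = w - 1  # distance classes from the axis
    for i in range(w):
        for j in range(w):
            if axis == "main-diagonal":
                if j <= i:
                    continue
                pi, pj = j, i
                d = j - i
            else:
                if i + j >= w - 1:
                    continue
                pi, pj = w - 1 - j, w - 1 - i
                d = (w - 1) - (i + j)
            weight = 1.0 if n == 1 else 1.0 + (n - d) / (n - 1)
            num += weight * (a[i, j] == a[pi, pj])
            den += weight
    return num / den


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """OLS estimates, SEs, R² via the closed-form normal equations."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    dof = n - D.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / tss
    return beta, se, r2
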