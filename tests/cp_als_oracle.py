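"""Independent masked CP-ALS oracle used only by the test suite.

A deliberately plain alternating-least-squares CP fit (no priors, no rank
adaptation) serving as a cross-check for the variational factorization; it
shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def cp_als(
    values: np.ndarray,
    mask: np.ndarray,
    rank: int,
    n_iter: int = 200,
    seed: int = 0,
    ridge: float = 1e-9,
) -> list[np.ndarray]:
    """Masked CP-ALS on a 3-way array; returns the three factor matrices."""
    rng = np.random.default_rng(seed)
    shape = values.shape
    w = mask.astype(float)
    y = values * w
    factors = [rng.standard_normal((s, rank)) for s in shape]
    eye = ridge * np.eye(rank)
    for _ in range(n_iter):
        for mode in range(3):
            o1, o2 = (n for n in range(3) if n != mode)
            b1, b2 = factors[o1], factors[o2]
            s = np.einsum(
                "ijk,jr,js,kr,ks->irs",
                np.moveaxis(w, mode, 0), b1, b1, b2, b2,
                optimize=True,
            )
            t = np.einsum(
                "ijk,jr,kr->ir", np.moveaxis(y, mode, 0), b1, b2, optimize=True
            )
            factors[mode] = np.linalg.solve(s + eye, t[..., None])[..., 0]
    return factors


def compose(factors: list[np.ndarray]) -> np.ndarray:
    a, b, c = factors
    return np.einsum("ir,jr,kr->ijk", a, b, c)
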