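"""Procrustes comparison of two ordinations with Monte-Carlo significance.

Symmetric (scaled) Procrustes: both configurations are centered and scaled
to unit sum of squares before the optimal rotation, so the residual m2 lies
in [0, 1]. Significance comes from re-fitting after random row permutations
of one configuration (a protest-style Monte-Carlo test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositional_diversity import OrdinationResult
from .core_data import DataError


@dataclass
class ProcrustesResult:
    m2: float
    t_statistic: float  # sqrt(1 - m2)
    p_value: float
    n_permutations: int
    n_axes: int
    seed: int


def _standardize(coords: np.ndarray) -> np.ndarray:
    x = coords - coords.mean(axis=0, keepdims=True)
    norm = np.sqrt((x**2).sum())
    if norm == 0:
        raise DataError("degenerate configuration: all points identical")
    return x / norm


def _m2(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Procrustes residual of two standardized configurations."""
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(
    ord_a: OrdinationResult,
    ord_b: OrdinationResult,
    n_axes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Test spatial congruence of two ordinations over the same samples.

    ``n_axes`` defaults to all axes available in both ordinations.
    """
    if ord_a.sample_ids != ord_b.sample_ids:
        diff = set(ord_a.sample_ids) ^ set(ord_b.sample_ids)
        if diff:
            raise DataError(f"ordination rosters differ: {sorted(diff)}")
        raise DataError("ordination sample orderings differ")
    available = min(ord_a.n_axes, ord_b.n_axes)
    if n_axes is None:
        n_axes = available
    if n_axes < 2:
        raise DataError("procrustes_test needs at least 2 axes")
    if n_axes > available:
        raise DataError(f"n_axes={n_axes} exceeds available axes ({available})")

    a = _standardize(ord_a.coordinates[:, :n_axes])
    b = _standardize(ord_b.coordinates[:, :n_axes])
    m2_obs = _m2(a, b)

    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _m2(a, b[perm]) <= m2_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProcrustesResult(
        m2=m2_obs,
        t_statistic=float(np.sqrt(max(0.0, 1.0 - m2_obs))),
        p_value=float(p),
        n_permutations=n_perm,
        n_axes=n_axes,
        seed=seed,
    )
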