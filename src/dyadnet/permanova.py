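"""Permutational multivariate ANOVA of a distance matrix against design terms.

Sequential (Type-I) sums of squares: terms enter the model in the caller's
order, so each term is adjusted for everything before it. Significance by
free permutation of sample labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DataError, DistanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class PermanovaResult:
    terms: list[str]
    df: list[int]
    ss: list[float]
    pseudo_f: list[float]
    p_values: list[float]
    ss_residual: float
    df_residual: int
    ss_total: float
    n_permutations: int
    seed: int
    n_samples: int = 0
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "df": d, "SS": s, "pseudo_F": f, "p": p}
            for t, d, s, f, p in zip(self.terms, self.df, self.ss,
                                     self.pseudo_f, self.p_values)
        ]
        rows.append({"term": "Residual", "df": self.df_residual,
                     "SS": self.ss_residual, "pseudo_F": np.nan, "p": np.nan})
        rows.append({"term": "Total", "df": self.df_residual + sum(self.df),
                     "SS": self.ss_total, "pseudo_F": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


def _term_columns(values: pd.Series, term: str) -> np.ndarray:
    """Design columns for one term: dummies for categoricals, raw for numeric."""
    if values.dtype == bool:
        return values.to_numpy(dtype=float)[:, None]
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)[:, None]
    levels = pd.unique(values)
    if len(levels) < 2:
        raise DataError(f"term {term!r} is constant on the analyzed samples")
    # full dummy coding; rank bookkeeping below handles the redundancy
    return np.column_stack([(values == lv).to_numpy(dtype=float) for lv in levels])


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > 1e-10 * max(1.0, s.max())
    u = u[:, keep]
    return u @ u.T, int(keep.sum())


def permanova(
    dist: DistanceMatrix,
    meta: SampleMetadata,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential PERMANOVA of ``dist`` against ordered design ``terms``.

    Rows with missing term values are dropped (complete cases) and logged.
    p-values use free permutation of sample labels, deterministic for a
    given seed.
    """
    if not terms:
        raise DataError("at least one term is required")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse",
                      stacklevel=2)
    df_meta = meta.frame
    missing_cols = [t for t in terms if t not in df_meta.columns]
    if missing_cols:
        raise DataError(f"metadata missing term column(s): {missing_cols}")
    ids = [s for s in dist.sample_ids if s in meta]
    sub = df_meta.loc[ids, terms]
    complete = sub.notna().all(axis=1)
    analyzed = [s for s, ok in zip(ids, complete) if ok]
    n_dropped = dist.n_samples - len(analyzed)
    if n_dropped:
        logger.info("permanova: dropped %d incomplete/unmatched sample(s); "
                    "analyzing n=%d", n_dropped, len(analyzed))
    if len(analyzed) < 3:
        raise DataError("fewer than 3 complete-case samples")
    d = dist.subset(analyzed)
    n = d.n_samples

    # Gower-centered inner-product matrix
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d.values**2) @ j

    x = np.ones((n, 1))
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    prev_rank = 1
    for term in terms:
        cols = _term_columns(df_meta.loc[analyzed, term], term)
        if np.unique(cols, axis=0).shape[0] < 2:
            raise DataError(f"term {term!r} is constant on the analyzed samples")
        x = np.hstack([x, cols])
        h, rank = _hat(x)
        added = rank - prev_rank
        if added == 0:
            raise DataError(f"term {term!r} is collinear with earlier terms "
                            "(zero added degrees of freedom)")
        hats.append(h)
        dfs.append(added)
        prev_rank = rank

    df_res = n - prev_rank
    if df_res < 1:
        raise DataError("model is saturated: no residual degrees of freedom")

    def _stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        tr_total = float(np.trace(gmat))
        # intercept-only projection: trace((11'/n) G) = sum(G)/n
        tr_prev = float(np.sum(gmat) / n)
        sss = []
        for h in hats:
            tr_h = float(np.sum(h * gmat))
            sss.append(tr_h - tr_prev)
            tr_prev = tr_h
        ss_res = float(tr_total - tr_prev)
        sss = np.array(sss)
        fs = (sss / np.array(dfs)) / (ss_res / df_res)
        return sss, fs, ss_res

    ss_obs, f_obs, ss_res = _stats(g)
    ss_total = float(np.trace(g))

    # Permutations act on the sorted sample-id roster, so the p-value is
    # invariant to the input ordering of the samples for a given seed.
    canon = sorted(analyzed)
    pos_of = {s: i for i, s in enumerate(analyzed)}
    canon_pos = np.array([pos_of[s] for s in canon])
    rank = np.array([canon.index(s) for s in analyzed])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        sigma = rng.permutation(n)
        perm = canon_pos[sigma[rank]]
        gp = g[np.ix_(perm, perm)]
        _, f_perm, _ = _stats(gp)
        # relative tolerance: permutations reproducing the observed
        # partition must count as ties despite trace-summation noise
        exceed += f_perm >= f_obs - 1e-8 * np.maximum(1.0, np.abs(f_obs))
    p = (exceed + 1) / (n_perm + 1)

    return PermanovaResult(
        terms=list(terms),
        df=dfs,
        ss=[float(v) for v in ss_obs],
        pseudo_f=[float(v) for v in f_obs],
        p_values=[float(v) for v in p],
        ss_residual=ss_res,
        df_residual=df_res,
        ss_total=ss_total,
        n_permutations=n_perm,
        seed=seed,
        n_samples=n,
        n_dropped=n_dropped,
    )
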