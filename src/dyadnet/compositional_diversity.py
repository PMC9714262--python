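"""CLR normalisation, alpha diversity, beta diversity, and PCoA.

Aitchison distance is the Euclidean distance between CLR-transformed
samples; Bray-Curtis works on proportions; unweighted UniFrac on
presence/absence against a rooted, branch-length-annotated tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_data import DataError, DistanceMatrix, TaxaTable, to_relative

logger = logging.getLogger(__name__)

BETA_METRICS = ("aitchison", "bray_curtis", "unweighted_unifrac")
ALPHA_METRICS = ("shannon", "simpson")


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    Axes are ordered by non-increasing eigenvalue; only positive-eigenvalue
    axes are retained.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def clr_transform(table: TaxaTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform: ln(c + pc) minus its per-sample mean.

    Returns a taxa x samples real matrix whose columns sum to zero.
    """
    if table.scale != "counts":
        raise DataError("clr_transform expects a counts-scale table")
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    logc = np.log(table.counts + pseudocount)
    return logc - logc.mean(axis=0, keepdims=True)


def alpha_diversity(table: TaxaTable, metric: str) -> dict[str, float]:
    """Per-sample Shannon entropy (natural log) or Simpson's 1 - sum(p^2)."""
    if metric not in ALPHA_METRICS:
        raise DataError(f"unknown alpha metric {metric!r}; expected {ALPHA_METRICS}")
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise DataError(f"zero-total sample(s): {', '.join(bad)}")
    p = table.counts / totals
    if metric == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(p), 0.0)
        vals = terms.sum(axis=0)
    else:
        vals = 1.0 - (p**2).sum(axis=0)
    return dict(zip(table.sample_ids, vals.astype(float)))


def beta_diversity(
    table: TaxaTable,
    metric: str,
    pseudocount: float = 1.0,
    tree=None,
) -> DistanceMatrix:
    """Pairwise sample dissimilarities under a named metric.

    ``tree`` (unweighted_unifrac only): a rooted ``skbio.TreeNode`` or a
    newick string/path accepted by :func:`read_tree`; its tips must cover
    every taxon with a nonzero count.
    """
    if metric == "aitchison":
        clr = clr_transform(table, pseudocount)
        vals = squareform(pdist(clr.T, metric="euclidean"))
    elif metric == "bray_curtis":
        rel = table if table.scale == "relative" else to_relative(table)
        p = rel.counts.T  # samples x taxa
        num = np.abs(p[:, None, :] - p[None, :, :]).sum(axis=2)
        den = (p[:, None, :] + p[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            vals = np.where(den > 0, num / den, 0.0)
        np.fill_diagonal(vals, 0.0)
    elif metric == "unweighted_unifrac":
        vals = _unweighted_unifrac(table, tree)
    else:
        raise DataError(f"unknown beta metric {metric!r}; expected {BETA_METRICS}")
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry against fp noise
    return DistanceMatrix(table.sample_ids, metric, vals)


def read_tree(source):
    """Read a rooted newick tree (path or string) as an ``skbio.TreeNode``."""
    from skbio import TreeNode

    if hasattr(source, "traverse"):
        return source
    import io
    import os

    text = None
    if isinstance(source, (str, bytes)) and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    return TreeNode.read(io.StringIO(text))


def _unweighted_unifrac(table: TaxaTable, tree) -> np.ndarray:
    from skbio.diversity import beta_diversity as skbio_beta

    if tree is None:
        raise DataError("unweighted_unifrac requires a tree")
    tree = read_tree(tree)
    tips = {t.name for t in tree.tips()}
    present = np.asarray(table.counts).sum(axis=1) > 0
    missing = [t for t, keep in zip(table.taxa_ids, present) if keep and t not in tips]
    if missing:
        raise DataError(f"taxa missing from tree: {', '.join(missing)}")
    keep_idx = [i for i, t in enumerate(table.taxa_ids) if table.taxa_ids[i] in tips]
    counts = (np.asarray(table.counts)[keep_idx, :] >= 1).astype(int).T
    taxa = [table.taxa_ids[i] for i in keep_idx]
    dm = skbio_beta("unweighted_unifrac", counts, ids=table.sample_ids,
                    taxa=taxa, tree=tree, validate=True)
    return np.asarray(dm.data, dtype=float)


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Negative-eigenvalue axes are discarded; their total magnitude is logged
    so Bray-Curtis ordinations are explicit about distortion.
    """
    n = dist.n_samples
    if n < 3:
        raise DataError("pcoa needs at least 3 samples")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, float(abs(eigvals).max()))
    pos = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    if neg_mass > 0:
        logger.info("pcoa discarded negative eigenvalues totalling %.4g "
                    "(%.2f%% of positive mass)", neg_mass,
                    100 * neg_mass / eigvals[pos].sum())
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    props = eigvals[pos] / eigvals[pos].sum()
    return OrdinationResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals[pos],
        proportion_explained=props,
    )
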