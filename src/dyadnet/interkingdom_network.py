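"""Bipartite bacteria-fungus co-abundance networks and connectedness.

Taxa of each kingdom are prevalence-filtered ("present in at least 30% of
samples", boundary inclusive), abundances converted to proportions, and
every bacteria x fungus pair scored by Spearman correlation. Edges with an
uncorrected p below alpha are retained; connectedness is the number of
significant edges divided by the number of nodes, with the node roster
being ALL prevalence-filtered taxa of both kingdoms regardless of degree
(an edgeless taxon still counts — this keeps connectedness comparable
across subgroups with the same roster; a connected-nodes-only denominator
is available via ``connectedness_over``).

No multiple-testing correction is applied to edges by default. With
hundreds of candidate pairs the expected number of false edges at
alpha=0.05 is substantial; an optional Benjamini-Hochberg mode is provided
for users who want corrected networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError, TaxaTable, to_relative

logger = logging.getLogger(__name__)


@dataclass
class NetworkEdge:
    bact: str
    fung: str
    rho: float
    p: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


@dataclass
class InterkingdomNetwork:
    bact_nodes: list[str]
    fung_nodes: list[str]
    edges: list[NetworkEdge]
    n_samples: int
    alpha: float
    label: str = ""

    @property
    def nodes(self) -> list[str]:
        return self.bact_nodes + self.fung_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.bact_nodes) + len(self.fung_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def connectedness(self) -> float:
        """Significant edges per node, over the full filtered roster."""
        return self.n_edges / self.n_nodes

    def connectedness_over(self, node_mode: str = "all") -> float:
        if node_mode == "all":
            return self.connectedness
        if node_mode == "connected":
            touched = {e.bact for e in self.edges} | {e.fung for e in self.edges}
            if not touched:
                return 0.0
            return self.n_edges / len(touched)
        raise DataError(f"unknown node_mode {node_mode!r}")

    def degrees(self) -> dict[str, int]:
        """Interkingdom degree of every node in the roster (0 if edgeless)."""
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.bact] += 1
            deg[e.fung] += 1
        return deg

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"bact": e.bact, "fung": e.fung, "rho": e.rho, "p": e.p,
              "sign": e.sign} for e in self.edges],
            columns=["bact", "fung", "rho", "p", "sign"],
        )

    def to_edge_tsv(self, path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = self.to_networkx()
        nx.write_graphml(g, path)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.bact_nodes:
            g.add_node(n, kingdom="bacteria")
        for n in self.fung_nodes:
            g.add_node(n, kingdom="fungi")
        for e in self.edges:
            g.add_edge(e.bact, e.fung, rho=e.rho, p=e.p, sign=e.sign)
        return g


def prevalence_filter(table: TaxaTable, min_prevalence: float = 0.30) -> TaxaTable:
    """Keep taxa present (count >= 1) in at least ``min_prevalence`` of samples."""
    if table.scale != "counts":
        raise DataError("prevalence_filter expects a counts-scale table")
    if not 0 < min_prevalence <= 1:
        raise DataError("min_prevalence must be in (0, 1]")
    presence = (table.counts >= 1).sum(axis=1) / table.n_samples
    keep = [t for t, pr in zip(table.taxa_ids, presence) if pr >= min_prevalence]
    dropped = table.n_taxa - len(keep)
    if not keep:
        raise DataError(
            f"prevalence filter at {min_prevalence:.0%} removed all "
            f"{table.n_taxa} {table.kingdom} taxa"
        )
    if dropped:
        logger.info("prevalence filter (%.0f%%) dropped %d of %d %s taxa",
                    100 * min_prevalence, dropped, table.n_taxa, table.kingdom)
    return table.select_taxa(keep)


def spearman_edge(x: np.ndarray, y: np.ndarray,
                  exact: bool = False) -> tuple[float, float]:
    """Tie-corrected Spearman rho and its two-sided p-value.

    The default p uses the t-approximation (the regime of the analyses this
    serves, n ~ 70-100). ``exact=True`` enumerates the full permutation
    null of the rank pairing instead; only feasible for n <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("spearman_edge expects two equal-length vectors")
    n = x.size
    if n < 4:
        raise DataError("spearman_edge needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) > 1.0 - 1e-12:  # clamp fp noise so perfect monotone -> p=0
        rho = float(np.copysign(1.0, rho))
    if exact:
        if n > 8:
            raise DataError("exact enumeration limited to n <= 8")
        from itertools import permutations

        rx_c = (rx - rx.mean()) / (rx.std() * n)
        ry_c = ry - ry.mean()
        denom = ry.std()
        hits = total = 0
        for perm in permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / denom
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, hits / total
    return rho, _spearman_p(rho, n)


def _spearman_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def build_network(
    bact: TaxaTable,
    fung: TaxaTable,
    alpha: float = 0.05,
    min_prevalence: float = 0.30,
    renormalize_after_filter: bool = False,
    bh_correct: bool = False,
    label: str = "",
) -> InterkingdomNetwork:
    """Build the bipartite co-abundance network from sample-aligned tables.

    Proportions default to the full-table composition before filtering
    (``renormalize_after_filter=True`` recomputes them within the filtered
    taxon set). ``bh_correct`` thresholds BH-adjusted edge q-values at
    ``alpha`` instead of raw p-values.
    """
    if bact.sample_ids != fung.sample_ids:
        raise DataError("tables are not sample-aligned (ids or order differ)")
    n = bact.n_samples
    if n < 4:
        raise DataError("need at least 4 shared samples to build a network")

    bact_f = prevalence_filter(bact, min_prevalence)
    fung_f = prevalence_filter(fung, min_prevalence)
    if renormalize_after_filter:
        prop_b = to_relative(bact_f).counts
        prop_f = to_relative(fung_f).counts
    else:
        # proportions on the full table, then restricted to the filtered taxa
        # (the restricted rows need not sum to 1, so keep plain arrays)
        full_b = to_relative(bact).counts
        full_f = to_relative(fung).counts
        pos_b = {t: i for i, t in enumerate(bact.taxa_ids)}
        pos_f = {t: i for i, t in enumerate(fung.taxa_ids)}
        prop_b = full_b[[pos_b[t] for t in bact_f.taxa_ids], :]
        prop_f = full_f[[pos_f[t] for t in fung_f.taxa_ids], :]

    # rank-transform once per taxon, then correlate all pairs at once
    rb = np.apply_along_axis(stats.rankdata, 1, prop_b)
    rf = np.apply_along_axis(stats.rankdata, 1, prop_f)
    sb = rb.std(axis=1)
    sf = rf.std(axis=1)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    rf_c = rf - rf.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rb_c @ rf_c.T) / n / np.outer(sb, sf)

    edges: list[NetworkEdge] = []
    cand: list[tuple[int, int, float, float]] = []
    for i in range(rho.shape[0]):
        if sb[i] == 0:
            continue  # constant taxon: node kept, no defined correlations
        for j in range(rho.shape[1]):
            if sf[j] == 0:
                continue
            r = float(np.clip(rho[i, j], -1.0, 1.0))
            cand.append((i, j, r, _spearman_p(r, n)))
    if bh_correct and cand:
        from .diffabund import bh_fdr

        qs = bh_fdr([c[3] for c in cand])
        cand = [(i, j, r, q) for (i, j, r, _), q in zip(cand, qs)]
    for i, j, r, p in cand:
        if p < alpha:
            edges.append(NetworkEdge(bact_f.taxa_ids[i], fung_f.taxa_ids[j], r, p))

    return InterkingdomNetwork(
        bact_nodes=list(bact_f.taxa_ids),
        fung_nodes=list(fung_f.taxa_ids),
        edges=edges,
        n_samples=n,
        alpha=alpha,
        label=label,
    )


def _edge_indicators(net: InterkingdomNetwork) -> np.ndarray:
    """0/1 vector over all candidate bacteria x fungus pairs (1 = edge)."""
    present = {(e.bact, e.fung) for e in net.edges}
    return np.array(
        [1.0 if (b, f) in present else 0.0
         for b in net.bact_nodes for f in net.fung_nodes]
    )


def compare_connectedness(
    net_a: InterkingdomNetwork, net_b: InterkingdomNetwork, unit: str = "pair"
) -> tuple[float, float, float]:
    """Welch t-test comparing how connected two networks are.

    The statistical unit defaults to the per-pair edge indicator (one 0/1
    observation per candidate bacteria x fungus pair): pair indicators are
    close to independent under the null, which keeps the test calibrated.
    ``unit="degree"`` instead compares per-node interkingdom degree
    distributions; node degrees share edges and that variant is
    anti-conservative on null data (kept for sensitivity analysis only).

    Returns (t, p, connectedness difference a - b). Zero-variance edge
    cases: identical constant observations give (0, 1); separated constant
    observations give (inf with the sign of the difference, 0).
    """
    if net_a.n_nodes < 2 or net_b.n_nodes < 2:
        raise DataError("compare_connectedness needs >= 2 nodes per network")
    if unit == "pair":
        da = _edge_indicators(net_a)
        db = _edge_indicators(net_b)
    elif unit == "degree":
        da = np.array(list(net_a.degrees().values()), dtype=float)
        db = np.array(list(net_b.degrees().values()), dtype=float)
    else:
        raise DataError(f"unknown unit {unit!r}; expected 'pair' or 'degree'")
    diff = net_a.connectedness - net_b.connectedness
    if da.std() == 0 and db.std() == 0:
        if da.mean() == db.mean():
            return 0.0, 1.0, diff
        return float(np.sign(da.mean() - db.mean()) * np.inf), 0.0, diff
    t, p = stats.ttest_ind(da, db, equal_var=False)
    return float(t), float(p), diff


def layout_network(net: InterkingdomNetwork, seed: int = 0) -> dict[str, np.ndarray]:
    """Deterministic Fruchterman-Reingold 2D layout of the network."""
    import networkx as nx

    if net.n_nodes == 0:
        raise DataError("cannot lay out an empty network")
    g = net.to_networkx()
    pos = nx.spring_layout(g, seed=seed, dim=2)
    out = {n: np.asarray(xy, dtype=float) for n, xy in pos.items()}
    for n, xy in out.items():
        if not np.all(np.isfinite(xy)):
            raise RuntimeError(f"non-finite layout coordinate for node {n!r}")
    return out


def connectedness_summary(networks: list[InterkingdomNetwork]) -> pd.DataFrame:
    """One row per network: label, nodes, edges, connectedness."""
    return pd.DataFrame(
        [{"label": n.label, "n_samples": n.n_samples, "n_nodes": n.n_nodes,
          "n_edges": n.n_edges, "connectedness": n.connectedness}
         for n in networks]
    )
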