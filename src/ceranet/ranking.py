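"""PageRank dominance ranking and gene-set enrichment filtering.

Every node of the integrated lncRNA-mRNA-protein network is scored by
PageRank (stationary distribution of a damped random walk; scores over all
composing nodes sum to 1).  mRNA nodes scoring at or above the mean are
"dominant"; dominant genes are then kept only if they belong to at least one
gene set enriched at the chosen FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, FrozenSet

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .networks import TypedNetwork


class RankingError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance within max_iter."""

    def __init__(self, iterations: int, residual: float, tol: float):
        self.iterations = iterations
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"PageRank did not converge: L1 residual {residual:.3e} > tol "
            f"{tol:.3e} after {iterations} iterations"
        )


@dataclass(frozen=True)
class PRConfig:
    damping: float = 0.85
    tol: float = 1e-8
    max_iter: int = 1000
    cutoff_scope: str = "all_nodes"  # or "mrna_nodes"

    def __post_init__(self) -> None:
        if not (0 < self.damping < 1):
            raise RankingError("damping must be in (0, 1)")
        if self.cutoff_scope not in ("all_nodes", "mrna_nodes"):
            raise RankingError("cutoff_scope must be all_nodes or mrna_nodes")


def pagerank(net: TypedNetwork, cfg: PRConfig | None = None) -> Dict[str, float]:
    """Power-iteration PageRank with uniform teleport over all nodes.

    Undirected edges are treated as reciprocal directed pairs; dangling-node
    mass is redistributed uniformly.  Iterates until the L1 change falls
    below ``cfg.tol``; raises :class:`ConvergenceError` otherwise.
    """
    cfg = cfg or PRConfig()
    nodes = sorted(net.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise RankingError("network is empty")
    index = {v: i for i, v in enumerate(nodes)}
    deg = np.zeros(n)
    rows, cols = [], []
    for a, b in net.graph.edges():
        ia, ib = index[a], index[b]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        deg[ia] += 1
        deg[ib] += 1
    x = np.full(n, 1.0 / n)
    d = cfg.damping
    teleport = (1.0 - d) / n
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    dangling = deg == 0
    for it in range(1, cfg.max_iter + 1):
        contrib = np.zeros(n)
        if rows.size:
            np.add.at(contrib, cols, x[rows] / deg[rows])
        dangling_mass = x[dangling].sum() / n
        x_new = teleport + d * (contrib + dangling_mass)
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < cfg.tol:
            x = x / x.sum()  # remove accumulated float drift
            return {v: float(x[index[v]]) for v in nodes}
    raise ConvergenceError(cfg.max_iter, residual, cfg.tol)


def select_dominant(
    scores: Mapping[str, float], net: TypedNetwork, cfg: PRConfig | None = None
) -> List[str]:
    """mRNA nodes with PageRank at or above the mean over the cutoff scope.

    A score exactly equal to the mean is retained.
    """
    cfg = cfg or PRConfig()
    missing = set(net.graph.nodes) - set(scores)
    if missing:
        raise RankingError(f"scores missing for nodes {sorted(missing)[:5]}")
    mrnas = net.nodes_of_type("mRNA")
    if cfg.cutoff_scope == "all_nodes":
        pool = [scores[v] for v in net.graph.nodes]
    else:
        pool = [scores[v] for v in mrnas]
    if not pool:
        return []
    mean = float(np.mean(pool))
    return sorted(g for g in mrnas if scores[g] >= mean)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    fdr: float
    members: FrozenSet[str] = field(default_factory=frozenset)


def hypergeom_enrich(
    query: Sequence[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Sequence[str],
    descriptions: Mapping[str, str] | None = None,
) -> List[EnrichmentResult]:
    """One-sided hypergeometric upper-tail enrichment with BH correction.

    Gene sets are restricted to the universe; p = P(X >= overlap) with
    X ~ Hypergeom(universe_size, set_size, query_size).
    """
    uni = set(universe)
    if not uni:
        raise RankingError("empty universe")
    q = set(query)
    if not q <= uni:
        raise RankingError("query must be a subset of the universe")
    descriptions = descriptions or {}
    terms, pvals, rows = [], [], []
    for term_id in sorted(gene_sets):
        members = frozenset(gene_sets[term_id]) & uni
        overlap = len(members & q)
        # upper tail: P(X >= overlap); sf(k-1) so overlap 0 gives p = 1
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(q)))
        terms.append(term_id)
        pvals.append(min(p, 1.0))
        rows.append((term_id, members, overlap))
    if not rows:
        return []
    fdrs = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentResult(
            term_id=term_id,
            term_name=descriptions.get(term_id, term_id),
            overlap=overlap,
            set_size=len(members),
            query_size=len(q),
            universe_size=len(uni),
            p=p,
            fdr=float(fdr),
            members=members,
        )
        for (term_id, members, overlap), p, fdr in zip(rows, pvals, fdrs)
    ]


def filter_enriched(
    dominant: Sequence[str],
    results: Iterable[EnrichmentResult],
    fdr_cut: float = 0.05,
) -> List[str]:
    """Keep dominant genes appearing in >=1 term enriched at fdr <= fdr_cut."""
    enriched_genes: Set[str] = set()
    for res in results:
        if res.fdr <= fdr_cut and res.overlap > 0:
            enriched_genes |= res.members
    return sorted(g for g in dominant if g in enriched_genes)
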