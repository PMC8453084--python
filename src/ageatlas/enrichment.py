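"""Over-representation analysis of a gene list against GMT gene sets.

A local stand-in for web-based pathway portals: each term is scored with an
exact hypergeometric upper-tail test against a user-supplied universe, and
p-values are corrected with Benjamini-Hochberg FDR. The universe should be
the set of genes actually measured upstream (the background of the
association test), not the union of the GMT terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_test",
    "bh_fdr",
    "run_ora",
]


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (a GMT line): term, free-text description, members."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            deduped = tuple(g for g in self.genes if not (g in seen or seen.add(g)))
            logger.warning(
                "gene set %r contains duplicated genes; deduplicated %d -> %d",
                self.name, len(self.genes), len(deduped),
            )
            object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation statistics for one term."""

    term: str
    term_size: int        # K: term genes inside the universe
    list_size: int        # n: query genes inside the universe
    universe_size: int    # N
    overlap: int          # k
    overlap_genes: tuple[str, ...]
    p_value: float
    q_value: float
    significant: bool = field(default=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (term <TAB> description <TAB> gene...) into gene sets."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected at least "
                    f"term, description and one gene, got {len(parts)} fields"
                )
            genes = tuple(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}: GMT line {lineno} has no genes")
            sets.append(GeneSet(parts[0], parts[1], genes))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a random size-``n`` draw (the gene list)
    from a universe of ``N`` genes and a fixed term of size ``K``.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= min(n, K) <= N)"
        )
    # sf(k-1) = P(X >= k); exact tail sum of the pmf.
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_ora(
    gene_list: Sequence[str],
    gene_sets: Sequence[GeneSet],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every term against the gene list; rank by p, attach BH q-values.

    Query genes outside the universe are dropped (count logged); term
    membership is intersected with the universe before testing.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = [g for g in dict.fromkeys(gene_list) if g in uni]
    dropped = len(set(gene_list)) - len(query)
    if dropped:
        logger.info("dropped %d query genes absent from the universe", dropped)
    if not query:
        raise ValueError("gene list empty after intersection with universe")
    qset = set(query)
    N, n = len(uni), len(query)

    raw: list[tuple[GeneSet, int, tuple[str, ...]]] = []
    for gs in gene_sets:
        members = [g for g in gs.genes if g in uni]
        hits = tuple(sorted(g for g in members if g in qset))
        raw.append((gs, len(members), hits))

    pvals = np.array(
        [hypergeometric_test(len(hits), n, K, N) for _, K, hits in raw]
    )
    qvals = bh_fdr(pvals) if len(pvals) else np.array([])

    results = [
        EnrichmentResult(
            term=gs.name,
            term_size=K,
            list_size=n,
            universe_size=N,
            overlap=len(hits),
            overlap_genes=hits,
            p_value=float(p),
            q_value=float(q),
            significant=bool(q < alpha),
        )
        for (gs, K, hits), p, q in zip(raw, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
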