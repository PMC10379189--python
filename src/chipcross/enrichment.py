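"""Over-representation analysis with the exact hypergeometric upper tail.

For a query of n genes drawn from a background of N, a term covering K
background genes and overlapping the query in k, the enrichment p-value is

    P[X >= k],  X ~ Hypergeometric(N, K, n)

computed exactly with big-integer binomial coefficients (no normal
approximation), then Benjamini-Hochberg adjusted across terms; terms with
q < alpha (default 0.05) are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TermMap",
    "EnrichmentResult",
    "EnrichmentError",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "read_term_map",
    "write_term_map",
    "write_enrichment",
]


class EnrichmentError(ValueError):
    """Raised for inconsistent counts or invalid query/background sets."""


@dataclass
class TermMap:
    """Mapping term_id -> (term_name, member gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_name, genes) in self.terms.items():
            if not genes:
                raise EnrichmentError(f"term {term_id!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def items(self):
        return self.terms.items()


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics.

    k = overlap with the query, n = query size, K = term size restricted to
    the background, N = background size.
    """

    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    significant: bool


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n).

    Summed with exact integer binomial coefficients and converted to float
    once, so deep tails keep full double precision.
    """
    if not (0 <= k <= min(n, K)):
        raise EnrichmentError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if n > N or K > N or n < 0 or K < 0:
        raise EnrichmentError(f"need n, K <= N; got n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return float(Fraction(numerator, comb(N, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    terms: TermMap,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query gene set.

    Only terms overlapping the query (k >= 1) are reported, sorted by
    (q, p, term_id).  Term gene sets are restricted to the background before
    counting.
    """
    query_set = set(query)
    background_set = set(background)
    if not query_set:
        raise EnrichmentError("query gene set is empty")
    stray = query_set - background_set
    if stray:
        raise EnrichmentError(
            f"query genes missing from background: {sorted(stray)[:10]}"
        )
    N, n = len(background_set), len(query_set)

    tested: list[tuple[str, str, int, int, float]] = []
    for term_id, (name, genes) in terms.items():
        members = genes & background_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, n, K, N)
        tested.append((term_id, name, k, K, p))

    qvals = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=name,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            q_value=float(q),
            significant=bool(q < alpha),
        )
        for (term_id, name, k, K, p), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def read_term_map(path: str) -> TermMap:
    """Read a GMT file (term, description, genes...) or two-column TSV
    (term, gene) into a :class:`TermMap`."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 3:
                term_id, name, genes = cols[0], cols[1], cols[2:]
                entry = terms.setdefault(term_id, (name, set()))
                entry[1].update(g for g in genes if g)
            elif len(cols) == 2:
                term_id, gene = cols
                entry = terms.setdefault(term_id, (term_id, set()))
                entry[1].add(gene)
            else:
                raise EnrichmentError(f"{path}:{lineno}: expected >= 2 columns")
    return TermMap(
        terms={tid: (name, frozenset(genes)) for tid, (name, genes) in terms.items()}
    )


def write_term_map(terms: TermMap, path: str) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in sorted(terms.items()):
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def write_enrichment(results: Sequence[EnrichmentResult], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "n", "K", "N", "p_value", "q_value", "significant"],
    ).to_csv(path, sep="\t", index=False)
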