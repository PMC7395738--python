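"""Over-representation analysis with Enrichr-style combined scores.

For each gene-set term the overlap with a query list is tested with the
hypergeometric (Fisher exact, upper tail) test, corrected across terms with
Benjamini-Hochberg. Terms are additionally scored by how much better their
rank (by p-value) is than expected under random queries: a null rank model
records the mean and standard deviation of every term's rank across many
random queries of the same size, giving a z-score

    z = (μ_rank − rank_observed) / σ_rank    (positive = better than expected)

and the combined score c = |ln p_adj| · z used to order the results.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from math import log, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "NullRankModel",
    "hypergeom_pvalue",
    "bh_adjust",
    "build_null_rank_model",
    "combined_score",
    "enrich",
    "enrichment_frame",
]

P_FLOOR = 1e-300
SIGMA_FLOOR = 1e-6


@dataclass
class EnrichmentRow:
    term_id: str
    overlap_genes: frozenset[str]
    k_overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p_value: float
    p_adj: float
    z: float
    combined_score: float


@dataclass
class NullRankModel:
    """Per-term expected rank (mean, sd) under random queries, per query size."""

    library_name: str
    n_random_queries: int
    seed: int
    stats: dict[int, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def bucket(self, query_size: int) -> dict[str, tuple[float, float]]:
        sizes = sorted(self.stats)
        if not sizes:
            raise ValueError("null model has no query-size buckets")
        nearest = min(sizes, key=lambda s: (abs(s - query_size), s))
        return self.stats[nearest]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "NullRankModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a NullRankModel")
        return obj


def hypergeom_pvalue(k_overlap: int, query_size: int, term_size: int, universe_size: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(universe, term, query)."""
    if not (0 <= k_overlap <= min(query_size, term_size) <= universe_size):
        raise ValueError(
            f"inconsistent counts: k={k_overlap}, query={query_size}, "
            f"term={term_size}, universe={universe_size}"
        )
    if query_size > universe_size:
        raise ValueError("query larger than universe")
    return float(hypergeom.sf(k_overlap - 1, universe_size, term_size, query_size))


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combined_score(p_adj: float, z: float) -> float:
    """Combined enrichment score: |ln(BH-adjusted p)| multiplied by the
    rank-deviation z-score (e.g. p_adj=0.01, z=2 gives |ln 0.01| * 2 = 9.210)."""
    if not 0 < p_adj <= 1:
        raise ValueError(f"p_adj must be in (0, 1], got {p_adj}")
    return abs(log(p_adj)) * z


def _term_arrays(library: GeneSetLibrary, universe: frozenset[str] | set[str]):
    """Terms restricted to the universe; drops terms with no gene in it."""
    term_ids, term_sets = [], []
    for term in sorted(library.terms):
        genes = library.terms[term] & universe
        if genes:
            term_ids.append(term)
            term_sets.append(genes)
    return term_ids, term_sets


def _pvalues_and_ranks(query: set[str], term_ids, term_sets, universe_size: int):
    """p per term (k >= 0 terms included with p computed from k) and 1-based
    ranks by p ascending; terms with tied p share their average rank so that
    exchangeable terms have identical null rank distributions."""
    q = len(query)
    ks = np.array([len(query & t) for t in term_sets])
    ts = np.array([len(t) for t in term_sets])
    ps = hypergeom.sf(ks - 1, universe_size, ts, q)
    ranks = rankdata(ps, method="average")
    return ks, ts, ps, ranks


def build_null_rank_model(
    library: GeneSetLibrary,
    query_sizes: list[int],
    n_random: int = 1000,
    seed: int = 0,
    universe: set[str] | frozenset[str] | None = None,
) -> NullRankModel:
    """Simulate the expected rank of every term under random queries.

    For each query size, ``n_random`` queries are drawn uniformly without
    replacement from the universe (default: the library universe); terms are
    ranked by p ascending (tied p-values share their average rank) and
    per-term rank mean and sd are recorded, with an sd floor of 1e-6.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if n_random < 10:
        raise ValueError(f"n_random must be >=10, got {n_random}")
    uni = frozenset(universe) if universe is not None else library.universe
    term_ids, term_sets = _term_arrays(library, uni)
    uni_list = np.array(sorted(uni))
    rng = np.random.default_rng(seed)

    stats: dict[int, dict[str, tuple[float, float]]] = {}
    for qsize in sorted(set(query_sizes)):
        if qsize < 1 or qsize > len(uni_list):
            raise ValueError(f"query size {qsize} infeasible for universe of {len(uni_list)}")
        all_ranks = np.empty((n_random, len(term_ids)))
        for i in range(n_random):
            query = set(rng.choice(uni_list, size=qsize, replace=False))
            _, _, _, ranks = _pvalues_and_ranks(query, term_ids, term_sets, len(uni_list))
            all_ranks[i] = ranks
        mu = all_ranks.mean(axis=0)
        sigma = np.maximum(all_ranks.std(axis=0, ddof=1) if n_random > 1 else 0.0, SIGMA_FLOOR)
        stats[qsize] = {t: (float(m), float(s)) for t, m, s in zip(term_ids, mu, sigma)}
    return NullRankModel(
        library_name=library.name, n_random_queries=n_random, seed=seed, stats=stats
    )


def enrich(
    query: set[str] | frozenset[str],
    library: GeneSetLibrary,
    universe: set[str] | frozenset[str],
    null_model: NullRankModel | None = None,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in every term of ``library``.

    Query genes outside the universe are dropped with a warning; term genes
    are intersected with the universe. One row is returned per term with
    overlap >= 1: hypergeometric p, BH adjustment across the tested terms,
    rank-deviation z against ``null_model`` (or a closed-form uniform-rank
    null when no model is supplied) and the combined score |ln p_adj| * z.
    Rows are sorted by combined score descending, ties by term id.
    """
    if not query:
        raise ValueError("query is empty")
    uni = frozenset(universe)
    q = frozenset(g.upper() for g in query) & uni
    dropped = len(query) - len(q)
    if dropped:
        logger.warning("%d query genes outside the universe were dropped", dropped)
    if not q:
        raise ValueError("query is empty after intersecting with the universe")

    term_ids, term_sets = _term_arrays(library, uni)
    if not term_ids:
        return []
    ks, ts, ps, ranks = _pvalues_and_ranks(set(q), term_ids, term_sets, len(uni))

    hit = ks >= 1
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return []
    p_adj = bh_adjust(ps[idx])

    if null_model is not None:
        bucket = null_model.bucket(len(q))
    else:
        # uniform-rank null over T terms: mu = (T+1)/2, sigma = sqrt((T^2-1)/12)
        T = len(term_ids)
        mu0 = (T + 1) / 2.0
        sd0 = max(sqrt((T * T - 1) / 12.0), SIGMA_FLOOR)
        bucket = {t: (mu0, sd0) for t in term_ids}

    rows = []
    for j, i in enumerate(idx):
        term = term_ids[i]
        mu, sigma = bucket.get(term, (np.nan, np.nan))
        if not np.isfinite(mu):
            raise ValueError(f"null model has no statistics for term {term!r}")
        z = (mu - ranks[i]) / sigma
        pa = max(float(p_adj[j]), P_FLOOR)
        rows.append(
            EnrichmentRow(
                term_id=term,
                overlap_genes=frozenset(set(q) & term_sets[i]),
                k_overlap=int(ks[i]),
                query_size=len(q),
                term_size=int(ts[i]),
                universe_size=len(uni),
                p_value=float(ps[i]),
                p_adj=pa,
                z=float(z),
                combined_score=combined_score(pa, float(z)),
            )
        )
    rows.sort(key=lambda r: (-r.combined_score, r.term_id))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per term)."""
    cols = ["term", "overlap", "k", "query", "term_size", "universe", "p", "p_adj", "z", "combined_score"]
    recs = [
        {
            "term": r.term_id,
            "overlap": ",".join(sorted(r.overlap_genes)),
            "k": r.k_overlap,
            "query": r.query_size,
            "term_size": r.term_size,
            "universe": r.universe_size,
            "p": r.p_value,
            "p_adj": r.p_adj,
            "z": r.z,
            "combined_score": r.combined_score,
        }
        for r in rows
    ]
    return pd.DataFrame(recs, columns=cols)
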