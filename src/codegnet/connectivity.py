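"""Connectivity-map-style matching of a query signature against drug signatures.

Each drug carries an up-set and a down-set of genes. The connectivity score
between a query (q_up, q_down) and a drug (d_up, d_down) is a signed Jaccard
statistic

    score = 1/2 [ (J(q_up, d_up) + J(q_down, d_down))
                − (J(q_up, d_down) + J(q_down, d_up)) ]          in [−1, +1]

with J the Jaccard index (J = 0 for an empty union). A score of +1 means the
drug exactly mimics the query signature (it could push cells toward the
disease state); −1 means it exactly reverses it (a repurposing candidate).
Drugs are statistically associated with the query by the hypergeometric
upper-tail test on the best of the four quadrant overlaps, Bonferroni-scaled
by 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .enrichment import hypergeom_pvalue

__all__ = [
    "DrugSignatureLibrary",
    "ConnectivityResult",
    "connectivity_score",
    "rank_drugs",
    "connectivity_frame",
]


@dataclass
class DrugSignatureLibrary:
    """Drug -> (up-set, down-set) signature collection."""

    drugs: dict[str, tuple[frozenset[str], frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        clean = {}
        uni = set(self.universe)
        for drug, (up, down) in self.drugs.items():
            up = frozenset(g.upper() for g in up)
            down = frozenset(g.upper() for g in down)
            if up & down:
                raise ValueError(f"drug {drug!r}: up/down sets overlap")
            uni |= up | down
            clean[drug] = (up, down)
        self.drugs = clean
        self.universe = frozenset(g.upper() for g in uni)

    @classmethod
    def from_paired_gmt(cls, up_library, down_library, universe=frozenset()) -> "DrugSignatureLibrary":
        """Build from paired GMT libraries with ``<drug>__up`` / ``<drug>__down`` terms."""
        drugs: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
        ups = {t[: -len("__up")]: g for t, g in up_library.terms.items() if t.endswith("__up")}
        downs = {t[: -len("__down")]: g for t, g in down_library.terms.items() if t.endswith("__down")}
        for drug in sorted(set(ups) | set(downs)):
            drugs[drug] = (ups.get(drug, frozenset()), downs.get(drug, frozenset()))
        return cls(drugs=drugs, universe=frozenset(universe))

    def __len__(self) -> int:
        return len(self.drugs)


@dataclass
class ConnectivityResult:
    drug: str
    score: float
    p_value: float
    overlaps: dict[str, frozenset[str]] = field(default_factory=dict)


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def connectivity_score(
    query_up: set[str] | frozenset[str],
    query_down: set[str] | frozenset[str],
    drug_up: set[str] | frozenset[str],
    drug_down: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    drug: str = "",
) -> ConnectivityResult:
    """Signed-Jaccard connectivity between a query and one drug signature."""
    q_up, q_down = frozenset(query_up), frozenset(query_down)
    d_up, d_down = frozenset(drug_up), frozenset(drug_down)
    if not q_up or not q_down:
        raise ValueError("query up and down sets must both be non-empty")
    if q_up & q_down:
        raise ValueError("query up/down sets overlap")
    if d_up & d_down:
        raise ValueError(f"drug {drug!r}: up/down sets overlap")
    uni = frozenset(universe) | q_up | q_down | d_up | d_down

    score = 0.5 * (
        (_jaccard(q_up, d_up) + _jaccard(q_down, d_down))
        - (_jaccard(q_up, d_down) + _jaccard(q_down, d_up))
    )

    overlaps = {
        "up_up": q_up & d_up,
        "down_down": q_down & d_down,
        "up_down": q_up & d_down,
        "down_up": q_down & d_up,
    }
    quadrants = [(q_up, d_up), (q_down, d_down), (q_up, d_down), (q_down, d_up)]
    p_best = 1.0
    for q, d in quadrants:
        if d:
            p_best = min(p_best, hypergeom_pvalue(len(q & d), len(q), len(d), len(uni)))
    p_value = min(1.0, 4.0 * p_best)  # Bonferroni over the four quadrant tests
    return ConnectivityResult(drug=drug, score=float(score), p_value=float(p_value), overlaps=overlaps)


def rank_drugs(
    query_up: set[str] | frozenset[str],
    query_down: set[str] | frozenset[str],
    library: DrugSignatureLibrary,
) -> tuple[list[ConnectivityResult], list[ConnectivityResult]]:
    """Score every drug in the library against the query.

    Returns ``(reversers, mimics)``: the same results ordered by score
    ascending (reversal candidates first) and descending (mimics first);
    ties broken by p-value then drug name.
    """
    if len(library) == 0:
        raise ValueError("drug library is empty")
    results = [
        connectivity_score(query_up, query_down, up, down, library.universe, drug=drug)
        for drug, (up, down) in sorted(library.drugs.items())
    ]
    reversers = sorted(results, key=lambda r: (r.score, r.p_value, r.drug))
    mimics = sorted(results, key=lambda r: (-r.score, r.p_value, r.drug))
    return reversers, mimics


def connectivity_frame(results: list[ConnectivityResult]) -> pd.DataFrame:
    recs = [
        {
            "drug": r.drug,
            "score": r.score,
            "p_value": r.p_value,
            "n_up_up": len(r.overlaps.get("up_up", ())),
            "n_down_down": len(r.overlaps.get("down_down", ())),
            "n_up_down": len(r.overlaps.get("up_down", ())),
            "n_down_up": len(r.overlaps.get("down_up", ())),
        }
        for r in results
    ]
    return pd.DataFrame(recs, columns=["drug", "score", "p_value", "n_up_up", "n_down_down", "n_up_down", "n_down_up"])
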