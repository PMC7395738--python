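"""Cross-study co-DEG consensus.

A gene is a co-DEG when it appears in the up (or down) list of at least
``min_support`` independent studies of the same category; genes supported by
a single study only are filtered out. A gene meeting the support threshold
in BOTH directions is flagged as conflicting and excluded from both
consensus sets, keeping downstream enrichment direction-pure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .chdir import GeneSignature
from .data_io import StudyCategory

__all__ = ["CoDEGSet", "compute_codegs", "support_table"]


@dataclass
class CoDEGSet:
    """Consensus co-up/co-down genes with per-gene study support."""

    category: StudyCategory
    co_up: frozenset[str]
    co_down: frozenset[str]
    support: dict[str, tuple[int, int]]  # gene -> (n_up_studies, n_down_studies)
    conflicting: frozenset[str] = field(default_factory=frozenset)
    min_support: int = 2
    n_studies: int = 0


def compute_codegs(signatures: list[GeneSignature], min_support: int = 2) -> CoDEGSet:
    """Compute consensus co-DEGs from per-study signatures of one category."""
    if len(signatures) < 2:
        raise ValueError(f"need >=2 signatures, got {len(signatures)}")
    categories = {s.category for s in signatures}
    if len(categories) > 1:
        raise ValueError(f"mixed study categories: {sorted(c.value for c in categories)}")
    if min_support < 1:
        raise ValueError("min_support must be >=1")

    n_up: Counter[str] = Counter()
    n_down: Counter[str] = Counter()
    for sig in signatures:
        n_up.update(sig.up_genes)
        n_down.update(sig.down_genes)

    seen = set(n_up) | set(n_down)
    support = {g: (n_up[g], n_down[g]) for g in sorted(seen)}
    up = {g for g in seen if n_up[g] >= min_support}
    down = {g for g in seen if n_down[g] >= min_support}
    conflicting = up & down
    return CoDEGSet(
        category=categories.pop(),
        co_up=frozenset(up - conflicting),
        co_down=frozenset(down - conflicting),
        support=support,
        conflicting=frozenset(conflicting),
        min_support=min_support,
        n_studies=len(signatures),
    )


def support_table(codegs: CoDEGSet) -> pd.DataFrame:
    """Tabulate per-gene support: (gene, n_up, n_down, status).

    Status is one of ``co_up``, ``co_down``, ``conflicting`` or ``single``.
    Rows are sorted by max support descending, then symbol ascending.
    """
    rows = []
    for gene, (nu, nd) in codegs.support.items():
        if gene in codegs.conflicting:
            status = "conflicting"
        elif gene in codegs.co_up:
            status = "co_up"
        elif gene in codegs.co_down:
            status = "co_down"
        else:
            status = "single"
        rows.append({"gene": gene, "n_up": nu, "n_down": nd, "status": status})
    df = pd.DataFrame(rows, columns=["gene", "n_up", "n_down", "status"])
    if not df.empty:
        df["_max"] = df[["n_up", "n_down"]].max(axis=1)
        df = df.sort_values(["_max", "gene"], ascending=[False, True]).drop(columns="_max")
        df = df.reset_index(drop=True)
    return df
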