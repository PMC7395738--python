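"""Characteristic Direction (CD) differential expression.

CD treats two-class differential expression geometrically: the genes are
ranked by the components of the unit vector normal to the best linear
separating hyperplane between cases and controls,

    b  ∝  Σ̂γ⁻¹ (μ̄_case − μ̄_control),      Σ̂γ = γ Σ̂ + (1 − γ) ν I,

where Σ̂ is the pooled within-class sample covariance, ν its mean diagonal
element and γ ∈ (0, 1] a shrinkage weight pulling the covariance toward the
sphere ν I. With far more genes than samples Σ̂ is rank-deficient, so the
solve is carried out in the PCA subspace spanned by the within-class-centred
data and mapped back to gene space: directions outside that subspace carry
sample variance 0 and are scaled by 1 / ((1 − γ) ν). The result is
L2-normalised and oriented so that positive components mean higher
expression in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionStudy, StudyCategory

logger = logging.getLogger(__name__)

__all__ = ["CDResult", "GeneSignature", "characteristic_direction", "signature_from_cd"]

DEFAULT_GAMMA = 0.5
MAX_COMPONENTS = 30
DEFAULT_CUTOFF = 500


@dataclass
class CDResult:
    """Unit-norm characteristic direction for one study.

    ``coefficients`` maps every gene of the study to its signed component
    (positive = higher in cases); ``n_components`` is the PCA dimension the
    solve was carried out in.
    """

    study_id: str
    coefficients: dict[str, float]
    gamma: float
    n_components: int
    category: StudyCategory = StudyCategory.CANCER_VS_NORMAL

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(list(self.coefficients.values())))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"{self.study_id}: coefficient vector norm {norm} != 1")


@dataclass
class GeneSignature:
    """Fixed-size up/down gene lists for one study, ranked by |CD component|."""

    study_id: str
    up_genes: list[str]
    down_genes: list[str]
    scores: dict[str, float]
    category: StudyCategory = StudyCategory.CANCER_VS_NORMAL

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError(f"{self.study_id}: up/down lists overlap")
        if any(self.scores[g] <= 0 for g in self.up_genes):
            raise ValueError(f"{self.study_id}: up gene with non-positive score")
        if any(self.scores[g] >= 0 for g in self.down_genes):
            raise ValueError(f"{self.study_id}: down gene with non-negative score")


def characteristic_direction(
    study: ExpressionStudy,
    gamma: float = DEFAULT_GAMMA,
    n_components: int | None = None,
) -> CDResult:
    """Compute the characteristic direction of one case/control study.

    Parameters
    ----------
    study
        Expression matrix (log2 scale) with >=2 samples per class.
    gamma
        Shrinkage weight in (0, 1]. Small values pull the covariance toward
        the sphere ν I, so the direction approaches the raw mean difference;
        gamma=1 uses the (pseudo-inverted) pooled covariance alone.
    n_components
        PCA dimension of the solve; default ``min(n_samples − 2, 30)``,
        capped at the rank of the centred data.

    Raises
    ------
    ValueError
        If a class has fewer than two samples, gamma is outside (0, 1], or
        the input is degenerate (zero within-class variance, or identical
        class means giving no discriminating direction).
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    case_idx, ctl_idx = study.case_indices, study.control_indices
    n1, n2 = len(case_idx), len(ctl_idx)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"{study.study_id}: need >=2 samples per class (got {n1}/{n2})")
    X = study.values
    n_genes = X.shape[0]
    if n_genes < 2:
        raise ValueError(f"{study.study_id}: need >=2 genes")

    Xc, Xn = X[:, case_idx], X[:, ctl_idx]
    d = Xc.mean(axis=1) - Xn.mean(axis=1)
    # within-class centred data, samples x genes
    W = np.concatenate(
        [(Xc - Xc.mean(axis=1, keepdims=True)).T, (Xn - Xn.mean(axis=1, keepdims=True)).T]
    )
    dof = n1 + n2 - 2
    nu = float((W**2).sum()) / (dof * n_genes)  # mean diagonal of pooled covariance
    if nu <= 0.0:
        raise ValueError(f"{study.study_id}: degenerate input (zero within-class variance)")
    if not np.any(d):
        raise ValueError(f"{study.study_id}: degenerate input (identical class means)")

    k_req = n_components if n_components is not None else min(n1 + n2 - 2, MAX_COMPONENTS)
    if k_req < 1:
        raise ValueError(f"n_components must be >=1, got {k_req}")

    _, s, Vt = np.linalg.svd(W, full_matrices=False)
    tol = s[0] * max(W.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = min(k_req, rank)
    V = Vt[:k].T  # genes x k, PCA basis of the centred data
    lam = s[:k] ** 2 / dof  # pooled-covariance eigenvalues in that basis

    d_proj = V.T @ d
    b = V @ (d_proj / (gamma * lam + (1.0 - gamma) * nu))
    complement_scale = (1.0 - gamma) * nu
    if complement_scale > 0.0:
        b = b + (d - V @ d_proj) / complement_scale
    # else gamma == 1 with rank-deficient covariance: pseudo-inverse solve,
    # the out-of-subspace component of d is dropped

    norm = float(np.linalg.norm(b))
    if norm == 0.0:
        raise ValueError(f"{study.study_id}: degenerate input (zero direction)")
    b = b / norm

    # orient: the gene with the largest case-upregulated mean difference gets
    # a positive coefficient (fall back to sign(b.d) if that component is ~0)
    gstar = int(np.argmax(d)) if np.any(d > 0) else int(np.argmin(d))
    target = np.sign(d[gstar])
    if abs(b[gstar]) > 1e-12:
        if np.sign(b[gstar]) != target:
            b = -b
    elif float(b @ d) < 0.0:
        b = -b

    return CDResult(
        study_id=study.study_id,
        coefficients={g: float(v) for g, v in zip(study.genes, b)},
        gamma=gamma,
        n_components=k,
        category=study.category,
    )


def signature_from_cd(cd: CDResult, cutoff: int = DEFAULT_CUTOFF) -> GeneSignature:
    """Convert a CD result into fixed-size up/down lists.

    Genes are ranked by |coefficient| descending (ties broken
    lexicographically by symbol); the top ``cutoff`` genes overall are kept
    and split by sign, preserving rank order. Genes with a coefficient of
    exactly zero are never assigned to either list. If ``cutoff`` exceeds the
    gene count, all genes are used and a warning is logged.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >=1, got {cutoff}")
    items = sorted(cd.coefficients.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    if cutoff > len(items):
        logger.warning(
            "%s: cutoff %d exceeds gene count %d, using all genes",
            cd.study_id, cutoff, len(items),
        )
    top = items[:cutoff]
    up = [g for g, v in top if v > 0]
    down = [g for g, v in top if v < 0]
    return GeneSignature(
        study_id=cd.study_id,
        up_genes=up,
        down_genes=down,
        scores={g: v for g, v in top if v != 0},
        category=cd.category,
    )
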