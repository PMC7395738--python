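"""Synthetic multi-study expression data with known ground truth.

The generator emulates the structure of a cross-study meta-analysis: several
independent case/control studies share a planted set of co-upregulated and
co-downregulated genes, each study adds its own private differential genes,
and the planted co-DEGs are wired to known upstream regulators — a set of
transcription factors whose target sets are drawn from the planted co-DEGs,
a hub protein connecting those TFs in the background PPI, and kinases whose
substrate sets cover the hub and the TFs. A drug-signature library contains
one planted signature reverser plus random decoys. Every downstream stage of
the pipeline can therefore be scored against known truth.

Expression is Gaussian on the log2 scale: per-study baselines are uniform on
[6, 12] and planted effects are expressed in units of the within-class
standard deviation. All randomness flows from one root seed through
``numpy.random.SeedSequence([seed, domain])`` with fixed domain constants
(studies=1, TF library=2, PPI=3, kinase library=4, drugs=5, pathways=6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionStudy, GeneSetLibrary, PPINetwork, StudyCategory
from .connectivity import DrugSignatureLibrary

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression_studies",
    "simulate_regulator_libraries",
    "simulate_pathway_library",
    "simulate_drug_library",
]

# seed-domain constants for the splitting scheme
_DOM_STUDIES, _DOM_TF, _DOM_PPI, _DOM_KINASE, _DOM_DRUG, _DOM_PATHWAY = 1, 2, 3, 4, 5, 6

HUB_SYMBOL = "HUB1"
REVERSER_DRUG = "RX_REVERSER"


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic meta-analysis.

    Defaults describe three independent studies of 10 cases vs 10 controls
    over a genome-scale panel of 20000 genes, 50 + 50 planted shared co-DEGs
    at an effect of 2 within-class standard deviations, 30 private DEGs per
    study, 10 planted TFs (20 co-DEG targets each) among 50 decoy TFs, and
    10 planted kinases among 30 decoys.
    """

    seed: int
    n_studies: int = 3
    n_genes: int = 20000
    n_case: int = 10
    n_control: int = 10
    n_co_up: int = 50
    n_co_down: int = 50
    n_private: int = 30
    effect_size: float = 2.0
    base_sd: float = 1.0
    n_tfs: int = 10
    targets_per_tf: int = 20
    decoys_per_tf_term: int = 5
    n_decoy_tfs: int = 50
    n_kinases: int = 10
    substrates_per_kinase: int = 6
    n_decoy_kinases: int = 30
    ppi_extra_edges: int = 200
    n_decoy_drugs: int = 20
    category: StudyCategory = StudyCategory.CANCER_VS_NORMAL

    def __post_init__(self) -> None:
        planted = self.n_co_up + self.n_co_down + self.n_studies * self.n_private
        if planted > self.n_genes:
            raise ValueError(
                f"infeasible counts: {planted} planted DEGs exceed {self.n_genes} genes"
            )
        for name in ("n_studies", "n_genes", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >=1")
        for name in (
            "n_co_up", "n_co_down", "n_private", "n_tfs", "targets_per_tf",
            "decoys_per_tf_term", "n_decoy_tfs", "n_kinases", "substrates_per_kinase",
            "n_decoy_kinases", "ppi_extra_edges", "n_decoy_drugs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >=0")
        if self.targets_per_tf > self.n_co_up + self.n_co_down:
            raise ValueError("targets_per_tf exceeds the planted co-DEG pool")
        if self.substrates_per_kinase > self.n_tfs + 1:
            raise ValueError("substrates_per_kinase exceeds planted TFs + hub")
        self.category = StudyCategory(self.category)


@dataclass
class GroundTruth:
    """What was planted: consult after running the pipeline to score recovery."""

    co_up: frozenset[str]
    co_down: frozenset[str]
    private: dict[str, dict[str, int]]  # study -> gene -> +1 (up in cases) / -1
    tf_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    kinase_substrates: dict[str, frozenset[str]] = field(default_factory=dict)
    hub: str = HUB_SYMBOL
    reverser_drug: str = REVERSER_DRUG

    @property
    def tfs(self) -> list[str]:
        return sorted(self.tf_targets)

    @property
    def kinases(self) -> list[str]:
        return sorted(self.kinase_substrates)


def _gene_symbols(n: int) -> np.ndarray:
    return np.array([f"G{i + 1:05d}" for i in range(n)])


def simulate_expression_studies(config: SimulationConfig) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate the case/control studies and the planted truth.

    Per study, gene g of sample j is N(mu_g, base_sd^2) with mu_g ~ U(6, 12)
    (log2 scale, study-specific baseline). Cases of every study are shifted
    by +effect for planted co-up genes and −effect for co-down genes
    (effect = effect_size * base_sd); each study's private DEGs are shifted
    in that study only, with a random sign per gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DOM_STUDIES]))
    genes = _gene_symbols(config.n_genes)

    perm = rng.permutation(config.n_genes)
    pos = 0
    co_up = frozenset(genes[perm[pos : pos + config.n_co_up]]); pos += config.n_co_up
    co_down = frozenset(genes[perm[pos : pos + config.n_co_down]]); pos += config.n_co_down
    private: dict[str, dict[str, int]] = {}
    study_ids = [f"STUDY{i + 1}" for i in range(config.n_studies)]
    for sid in study_ids:
        block = genes[perm[pos : pos + config.n_private]]
        pos += config.n_private
        signs = rng.choice([1, -1], size=len(block))
        private[sid] = {g: int(s) for g, s in zip(block, signs)}

    effect = config.effect_size * config.base_sd
    up_idx = np.isin(genes, sorted(co_up))
    down_idx = np.isin(genes, sorted(co_down))

    studies = []
    for sid in study_ids:
        n_s = config.n_case + config.n_control
        mu = rng.uniform(6.0, 12.0, size=config.n_genes)
        values = mu[:, None] + rng.normal(0.0, config.base_sd, size=(config.n_genes, n_s))
        case_cols = np.arange(config.n_case)
        values[np.ix_(up_idx, case_cols)] += effect
        values[np.ix_(down_idx, case_cols)] -= effect
        gene_pos = {g: i for i, g in enumerate(genes)}
        for g, sign in private[sid].items():
            values[gene_pos[g], case_cols] += sign * effect
        case_samples = [f"{sid}_CASE{j + 1}" for j in range(config.n_case)]
        control_samples = [f"{sid}_CTL{j + 1}" for j in range(config.n_control)]
        studies.append(
            ExpressionStudy(
                study_id=sid,
                genes=list(genes),
                samples=case_samples + control_samples,
                values=values,
                case_samples=case_samples,
                control_samples=control_samples,
                category=config.category,
            )
        )
    truth = GroundTruth(co_up=co_up, co_down=co_down, private=private)
    return studies, truth


def simulate_regulator_libraries(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[GeneSetLibrary, GeneSetLibrary, PPINetwork]:
    """Build the TF-target library, the kinase-substrate library and the PPI.

    Planted TF terms draw their targets from the planted co-DEGs (plus a few
    non-DEG decoy genes); decoy TF terms are size-matched sets of non-DEG
    genes. The PPI is a star connecting the hub protein to every planted TF,
    plus random background edges. Planted kinase substrate sets consist of
    the hub and planted TFs; decoy kinase terms are random non-network genes.
    Updates ``truth.tf_targets`` and ``truth.kinase_substrates`` in place.
    """
    genes = _gene_symbols(config.n_genes)
    deg = set(truth.co_up) | set(truth.co_down)
    for per_study in truth.private.values():
        deg |= set(per_study)
    non_deg = np.array(sorted(set(genes) - deg))
    codeg_pool = np.array(sorted(set(truth.co_up) | set(truth.co_down)))

    tf_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DOM_TF]))
    tf_terms: dict[str, frozenset[str]] = {}
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    for tf in tfs:
        targets = frozenset(tf_rng.choice(codeg_pool, size=config.targets_per_tf, replace=False))
        decoys = frozenset(tf_rng.choice(non_deg, size=config.decoys_per_tf_term, replace=False))
        truth.tf_targets[tf] = targets
        tf_terms[tf] = targets | decoys
    term_size = config.targets_per_tf + config.decoys_per_tf_term
    for i in range(config.n_decoy_tfs):
        tf_terms[f"DTF{i + 1:03d}"] = frozenset(
            tf_rng.choice(non_deg, size=term_size, replace=False)
        )
    tf_library = GeneSetLibrary(name="tf_targets", terms=tf_terms)

    ppi_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DOM_PPI]))
    edges: list[tuple[str, str]] = [(truth.hub, tf) for tf in tfs]
    ppi_pool = np.concatenate([genes, np.array(tfs)])
    for _ in range(config.ppi_extra_edges):
        a, b = ppi_rng.choice(ppi_pool, size=2, replace=False)
        edges.append((str(a), str(b)))
    ppi = PPINetwork.build([truth.hub, *tfs], edges)

    kin_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DOM_KINASE]))
    kin_terms: dict[str, frozenset[str]] = {}
    network_symbols = np.array(sorted(tfs))
    for i in range(config.n_kinases):
        kin = f"KN{i + 1:02d}"
        n_tf_subs = max(config.substrates_per_kinase - 1, 0)
        subs = {truth.hub} | set(kin_rng.choice(network_symbols, size=n_tf_subs, replace=False))
        truth.kinase_substrates[kin] = frozenset(subs)
        kin_terms[kin] = frozenset(subs)
    for i in range(config.n_decoy_kinases):
        kin_terms[f"DKN{i + 1:03d}"] = frozenset(
            kin_rng.choice(non_deg, size=config.substrates_per_kinase, replace=False)
        )
    kinase_library = GeneSetLibrary(name="kinase_substrates", terms=kin_terms)
    return tf_library, kinase_library, ppi


def simulate_pathway_library(
    truth: GroundTruth,
    config: SimulationConfig,
    n_decoy_pathways: int = 28,
    genes_per_pathway: int = 40,
) -> GeneSetLibrary:
    """A functional-annotation library with one planted term per direction.

    ``PATH_UP`` (``PATH_DOWN``) contains most of the planted co-up (co-down)
    genes plus random fillers; decoy pathways are random non-DEG gene sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DOM_PATHWAY]))
    genes = _gene_symbols(config.n_genes)
    deg = set(truth.co_up) | set(truth.co_down)
    non_deg = np.array(sorted(set(genes) - deg))

    terms: dict[str, frozenset[str]] = {}
    for name, pool in (("PATH_UP", sorted(truth.co_up)), ("PATH_DOWN", sorted(truth.co_down))):
        n_core = max(1, int(round(0.8 * len(pool))))
        core = set(rng.choice(np.array(pool), size=min(n_core, len(pool)), replace=False))
        n_fill = max(genes_per_pathway - len(core), 0)
        fill = set(rng.choice(non_deg, size=n_fill, replace=False))
        terms[name] = frozenset(core | fill)
    for i in range(n_decoy_pathways):
        terms[f"PATH_DECOY{i + 1:03d}"] = frozenset(
            rng.choice(non_deg, size=genes_per_pathway, replace=False)
        )
    return GeneSetLibrary(name="pathways", terms=terms)


def simulate_drug_library(
    truth: GroundTruth, n_decoy_drugs: int, config: SimulationConfig
) -> DrugSignatureLibrary:
    """Drug-signature library with one planted signature reverser.

    The reverser's up-set is an 80% random sample of the planted co-down
    genes and its down-set an 80% sample of the co-up genes, so it reverses
    the disease signature; decoys are random same-size disjoint sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DOM_DRUG]))
    genes = _gene_symbols(config.n_genes)

    co_up = np.array(sorted(truth.co_up))
    co_down = np.array(sorted(truth.co_down))
    n_up = max(1, int(round(0.8 * len(co_down))))
    n_down = max(1, int(round(0.8 * len(co_up))))
    drugs: dict[str, tuple[frozenset[str], frozenset[str]]] = {
        truth.reverser_drug: (
            frozenset(rng.choice(co_down, size=n_up, replace=False)),
            frozenset(rng.choice(co_up, size=n_down, replace=False)),
        )
    }
    for i in range(n_decoy_drugs):
        pick = rng.choice(genes, size=n_up + n_down, replace=False)
        drugs[f"DRUG{i + 1:03d}"] = (frozenset(pick[:n_up]), frozenset(pick[n_up:]))
    return DrugSignatureLibrary(drugs=drugs, universe=frozenset(genes))
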