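"""End-to-end orchestration of the co-DEG meta-analysis.

Stage order mirrors the analysis workflow: load (or simulate) the studies,
signature-integrity QC, characteristic-direction differential expression,
fixed-size signatures, cross-study co-DEG consensus, functional enrichment,
upstream TF -> PPI -> kinase network inference with hub detection, and
drug-signature connectivity. Every output is a deterministic TSV (plus SIF
and GraphML for the networks) so that a rerun with the same seed reproduces
byte-identical report tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import chdir as _chdir
from .chdir import GeneSignature, characteristic_direction, signature_from_cd
from .connectivity import ConnectivityResult, DrugSignatureLibrary, connectivity_frame, rank_drugs
from .consensus import CoDEGSet, compute_codegs, support_table
from .data_io import (
    ExpressionStudy,
    GeneSetLibrary,
    PPINetwork,
    QCReport,
    validate_signature_metadata,
    write_gene_list,
    write_signature_table,
)
from .enrichment import EnrichmentRow, build_null_rank_model, enrich, enrichment_frame
from .regnet import (
    RegulatoryNetwork,
    compute_hub_table,
    g2n_expand,
    kinase_enrich_and_attach,
    select_hubs,
    top_regulators,
    write_network_graphml,
    write_network_sif,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_drug_library,
    simulate_expression_studies,
    simulate_pathway_library,
    simulate_regulator_libraries,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineResult", "run_full_pipeline"]

STAGES = (
    "load_data",
    "qc",
    "differential_expression",
    "signatures",
    "consensus",
    "enrichment",
    "regulatory_network",
    "connectivity",
)

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names where."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    """In-memory view of everything the pipeline computed."""

    out_dir: Path
    manifest: dict
    studies: list[ExpressionStudy] = field(default_factory=list)
    truth: GroundTruth | None = None
    qc_reports: list[QCReport] = field(default_factory=list)
    signatures: list[GeneSignature] = field(default_factory=list)
    codegs: CoDEGSet | None = None
    pathway_enrichment: dict[str, list[EnrichmentRow]] = field(default_factory=dict)
    tf_enrichment: dict[str, list[EnrichmentRow]] = field(default_factory=dict)
    kinase_enrichment: dict[str, list[EnrichmentRow]] = field(default_factory=dict)
    top_tfs: dict[str, list[str]] = field(default_factory=dict)
    networks: dict[str, RegulatoryNetwork] = field(default_factory=dict)
    hub_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    hubs: dict[str, list[str]] = field(default_factory=dict)
    reversers: list[ConnectivityResult] = field(default_factory=list)
    mimics: list[ConnectivityResult] = field(default_factory=list)


def _derived_seed(seed: int, domain: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([seed, 97, domain]).generate_state(1)[0] >> 1)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_full_pipeline(
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    *,
    studies: list[ExpressionStudy] | None = None,
    tf_library: GeneSetLibrary | None = None,
    kinase_library: GeneSetLibrary | None = None,
    pathway_library: GeneSetLibrary | None = None,
    ppi: PPINetwork | None = None,
    drug_library: DrugSignatureLibrary | None = None,
    valid_symbols: set[str] | None = None,
    seed: int | None = None,
    gamma: float = _chdir.DEFAULT_GAMMA,
    cutoff: int = _chdir.DEFAULT_CUTOFF,
    min_support: int = 2,
    top_tfs: int = 10,
    top_kinases: int = 10,
    top_hubs: int = 5,
    max_path_length: int = 2,
    n_null_queries: int = 1000,
) -> PipelineResult:
    """Run every stage of the meta-analysis and write a report directory.

    Either pass a :class:`SimulationConfig` (all inputs are generated with
    known ground truth) or supply ``studies`` plus the libraries/PPI/drug
    inputs directly, along with ``seed`` for the enrichment null models.
    Stage failures raise :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    result = PipelineResult(out_dir=out_dir, manifest={})

    def stage(name):
        def deco(fn):
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc
            completed.append(name)
        return deco

    # ---- load_data -------------------------------------------------------
    @stage("load_data")
    def _load():
        nonlocal studies, tf_library, kinase_library, pathway_library, ppi, drug_library, seed
        if config is not None:
            sim_studies, truth = simulate_expression_studies(config)
            tf_lib, kin_lib, sim_ppi = simulate_regulator_libraries(truth, config)
            studies = sim_studies
            result.truth = truth
            tf_library = tf_library or tf_lib
            kinase_library = kinase_library or kin_lib
            ppi = ppi or sim_ppi
            pathway_library = pathway_library or simulate_pathway_library(truth, config)
            drug_library = drug_library or simulate_drug_library(truth, config.n_decoy_drugs, config)
            seed = config.seed
        if not studies or len(studies) < 2:
            raise ValueError("need at least two studies")
        if seed is None:
            raise ValueError("seed is required when no SimulationConfig is given")
        result.studies = studies

    # ---- qc --------------------------------------------------------------
    @stage("qc")
    def _qc():
        nonlocal studies, valid_symbols
        symbols = valid_symbols or set().union(*(set(s.genes) for s in studies))
        reports = [validate_signature_metadata(s, symbols) for s in studies]
        result.qc_reports = reports
        _write_tsv(pd.DataFrame([r.to_row() for r in reports]), out_dir / "qc_report.tsv")
        accepted = [s for s, r in zip(studies, reports) if r.status == "accepted"]
        if len(accepted) < 2:
            raise ValueError("fewer than two studies pass QC")
        studies = accepted

    # ---- differential_expression + signatures ----------------------------
    cd_results = []

    @stage("differential_expression")
    def _cd():
        for study in studies:
            cd = characteristic_direction(study, gamma=gamma)
            cd_results.append(cd)
            write_signature_table(cd.coefficients, out_dir / f"{study.study_id}.cd.tsv")

    @stage("signatures")
    def _sigs():
        for cd in cd_results:
            sig = signature_from_cd(cd, cutoff=cutoff)
            result.signatures.append(sig)
            write_gene_list(sig.up_genes, out_dir / f"{sig.study_id}.up.txt")
            write_gene_list(sig.down_genes, out_dir / f"{sig.study_id}.down.txt")

    # ---- consensus -------------------------------------------------------
    @stage("consensus")
    def _consensus():
        result.codegs = compute_codegs(result.signatures, min_support=min_support)
        _write_tsv(support_table(result.codegs), out_dir / "codeg_support.tsv")

    measured = set().union(*(set(s.genes) for s in studies))
    queries = {"up": frozenset(result.codegs.co_up), "down": frozenset(result.codegs.co_down)}

    # ---- enrichment (functional annotation) ------------------------------
    @stage("enrichment")
    def _enrich():
        if pathway_library is None:
            logger.warning("no functional-annotation library supplied; stage writes nothing")
            return
        universe = pathway_library.universe & measured
        sizes = [len(q & universe) for q in queries.values() if q & universe]
        if not sizes:
            logger.warning("no co-DEG overlaps the annotation universe")
            return
        null = build_null_rank_model(
            pathway_library, sizes, n_random=n_null_queries,
            seed=_derived_seed(seed, 1), universe=universe,
        )
        for direction, query in queries.items():
            if not query & universe:
                continue
            rows = enrich(query, pathway_library, universe, null)
            result.pathway_enrichment[direction] = rows
            _write_tsv(enrichment_frame(rows), out_dir / f"enrich_pathways_{direction}.tsv")

    # ---- regulatory_network ---------------------------------------------
    @stage("regulatory_network")
    def _regnet():
        if tf_library is None or kinase_library is None or ppi is None:
            missing = [
                name for name, obj in
                (("tf_library", tf_library), ("kinase_library", kinase_library), ("ppi", ppi))
                if obj is None
            ]
            raise ValueError(f"missing inputs: {', '.join(missing)}")
        tf_universe = tf_library.universe & measured
        sizes = [len(q & tf_universe) for q in queries.values() if q & tf_universe]
        if not sizes:
            raise ValueError("no co-DEG overlaps the TF-target universe")
        tf_null = build_null_rank_model(
            tf_library, sizes, n_random=n_null_queries,
            seed=_derived_seed(seed, 2), universe=tf_universe,
        )
        for direction, query in queries.items():
            if not query & tf_universe:
                logger.warning("no %s co-DEGs in the TF universe; direction skipped", direction)
                continue
            rows = enrich(query, tf_library, tf_universe, tf_null)
            result.tf_enrichment[direction] = rows
            _write_tsv(enrichment_frame(rows), out_dir / f"enrich_tf_{direction}.tsv")
            seeds_tf = top_regulators(rows, top_tfs)
            result.top_tfs[direction] = seeds_tf
            net = g2n_expand(seeds_tf, ppi, max_path_length=max_path_length,
                             provenance=f"codeg_{direction}")
            kin_universe = kinase_library.universe | set(net.nodes)
            kin_null = build_null_rank_model(
                kinase_library, [len(net.nodes)], n_random=n_null_queries,
                seed=_derived_seed(seed, 3), universe=kin_universe,
            )
            net, kin_rows = kinase_enrich_and_attach(
                net, kinase_library, kin_universe, kin_null, n=top_kinases
            )
            result.kinase_enrichment[direction] = kin_rows
            _write_tsv(enrichment_frame(kin_rows), out_dir / f"enrich_kinase_{direction}.tsv")
            result.networks[direction] = net
            hub_table = compute_hub_table(net)
            result.hubs[direction] = select_hubs(hub_table, top_hubs)
            result.hub_tables[direction] = hub_table
            _write_tsv(hub_table, out_dir / f"hubs_{direction}.tsv")
            write_network_sif(net, out_dir / f"network_{direction}.sif")
            write_network_graphml(net, out_dir / f"network_{direction}.graphml")

    # ---- connectivity ----------------------------------------------------
    @stage("connectivity")
    def _connect():
        if drug_library is None:
            raise ValueError("missing inputs: drug_library")
        if not queries["up"] or not queries["down"]:
            raise ValueError("connectivity needs non-empty co-up and co-down sets")
        reversers, mimics = rank_drugs(queries["up"], queries["down"], drug_library)
        result.reversers, result.mimics = reversers, mimics
        _write_tsv(connectivity_frame(reversers), out_dir / "drugs_reversers.tsv")
        _write_tsv(connectivity_frame(mimics), out_dir / "drugs_mimics.tsv")

    # ---- manifest --------------------------------------------------------
    try:
        pkg_version = _pkg_version("codegnet")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "package": "codegnet",
        "version": pkg_version,
        "seed": seed,
        "parameters": {
            "gamma": gamma,
            "cutoff": cutoff,
            "min_support": min_support,
            "top_tfs": top_tfs,
            "top_kinases": top_kinases,
            "top_hubs": top_hubs,
            "max_path_length": max_path_length,
            "n_null_queries": n_null_queries,
        },
        "n_studies": len(studies),
        "n_genes": len(measured),
        "stages": [{"name": s, "status": "completed"} for s in completed],
    }
    if config is not None:
        manifest["simulation"] = {
            k: (v.value if hasattr(v, "value") else v) for k, v in vars(config).items()
        }
    result.manifest = manifest
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
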