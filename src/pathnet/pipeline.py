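"""End-to-end orchestration: curation -> enrichment -> set cover ->
similarity -> threshold scan -> pruning -> disease mapping -> clustering
tests, with a stage log that accounts for every pathway removed.

All numeric knobs live in :class:`PipelineConfig`; the defaults are the
canonical values of the method (alpha 0.01 for both GO and disease
enrichment, minimum 4 annotated genes, 99.95% set-cover coverage,
50 candidate thresholds, 100 null replicates per disease).  A single
master seed derives all stage seeds, so outputs are a pure function of
(inputs, config).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pathnet import annotations as ann
from pathnet import curation, disease, enrichment, network, semsim, setcover
from pathnet.curation import DEFAULT_NAME_FILTERS, PathwaySet
from pathnet.network import PathwayNetwork
from pathnet.ontology import OntologyDAG, load_obo


@dataclass
class PipelineConfig:
    obo: str | os.PathLike
    gaf: str | os.PathLike
    gmt: str | os.PathLike
    diseases: str | os.PathLike | None = None
    namespace: str = "biological_process"
    alpha_go: float = 0.01
    alpha_disease: float = 0.01
    min_annotated: int = 4
    min_disease_genes: int = 4
    coverage_fraction: float = 0.9995
    target_size: int | None = None  # None = median candidate size
    sim_method: str = "wang"
    sim_agg: str = "bma"
    wang_weights: semsim.WangWeights = field(default_factory=semsim.WangWeights)
    n_thresholds: int = 50
    disease_reps: int = 100
    seed: int = 17
    name_filters: Mapping[str, Sequence[str]] | None = None


@dataclass
class PipelineResult:
    pathways: PathwaySet
    profiles: list[enrichment.FunctionalProfile]
    similarity: pd.DataFrame
    threshold: float
    scan: pd.DataFrame
    net: PathwayNetwork
    clustering: float
    random_clustering: list[float]
    power_law: network.PowerLawFit | None
    disease_map: dict[str, list[str]]
    disease_results: list[disease.DiseaseModuleResult]
    stage_log: list[tuple[str, int, str]]
    dag: OntologyDAG = None
    table: ann.AnnotationTable = None
    background: frozenset[str] = frozenset()

    def stage_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_log, columns=["stage", "count", "detail"])


def _stage_seed(master: int, stage: str) -> int:
    digest = sum(ord(c) * 31**i for i, c in enumerate(stage)) % (2**16)
    return int(
        np.random.SeedSequence([master, digest]).generate_state(1)[0] % (2**31)
    )


def run_all(cfg: PipelineConfig, outdir: str | os.PathLike | None = None) -> PipelineResult:
    """Execute every stage in order; see module docstring for the sequence."""
    log: list[tuple[str, int, str]] = []

    dag = load_obo(cfg.obo, namespace=cfg.namespace)
    table = ann.load_gaf(cfg.gaf, namespace=cfg.namespace)
    table = ann.propagate(ann.filter_evidence(table), dag)

    ps = curation.load_gmt(cfg.gmt)
    initial = len(ps)
    log.append(("input", initial, "raw pathways"))
    ps = curation.deduplicate(ps)
    ps = curation.filter_by_name(ps, cfg.name_filters or DEFAULT_NAME_FILTERS)
    ps = curation.filter_annotation_coverage(ps, table, cfg.min_annotated)
    log.extend(ps.curation_log)

    background = frozenset().union(*(p.genes for p in ps.pathways)) & table.genes
    profiles = enrichment.profile_pathways(ps, table, alpha=cfg.alpha_go, background=background)
    with_terms = {p.pathway_id for p in profiles if p.enriched}
    removed = [p for p in ps.pathways if p.id not in with_terms]
    ps = PathwaySet(
        pathways=[p for p in ps.pathways if p.id in with_terms],
        curation_log=list(ps.curation_log),
    )
    log.append(("enrichment_filter", len(removed), "no enriched GO terms"))
    profiles = [p for p in profiles if p.pathway_id in with_terms]

    # minimal functional profiles
    t2g = table.term_to_genes()
    by_id = {p.id: p for p in ps.pathways}
    for prof in profiles:
        pw = by_id[prof.pathway_id]
        genes = pw.annotated_genes or pw.genes
        cand = [(r.term, r.p, t2g[r.term] & genes) for r in prof.enriched]
        prof.minimal = setcover.minimize_profile(genes, cand)

    pre_cover = len(ps)
    ps, trace = setcover.proportional_set_cover(
        ps, target_size=cfg.target_size, coverage_fraction=cfg.coverage_fraction
    )
    log.append(("set_cover", pre_cover - len(ps), "redundant (not in set cover)"))
    log.append(("retained", len(ps), "final pathway nodes"))
    kept_ids = set(ps.ids())
    profiles = [p for p in profiles if p.pathway_id in kept_ids]

    # similarity edges
    ic = semsim.build_ic_map(table) if cfg.sim_method == "resnik" else None
    termsim = semsim.make_termsim(
        dag, method=cfg.sim_method, weights=cfg.wang_weights, ic=ic
    )
    term_sets = {p.pathway_id: p.terms for p in profiles}
    sim = semsim.similarity_matrix(term_sets, termsim, agg=cfg.sim_agg)

    theta, scan = network.threshold_scan(sim, n_thresholds=cfg.n_thresholds)
    net = network.prune(
        sim, theta,
        provenance={"method": cfg.sim_method, "agg": cfg.sim_agg, "threshold": theta},
    )
    cc = network.clustering_coefficient(net)
    rand_cc = []
    for i in range(10):
        rnet = network.degree_preserving_randomize(
            net, seed=_stage_seed(cfg.seed, f"randomize{i}")
        )
        rand_cc.append(network.clustering_coefficient(rnet))
    degs = [d for _, d in net.graph.degree()]
    try:
        plaw = network.power_law_test(degs)
    except ValueError:
        plaw = None

    # disease mapping and clustering tests
    disease_map: dict[str, list[str]] = {}
    disease_results: list[disease.DiseaseModuleResult] = []
    if cfg.diseases is not None:
        anns = disease.load_disease_table(cfg.diseases)
        anns = disease.filter_min_genes(anns, cfg.min_disease_genes)
        disease_map, skipped = disease.map_diseases(
            anns, ps, background, alpha=cfg.alpha_disease
        )
        log.append(("disease_skipped", len(skipped), "no background overlap"))
        disease_results = disease.disease_module_analysis(
            net, disease_map, reps=cfg.disease_reps,
            seed=_stage_seed(cfg.seed, "disease_null"),
        )

    result = PipelineResult(
        pathways=ps,
        profiles=profiles,
        similarity=sim,
        threshold=theta,
        scan=scan,
        net=net,
        clustering=cc,
        random_clustering=rand_cc,
        power_law=plaw,
        disease_map=disease_map,
        disease_results=disease_results,
        stage_log=log,
        dag=dag,
        table=table,
        background=background,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    curation.write_gmt(res.pathways, outdir / "pathways_final.gmt")
    prof_rows = [
        {"pathway": p.pathway_id, "n_enriched": len(p.enriched),
         "minimal_terms": ";".join(p.minimal or [])}
        for p in res.profiles
    ]
    pd.DataFrame(prof_rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    res.similarity.to_csv(outdir / "similarity.tsv", sep="\t")
    res.scan.to_csv(outdir / "threshold_scan.tsv", sep="\t", index=False)
    network.write_edge_list(res.net, outdir / "edges.tsv")
    stats = {
        "threshold": res.threshold,
        "n_nodes": res.net.graph.number_of_nodes(),
        "n_isolated": len(res.net.isolated),
        "n_edges": res.net.n_edges,
        "clustering_coefficient": res.clustering,
        "random_clustering_mean": float(np.mean(res.random_clustering)),
    }
    if res.power_law is not None:
        stats.update(
            power_law_alpha=res.power_law.alpha, power_law_p=res.power_law.p
        )
    pd.Series(stats).to_csv(outdir / "network_stats.tsv", sep="\t", header=False)
    pd.DataFrame(
        [{"disease": d, "pathways": ";".join(nodes)} for d, nodes in sorted(res.disease_map.items())]
    ).to_csv(outdir / "disease_map.tsv", sep="\t", index=False)
    disease.results_frame(res.disease_results).to_csv(
        outdir / "disease_modules.tsv", sep="\t", index=False
    )
    res.stage_log_frame().to_csv(outdir / "stage_log.tsv", sep="\t", index=False)
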