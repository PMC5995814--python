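"""Synthetic ontology / annotation / pathway / disease generator.

Emulates the statistical shape of the real inputs (a GO-style Biological
Process DAG, GAF annotations with mixed evidence, a heavily redundant
long-tailed pathway collection, and disease gene tables mixing genuine
modules with null diseases) so the whole pipeline is testable offline.

Structure: the ontology is a rooted random DAG whose first-level subtrees
("branches") act as functional themes.  Each gene has a home branch and is
annotated mostly to terms of that branch; each pathway belongs to a theme
and samples most of its genes from that theme's gene pool.  Planted
diseases draw their genes from a few pathways of one theme (so their
mapped nodes are functionally close); null diseases draw genes uniformly.
Exact duplicates, disease-named pathways, IEA-only genes and sub-minimum
pathways are planted deliberately so that every curation branch fires on
the standard fixture.

Everything is a pure function of (config, seed): regenerating produces
byte-identical files.  Ground truth (pathway themes, disease status) is
emitted alongside the data so tests never reverse-engineer the generator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from pathnet.ontology import OntologyDAG, load_obo


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults are the standard fixture.

    The standard fixture ("std-v1") is sized so enrichment and the
    disease-module statistics have power while the full pipeline runs in
    seconds: 160 terms in 8 branches, 1000 genes, ~220 raw pathways,
    10 planted + 10 null diseases.  Distribution targets follow the shape
    of real pathway/GO corpora: a long-tailed pathway-size distribution
    with median ~23 and heavily overdispersed per-gene annotation counts
    (mean 8.2, sd ~9).
    """

    seed: int = 17
    # ontology
    n_terms: int = 160
    dag_extra_edge_prob: float = 0.15
    cross_branch_prob: float = 0.3
    part_of_fraction: float = 0.15
    # annotations
    n_genes: int = 1000
    terms_per_gene_mean: float = 8.2
    terms_per_gene_sd: float = 9.2
    home_branch_bias: float = 0.9
    iea_fraction: float = 0.2
    iea_only_fraction: float = 0.076
    unannotated_fraction: float = 0.04
    # pathways
    n_themes: int = 8
    pathways_per_theme: int = 24
    pathway_theme_bias: float = 0.8
    secondary_seed_fraction: float = 0.3  # of theme draws, see sample_genes
    cross_theme_pathway_prob: float = 0.3
    pathway_size_median: int = 23
    pathway_size_sigma: float = 1.2
    duplicate_fraction: float = 0.1
    overlap_inflation: float = 0.15
    n_disease_named: int = 9
    n_tiny_pathways: int = 2
    # diseases
    n_planted_diseases: int = 10
    genes_per_disease: int = 30
    n_null_diseases: int = 10
    disease_name_templates: tuple[str, ...] = (
        "synthetic sarcoma {i}",
        "familial tumor syndrome {i}",
        "synthetic carcinoma {i}",
        "hereditary disorder {i}",
        "synthetic neuropathy {i}",
    )

    def rng_for(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


#: published standard-fixture configuration
STD_V1 = GeneratorConfig()

_STAGE_ONTOLOGY, _STAGE_ANNOT, _STAGE_PATHWAYS, _STAGE_DISEASES = range(4)


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_ontology(cfg: GeneratorConfig) -> str:
    """Emit a rooted DAG as OBO text.

    Term 1 is the root; terms 2..n_themes+1 are branch roots (the themes);
    every later term attaches to an earlier term of its branch, plus an
    extra same-branch parent with probability ``dag_extra_edge_prob``.
    ``part_of_fraction`` of non-root edges are labeled part_of.
    """
    if cfg.n_terms < 5:
        raise ValueError("need at least 5 terms")
    rng = cfg.rng_for(_STAGE_ONTOLOGY)
    root = _term_id(1)
    branch_of: dict[str, int] = {}
    edges: list[tuple[str, str, str]] = []  # child, parent, relation
    branch_members: list[list[str]] = [[] for _ in range(cfg.n_themes)]
    for b in range(cfg.n_themes):
        t = _term_id(2 + b)
        branch_of[t] = b
        branch_members[b].append(t)
        edges.append((t, root, "is_a"))
    for i in range(2 + cfg.n_themes, cfg.n_terms + 1):
        t = _term_id(i)
        b = int(rng.integers(cfg.n_themes))
        branch_of[t] = b
        pool = branch_members[b]
        parent = pool[int(rng.integers(len(pool)))]
        rel = "part_of" if rng.random() < cfg.part_of_fraction else "is_a"
        edges.append((t, parent, rel))
        if rng.random() < cfg.dag_extra_edge_prob:
            # extra parent; occasionally from another branch, creating the
            # cross-process term sharing real ontologies exhibit
            if rng.random() < cfg.cross_branch_prob and cfg.n_themes > 1:
                other = (b + 1 + int(rng.integers(cfg.n_themes - 1))) % cfg.n_themes
                opool = branch_members[other]
                extra = opool[int(rng.integers(len(opool)))]
            elif len(pool) > 1:
                extra = pool[int(rng.integers(len(pool)))]
            else:
                extra = parent
            if extra != parent:
                rel2 = "part_of" if rng.random() < cfg.part_of_fraction else "is_a"
                edges.append((t, extra, rel2))
        branch_members[b].append(t)

    lines = [
        "format-version: 1.2",
        "default-namespace: biological_process",
        "ontology: synthetic_bp",
        "",
    ]
    by_term: dict[str, list[tuple[str, str]]] = {}
    for c, p, r in edges:
        by_term.setdefault(c, []).append((p, r))
    all_terms = [root] + [_term_id(i) for i in range(2, cfg.n_terms + 1)]
    for t in all_terms:
        lines.append("[Term]")
        lines.append(f"id: {t}")
        label = "root" if t == root else f"branch{branch_of[t]} term {t[-4:]}"
        lines.append(f"name: synthetic {label}")
        lines.append("namespace: biological_process")
        for p, r in sorted(by_term.get(t, [])):
            if r == "is_a":
                lines.append(f"is_a: {p}")
            else:
                lines.append(f"relationship: part_of {p}")
        lines.append("")
    return "\n".join(lines)


def _branch_map(dag: OntologyDAG) -> dict[str, int]:
    """Recover each term's theme from the generator's naming convention,
    falling back to the first-level ancestor for foreign ontologies."""
    import re

    out: dict[str, int] = {}
    pattern = re.compile(r"branch(\d+)")
    for t in sorted(dag.terms):
        m = pattern.search(dag.names.get(t, ""))
        if m:
            out[t] = int(m.group(1))
    if out:
        return out
    root = min(dag.roots)
    branch_roots = sorted(
        t for t in dag.terms if any(p == root for p, _ in dag.parents(t))
    )
    for t in sorted(dag.terms):
        if t == root:
            continue
        anc = dag.ancestors(t) | {t}
        for i, br in enumerate(branch_roots):
            if br in anc:
                out[t] = i
                break
    return out


def _branch_balls(dag: OntologyDAG, branch_of: dict[str, int], radius: int = 2) -> dict[str, list[str]]:
    """Undirected radius-*radius* neighborhood of each term within its branch.

    These balls define the 'functional locality' used for both gene
    annotation and pathway gene sampling.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(branch_of)
    for c, p, _rel in dag.edges():
        if c in branch_of and p in branch_of and branch_of[c] == branch_of[p]:
            g.add_edge(c, p)
    balls: dict[str, list[str]] = {}
    for t in sorted(branch_of):
        lengths = nx.single_source_shortest_path_length(g, t, cutoff=radius)
        balls[t] = sorted(lengths)
    return balls


def _home_terms(cfg: GeneratorConfig, dag: OntologyDAG) -> dict[str, str]:
    """Deterministic gene -> home-term map (no randomness, shared by stages).

    Gene i belongs to branch (i-1) mod n_themes and cycles through that
    branch's terms, so every term anchors roughly the same number of genes.
    """
    branch_of = _branch_map(dag)
    terms_by_branch: list[list[str]] = [[] for _ in range(cfg.n_themes)]
    for t in sorted(branch_of):
        terms_by_branch[branch_of[t]].append(t)
    out: dict[str, str] = {}
    for i in range(1, cfg.n_genes + 1):
        b = (i - 1) % cfg.n_themes
        pool = terms_by_branch[b]
        out[_gene_id(i)] = pool[((i - 1) // cfg.n_themes) % len(pool)]
    return out


def _gene_id(i: int) -> str:
    return f"SYNG{i:04d}"


def generate_annotations(cfg: GeneratorConfig, dag: OntologyDAG) -> str:
    """Emit GAF 2.1 text assigning terms to genes.

    Each gene's direct-term count follows a truncated negative-binomial
    with the configured mean/sd; ``home_branch_bias`` of the draws come
    from the gene's home branch.  A configured fraction of genes is
    IEA-only (lost at evidence filtering) or entirely unannotated;
    otherwise each entry is IEA with probability ``iea_fraction``.
    """
    rng = cfg.rng_for(_STAGE_ANNOT)
    branch_of = _branch_map(dag)
    root = min(dag.roots)
    balls = _branch_balls(dag, branch_of)
    homes = _home_terms(cfg, dag)
    non_root = sorted(set(dag.terms) - {root})

    m, v = cfg.terms_per_gene_mean - 1, cfg.terms_per_gene_sd**2
    use_nb = v > m > 0
    if use_nb:
        r = m * m / (v - m)
        p_nb = r / (r + m)

    rows: list[str] = []
    for i in range(1, cfg.n_genes + 1):
        gene = _gene_id(i)
        u = rng.random()
        if u < cfg.unannotated_fraction:
            continue
        iea_only = u < cfg.unannotated_fraction + cfg.iea_only_fraction
        count = 1 + (int(rng.negative_binomial(r, p_nb)) if use_nb else int(rng.poisson(m)))
        count = min(count, 40)
        # the home term itself, then distinct local-neighborhood draws,
        # remainder from anywhere in the ontology
        local_pool = balls[homes[gene]]
        n_local = min(int(round(cfg.home_branch_bias * count)), len(local_pool))
        chosen: set[str] = {homes[gene]}
        if n_local > 0:
            chosen.update(
                local_pool[j]
                for j in rng.choice(len(local_pool), size=n_local, replace=False)
            )
        rest = [t for t in non_root if t not in chosen]
        n_rest = min(count - len(chosen) + 1, len(rest))
        if n_rest > 0:
            chosen.update(rest[j] for j in rng.choice(len(rest), size=n_rest, replace=False))
        for term in sorted(chosen):
            if iea_only:
                ev = "IEA"
            else:
                ev = "IEA" if rng.random() < cfg.iea_fraction else "EXP"
            rows.append(
                "\t".join(
                    [
                        "SYNDB", gene, gene, "", term, "SYNREF:1", ev, "", "P",
                        "", "", "protein", "taxon:9606", "20200101", "SYNDB", "", "",
                    ]
                )
            )
    return "!gaf-version: 2.1\n" + "\n".join(rows) + "\n"


def _pathway_name(theme: int, j: int) -> str:
    motifs = (
        "signaling cascade", "biosynthetic route", "transport program",
        "assembly process", "regulatory circuit", "response program",
        "homeostasis pathway", "remodeling pathway",
    )
    return f"synthetic {motifs[theme % len(motifs)]} {theme}.{j}"


def generate_pathways(
    cfg: GeneratorConfig, gaf_text: str, dag: OntologyDAG
) -> tuple[str, list[dict]]:
    """Emit GMT text plus per-pathway ground truth.

    Themed pathways sample ``home_branch_bias`` of their genes from their
    theme's gene pool, the rest uniformly; ``overlap_inflation`` of slots
    are drawn from a small hub-gene pool shared across all pathways, which
    inflates per-gene pathway membership the way promiscuous signaling
    genes do in real collections.  Planted extras: exact duplicates,
    disease/drug/addiction-named pathways, and sub-minimum tiny pathways.
    """
    rng = cfg.rng_for(_STAGE_PATHWAYS)
    genes = [_gene_id(i) for i in range(1, cfg.n_genes + 1)]
    branch_of = _branch_map(dag)
    homes = _home_terms(cfg, dag)
    # genes under each term: homes at the term or any of its descendants.
    # After propagation all of them carry the term, which is what gives a
    # seeded pathway its coherent enrichment signal.
    genes_under_term: dict[str, list[str]] = {t: [] for t in branch_of}
    for g in genes:
        for t in dag.ancestors(homes[g]) | {homes[g]}:
            if t in genes_under_term:
                genes_under_term[t].append(g)
    terms_by_branch: list[list[str]] = [[] for _ in range(cfg.n_themes)]
    for t in sorted(branch_of):
        terms_by_branch[branch_of[t]].append(t)
    hubs = genes[: max(1, cfg.n_genes // 20)]

    def seed_candidates(theme: int) -> list[str]:
        """Branch terms specific enough to seed a pathway (moderate pool)."""
        lo, hi = 10, max(20, cfg.n_genes // (2 * cfg.n_themes))
        ok = [t for t in terms_by_branch[theme] if lo <= len(genes_under_term[t]) <= hi]
        if ok:
            return ok
        return sorted(
            terms_by_branch[theme], key=lambda t: -len(genes_under_term[t])
        )[:5]

    truth: list[dict] = []
    lines: list[str] = []
    base: list[tuple[str, str, list[str], int]] = []

    def sample_genes(
        theme: int, size: int,
        seed_term: str | None = None, second_seed: str | None = None,
    ) -> list[str]:
        local = genes_under_term[seed_term] if seed_term else []
        second = genes_under_term[second_seed] if second_seed else []
        size = min(size, cfg.n_genes - 1)
        out: set[str] = set()
        attempts = 0
        while len(out) < size and attempts < 50 * size:
            attempts += 1
            u = rng.random()
            if u < cfg.overlap_inflation:
                pool = hubs
            elif u < cfg.overlap_inflation + cfg.pathway_theme_bias and local:
                # a slice of the themed draws comes from the secondary
                # functional locality (possibly another branch: cross-talk)
                if second and rng.random() < cfg.secondary_seed_fraction:
                    pool = second
                else:
                    pool = local
            else:
                pool = genes
            out.add(pool[int(rng.integers(len(pool)))])
        # deterministic fill if the biased pools cannot reach the size
        # (possible when overlap_inflation + pathway_theme_bias >= 1)
        for g in genes:
            if len(out) >= size:
                break
            out.add(g)
        return sorted(out)

    def draw_size() -> int:
        s = int(round(rng.lognormal(np.log(cfg.pathway_size_median), cfg.pathway_size_sigma)))
        return max(8, min(s, cfg.n_genes // 2))

    idx = 0
    for theme in range(cfg.n_themes):
        seeds = seed_candidates(theme)
        for j in range(cfg.pathways_per_theme):
            idx += 1
            pid = f"SYNP{idx:04d}"
            name = _pathway_name(theme, j)
            # each pathway nucleates around one functional locality (seed
            # term) plus a secondary locality, sometimes in another branch,
            # emulating cross-process pathways that knit the network together
            seed_term = seeds[int(rng.integers(len(seeds)))]
            if rng.random() < cfg.cross_theme_pathway_prob and cfg.n_themes > 1:
                other = (theme + 1 + int(rng.integers(cfg.n_themes - 1))) % cfg.n_themes
                spool = seed_candidates(other)
            else:
                spool = seeds
            second_seed = spool[int(rng.integers(len(spool)))]
            size = draw_size()
            # small pathways stay functionally pure; only larger ones span
            # a second locality
            members = sample_genes(
                theme, size, seed_term, second_seed if size >= 20 else None
            )
            base.append((pid, name, members, theme))
            truth.append(
                {"pathway": pid, "name": name, "theme": theme, "planted": "themed",
                 "seed_term": seed_term}
            )

    # exact duplicates of existing pathways (same gene set, new id)
    n_dup = int(round(cfg.duplicate_fraction * len(base)))
    for d in range(n_dup):
        src = base[int(rng.integers(len(base)))]
        idx += 1
        pid = f"SYNP{idx:04d}"
        name = src[1] + " (duplicate)"
        base.append((pid, name, list(src[2]), src[3]))
        truth.append(
            {"pathway": pid, "name": name, "theme": src[3], "planted": "duplicate",
             "seed_term": ""}
        )

    # disease / drug / addiction named pathways (removed by name filtering)
    flavor_names = (
        "colorectal cancer pathway", "asthma pathway", "HIV infection response",
        "doxorubicin metabolism", "statin pathway", "tamoxifen drug metabolism",
        "cocaine addiction", "nicotine addiction", "morphine addiction",
    )
    for d in range(cfg.n_disease_named):
        idx += 1
        pid = f"SYNP{idx:04d}"
        theme = int(rng.integers(cfg.n_themes))
        name = flavor_names[d % len(flavor_names)]
        dn_seeds = seed_candidates(theme)
        seed_term = dn_seeds[int(rng.integers(len(dn_seeds)))]
        members = sample_genes(theme, draw_size(), seed_term)
        base.append((pid, name, members, theme))
        truth.append(
            {"pathway": pid, "name": name, "theme": theme, "planted": "disease_named",
             "seed_term": seed_term}
        )

    # tiny pathways below the annotated-gene minimum
    for d in range(cfg.n_tiny_pathways):
        idx += 1
        pid = f"SYNP{idx:04d}"
        theme = int(rng.integers(cfg.n_themes))
        name = f"synthetic fragment pathway {d}"
        members = sample_genes(theme, 3)
        base.append((pid, name, members, theme))
        truth.append(
            {"pathway": pid, "name": name, "theme": theme, "planted": "tiny",
             "seed_term": ""}
        )

    for pid, name, members, _theme in base:
        lines.append("\t".join([pid, name, *members]))
    return "\n".join(lines) + "\n", truth


def generate_diseases(
    cfg: GeneratorConfig, pathway_truth: list[dict], gmt_text: str
) -> tuple[str, list[dict]]:
    """Emit a disease gene table plus ground truth.

    Planted diseases sample their genes from 3-6 themed pathways of one
    theme; null diseases sample genes uniformly from the pathway gene
    universe.  Half the planted names match the cancer term list so the
    name-based system selection is exercised.
    """
    rng = cfg.rng_for(_STAGE_DISEASES)
    pathways: dict[str, list[str]] = {}
    for line in gmt_text.splitlines():
        if not line.strip():
            continue
        pid, _name, *members = line.split("\t")
        pathways[pid] = members
    themed = [r for r in pathway_truth if r["planted"] == "themed"]
    by_theme: dict[int, list[str]] = {}
    for r in themed:
        by_theme.setdefault(r["theme"], []).append(r["pathway"])
    universe = sorted({g for members in pathways.values() for g in members})

    rows: list[str] = []
    truth: list[dict] = []
    templates = cfg.disease_name_templates
    for d in range(cfg.n_planted_diseases):
        did = f"SYND{d + 1:03d}"
        theme = d % cfg.n_themes
        name = templates[d % len(templates)].format(i=d + 1)
        cands = sorted(by_theme[theme])
        n_src = min(int(rng.integers(5, 10)), len(cands))
        # anchor on one pathway and take its most gene-overlapping theme
        # mates as co-sources, so the disease hits functionally close nodes
        anchor = cands[int(rng.integers(len(cands)))]
        overlap = sorted(
            (c for c in cands if c != anchor),
            key=lambda c: (-len(set(pathways[c]) & set(pathways[anchor])), c),
        )
        sources = [anchor] + overlap[: n_src - 1]
        # disease loci are the functional core shared by the source
        # pathways: theme-homed genes, preferring genes that recur across
        # several sources (hub/background genes are excluded)
        themed = [
            g
            for c in sources
            for g in pathways[c]
            if (int(g[4:]) - 1) % cfg.n_themes == theme
        ]
        from collections import Counter as _Counter

        counts = _Counter(themed)
        core = sorted(g for g, c in counts.items() for _ in range(c) if c >= 2)
        pool = core if len(set(core)) >= cfg.genes_per_disease else sorted(themed)
        chosen: set[str] = set()
        size = min(cfg.genes_per_disease, len(set(pool)))
        while len(chosen) < size:
            chosen.add(pool[int(rng.integers(len(pool)))])
        for gene in sorted(chosen):
            rows.append("\t".join([did, name, gene, "disease"]))
        truth.append(
            {
                "disease": did,
                "name": name,
                "status": "planted",
                "theme": theme,
                "source_pathways": ";".join(sources),
            }
        )
    for d in range(cfg.n_null_diseases):
        did = f"SYND{cfg.n_planted_diseases + d + 1:03d}"
        name = f"synthetic null disorder {d + 1}"
        chosen = rng.choice(len(universe), size=cfg.genes_per_disease, replace=False)
        for gi in sorted(chosen):
            rows.append("\t".join([did, name, universe[gi], "disease"]))
        truth.append(
            {"disease": did, "name": name, "status": "null", "theme": -1,
             "source_pathways": ""}
        )
    return "\n".join(rows) + "\n", truth


@dataclass
class SyntheticCorpus:
    obo: str
    gaf: str
    gmt: str
    diseases: str
    pathway_truth: list[dict] = field(default_factory=list)
    disease_truth: list[dict] = field(default_factory=list)


def generate_corpus(cfg: GeneratorConfig = STD_V1) -> SyntheticCorpus:
    """Generate the full corpus in memory."""
    import io

    obo = generate_ontology(cfg)
    dag = load_obo(io.StringIO(obo))
    gaf = generate_annotations(cfg, dag)
    gmt, ptruth = generate_pathways(cfg, gaf, dag)
    dis, dtruth = generate_diseases(cfg, ptruth, gmt)
    return SyntheticCorpus(
        obo=obo, gaf=gaf, gmt=gmt, diseases=dis,
        pathway_truth=ptruth, disease_truth=dtruth,
    )


def generate_all(outdir: str | os.PathLike, cfg: GeneratorConfig = STD_V1) -> dict[str, Path]:
    """Write the corpus and its ground truth to *outdir*; return file paths."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = generate_corpus(cfg)
    paths = {
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "gmt": out / "pathways.gmt",
        "diseases": out / "diseases.tsv",
        "pathway_truth": out / "pathway_truth.tsv",
        "disease_truth": out / "disease_truth.tsv",
    }
    paths["obo"].write_text(corpus.obo)
    paths["gaf"].write_text(corpus.gaf)
    paths["gmt"].write_text(corpus.gmt)
    paths["diseases"].write_text(corpus.diseases)
    pd.DataFrame(corpus.pathway_truth).to_csv(paths["pathway_truth"], sep="\t", index=False)
    pd.DataFrame(corpus.disease_truth).to_csv(paths["disease_truth"], sep="\t", index=False)
    return paths


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(cfg, seed=seed)
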