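"""End-to-end discovery of miRNA-lncRNA-mRNA regulatory modules.

Stage order: differential expression (stability-selected for mRNA/lncRNA,
single-pass for miRNA) -> confidence+co-expression interaction network over
DE mRNAs -> mRNA classifier + attribution -> joint MCC x contribution
candidate selection -> sign-constrained ceRNA triplet screen over validated
target pairs -> ceRNA network and classifier -> potential-ceRNA subnetwork
(contribution > 1e-4) -> direction-consistent per-miRNA modules.

A ceRNA triplet (mRNA, miRNA, lncRNA) passes the screen when the miRNA is
negatively correlated with both partners, the partners are positively
correlated with each other, all three correlations have p < 0.05, and both
(miRNA, partner) pairs are validated targets.
"""

from __future__ import annotations

import importlib.metadata
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import diffexpr, dnn, io as cio, network
from .attribution import ContributionTable, compute_attributions, prune_and_retrain
from .simulate import CLASSES, ExpressionDataset, GroundTruth

logger = logging.getLogger("cernamod")

TRIPLET_COLUMNS = [
    "mrna_id", "mirna_id", "lncrna_id",
    "r_mm", "p_mm", "r_ml", "p_ml", "r_gl", "p_gl",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def select_candidate_mrnas(
    contributions: pd.Series,
    centrality: pd.Series,
    shap_threshold: float = 1e-4,
    mcc_threshold: float = 8.0,
) -> list:
    """mRNAs with MCC strictly above ``mcc_threshold`` and mean-|attribution|
    strictly above ``shap_threshold``; nodes without an MCC entry count as 0."""
    if isinstance(contributions, ContributionTable):
        contributions = contributions.shap
    mcc = centrality.reindex(contributions.index).fillna(0)
    mask = (contributions.to_numpy() > shap_threshold) & (mcc.to_numpy() > mcc_threshold)
    selected = sorted(contributions.index[mask])
    if not selected:
        logger.warning("candidate selection produced an empty set")
    return selected


def _eligible(de_table: pd.DataFrame, ids) -> list:
    """Features of the DE table that are significant (and stable when tracked)."""
    sub = de_table.loc[de_table.index.intersection(ids)]
    ok = sub["direction"].to_numpy() != "none"
    if "stable" in sub.columns:
        ok &= sub["stable"].to_numpy().astype(bool)
    return sorted(sub.index[ok])


def screen_triplets(
    expr: pd.DataFrame,
    de_table: pd.DataFrame,
    targets_mrna: pd.DataFrame,
    targets_lncrna: pd.DataFrame,
    candidate_mrnas,
    p_threshold: float = 0.05,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Enumerate validated (miRNA, mRNA) x (miRNA, lncRNA) pairs and keep
    triplets satisfying the ceRNA sign pattern at significance ``p_threshold``.

    ``expr`` is the normalized abundance matrix holding all three RNA classes
    (rows) over the same samples; miRNAs and lncRNAs are restricted to
    significant DE features and mRNAs to ``candidate_mrnas``. When ``samples``
    metadata is supplied, expression is centered within condition before
    correlating, so triplets must co-vary beyond the shared tumor/normal
    shift (otherwise any two differential features whose directions align
    would correlate spuriously across the pooled samples).
    """
    if targets_mrna.empty or targets_lncrna.empty:
        logger.warning("empty target table(s); no triplets can be formed")
        return pd.DataFrame(columns=TRIPLET_COLUMNS)
    if samples is not None:
        expr = expr[list(samples["sample_id"])]
        centered = expr.to_numpy(dtype=float).copy()
        cond = samples["condition"].to_numpy()
        for value in np.unique(cond):
            cols = cond == value
            centered[:, cols] -= centered[:, cols].mean(axis=1, keepdims=True)
        expr = pd.DataFrame(centered, index=expr.index, columns=expr.columns)
    candidates = sorted(set(candidate_mrnas) & set(expr.index))
    mirnas = set(_eligible(de_table, set(targets_mrna["mirna_id"]) | set(targets_lncrna["mirna_id"])))
    mirnas &= set(expr.index)
    lncrnas = set(_eligible(de_table, set(targets_lncrna["target_id"]))) & set(expr.index)

    tm = targets_mrna[
        targets_mrna["mirna_id"].isin(mirnas) & targets_mrna["target_id"].isin(candidates)
    ]
    tl = targets_lncrna[
        targets_lncrna["mirna_id"].isin(mirnas) & targets_lncrna["target_id"].isin(lncrnas)
    ]
    shared = sorted(set(tm["mirna_id"]) & set(tl["mirna_id"]))
    if not shared:
        return pd.DataFrame(columns=TRIPLET_COLUMNS)

    mm_pairs = sorted({(mi, m) for mi, m in zip(tm["mirna_id"], tm["target_id"]) if mi in shared})
    ml_pairs = sorted({(mi, l) for mi, l in zip(tl["mirna_id"], tl["target_id"]) if mi in shared})
    corr_mm = network.correlate_rows(expr, mm_pairs).set_index(["node_a", "node_b"])
    corr_ml = network.correlate_rows(expr, ml_pairs).set_index(["node_a", "node_b"])

    keep_mm = {}
    for (mi, m), row in corr_mm.iterrows():
        if row["r"] < 0 and row["p"] < p_threshold:
            keep_mm.setdefault(mi, []).append((m, row["r"], row["p"]))
    keep_ml = {}
    for (mi, l), row in corr_ml.iterrows():
        if row["r"] < 0 and row["p"] < p_threshold:
            keep_ml.setdefault(mi, []).append((l, row["r"], row["p"]))

    gl_pairs = sorted(
        {
            (m, l)
            for mi in shared
            for (m, _, _) in keep_mm.get(mi, [])
            for (l, _, _) in keep_ml.get(mi, [])
        }
    )
    if not gl_pairs:
        return pd.DataFrame(columns=TRIPLET_COLUMNS)
    corr_gl = network.correlate_rows(expr, gl_pairs).set_index(["node_a", "node_b"])

    rows = []
    for mi in shared:
        for m, r_mm, p_mm in keep_mm.get(mi, []):
            for l, r_ml, p_ml in keep_ml.get(mi, []):
                gl = corr_gl.loc[(m, l)]
                if gl["r"] > 0 and gl["p"] < p_threshold:
                    rows.append((m, mi, l, r_mm, p_mm, r_ml, p_ml, gl["r"], gl["p"]))
    out = pd.DataFrame(rows, columns=TRIPLET_COLUMNS)
    return out.sort_values(["mirna_id", "mrna_id", "lncrna_id"], ignore_index=True)


def build_cerna_network(triplets: pd.DataFrame, interaction_graph: nx.Graph) -> nx.Graph:
    """Mixed ceRNA network: triplet pairings plus interaction edges among
    included mRNAs; nodes carry ``rna_class``, edges carry ``kind``."""
    g = nx.Graph()
    for _, t in triplets.iterrows():
        g.add_node(t["mrna_id"], rna_class="mrna")
        g.add_node(t["mirna_id"], rna_class="mirna")
        g.add_node(t["lncrna_id"], rna_class="lncrna")
        g.add_edge(t["mirna_id"], t["mrna_id"], kind="mirna-mrna")
        g.add_edge(t["mirna_id"], t["lncrna_id"], kind="mirna-lncrna")
        g.add_edge(t["mrna_id"], t["lncrna_id"], kind="mrna-lncrna")
    mrnas = [n for n, d in g.nodes(data=True) if d["rna_class"] == "mrna"]
    for u, v, data in interaction_graph.edges(data=True):
        if u in mrnas and v in mrnas and not g.has_edge(u, v):
            g.add_edge(u, v, kind="interaction", **{k: data[k] for k in ("confidence",) if k in data})
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def select_potential_cernas(
    contributions: pd.Series,
    net: nx.Graph,
    threshold: float = 1e-4,
) -> nx.Graph:
    """Induced subnetwork on nodes with contribution strictly above threshold;
    isolated nodes are dropped and each node records its contribution."""
    if isinstance(contributions, ContributionTable):
        contributions = contributions.shap
    passing = [n for n in net.nodes if float(contributions.get(n, 0.0)) > threshold]
    sub = net.subgraph(passing).copy()
    sub.remove_nodes_from(list(nx.isolates(sub)))
    if sub.number_of_nodes() == 0:
        logger.warning("potential-ceRNA subnetwork is empty")
    for n in sub.nodes:
        sub.nodes[n]["shap_value"] = float(contributions.get(n, 0.0))
    return sub


@dataclass(frozen=True)
class RegulatoryModule:
    """One miRNA with its screened targets sharing an expression direction."""

    mirna_id: str
    direction: str
    mrna_ids: tuple
    lncrna_ids: tuple
    primary: bool = True
    mirna_shap: float = 0.0

    @property
    def members(self) -> tuple:
        return tuple(sorted(self.mrna_ids + self.lncrna_ids))

    def to_dict(self) -> dict:
        return {
            "mirna_id": self.mirna_id,
            "direction": self.direction,
            "mrna_ids": list(self.mrna_ids),
            "lncrna_ids": list(self.lncrna_ids),
            "primary": self.primary,
            "mirna_shap": self.mirna_shap,
        }


def extract_modules(subnetwork: nx.Graph, de_table: pd.DataFrame) -> list:
    """Group each miRNA's validated-target neighbors by DE direction.

    One module per (miRNA, direction) group containing at least one mRNA;
    when both direction groups qualify, the larger is marked primary.
    Modules are ordered by the miRNA's contribution, descending.
    """
    modules = []
    direction = de_table["direction"]
    for mi in sorted(n for n, d in subnetwork.nodes(data=True) if d.get("rna_class") == "mirna"):
        groups: dict = {}
        for nb in subnetwork.neighbors(mi):
            kind = subnetwork.edges[mi, nb].get("kind", "")
            if kind not in ("mirna-mrna", "mirna-lncrna"):
                continue
            d = direction.get(nb, "none")
            if d not in ("up", "down"):
                continue
            groups.setdefault(d, {"mrna": [], "lncrna": []})
            groups[d][subnetwork.nodes[nb]["rna_class"]].append(nb)
        qualifying = {d: g for d, g in groups.items() if g["mrna"]}
        if not qualifying:
            continue
        largest = max(
            qualifying,
            key=lambda d: (len(qualifying[d]["mrna"]) + len(qualifying[d]["lncrna"]), d),
        )
        for d, g in sorted(qualifying.items()):
            if not g["lncrna"]:
                logger.info("module %s/%s has no lncRNA member", mi, d)
            modules.append(
                RegulatoryModule(
                    mirna_id=mi,
                    direction=d,
                    mrna_ids=tuple(sorted(g["mrna"])),
                    lncrna_ids=tuple(sorted(g["lncrna"])),
                    primary=(d == largest),
                    mirna_shap=float(subnetwork.nodes[mi].get("shap_value", 0.0)),
                )
            )
    modules.sort(key=lambda m: (-m.mirna_shap, m.mirna_id, m.direction))
    return modules


@dataclass
class PipelineResult:
    de_tables: dict
    interaction_graph: nx.Graph
    centrality: pd.Series
    mrna_features: list
    mrna_result: dnn.TrainResult
    mrna_contrib: ContributionTable
    candidates: list
    triplets: pd.DataFrame
    cerna_network: nx.Graph
    cerna_result: dnn.TrainResult | None
    cerna_contrib: ContributionTable | None
    subnetwork: nx.Graph
    modules: list
    manifest: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def log_abundance(dataset: ExpressionDataset) -> pd.DataFrame:
    """Combined log2(abundance + 1) matrix over all three RNA classes."""
    frames = [np.log2(dataset.abundance[c] + 1.0) for c in CLASSES]
    return pd.concat(frames, axis=0)


def run_pipeline(
    dataset: ExpressionDataset,
    config: cio.PipelineConfig | None = None,
    outdir=None,
) -> PipelineResult:
    """Execute every stage on one dataset; optionally write all artifacts.

    Writes (under ``outdir``): per-class DE tables, the filtered interaction
    edge list, MCC centrality, both contribution tables, screened triplets,
    subnetwork edges, ``modules.json`` and a ``manifest.json`` recording
    versions, seeds, thresholds and stage counts.
    """
    config = config or cio.PipelineConfig()
    seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(8) % (2**31)]

    de_tables = _stage("diffexpr")(_run_de)(dataset, config, seeds)
    logab = log_abundance(dataset)
    y = (dataset.samples["condition"] == "tumor").to_numpy().astype(float)
    sample_order = list(dataset.samples["sample_id"])
    logab = logab[sample_order]

    graph = _stage("network")(_run_network)(dataset, de_tables, logab, config)
    centrality = _stage("network")(network.mcc_centrality)(graph)

    mrna_features = sorted(graph.nodes)
    if not mrna_features:
        raise PipelineError("stage 'network' failed: interaction network is empty")
    mrna_features, mrna_result, mrna_contrib = _stage("deepmodel")(_run_classifier)(
        logab, y, mrna_features, config.hidden_sizes, config, seeds[1], prune=True
    )

    candidates = select_candidate_mrnas(
        mrna_contrib.shap, centrality, config.shap_threshold, config.mcc_threshold
    )

    de_all = pd.concat([de_tables[c] for c in CLASSES], axis=0)
    triplets = _stage("triplets")(screen_triplets)(
        logab, de_all, dataset.targets_mrna, dataset.targets_lncrna,
        candidates, config.corr_p, samples=dataset.samples,
    )
    cerna_net = _stage("cerna_network")(build_cerna_network)(triplets, graph)

    cerna_result = cerna_contrib = None
    subnetwork = nx.Graph()
    modules: list = []
    if cerna_net.number_of_nodes() > 0:
        nodes, cerna_result, cerna_contrib = _stage("cerna_model")(_run_classifier)(
            logab, y, sorted(cerna_net.nodes), config.cerna_hidden_sizes, config,
            seeds[2], prune=False,
        )
        subnetwork = select_potential_cernas(
            cerna_contrib.shap, cerna_net, config.shap_threshold
        )
        modules = _stage("modules")(extract_modules)(subnetwork, de_all)
    else:
        logger.warning("ceRNA network is empty; no modules extracted")

    manifest = _build_manifest(config, de_tables, graph, candidates, triplets, cerna_net, subnetwork, modules, mrna_result, cerna_result)
    result = PipelineResult(
        de_tables=de_tables,
        interaction_graph=graph,
        centrality=centrality,
        mrna_features=mrna_features,
        mrna_result=mrna_result,
        mrna_contrib=mrna_contrib,
        candidates=candidates,
        triplets=triplets,
        cerna_network=cerna_net,
        cerna_result=cerna_result,
        cerna_contrib=cerna_contrib,
        subnetwork=subnetwork,
        modules=modules,
        manifest=manifest,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def _run_de(dataset, config, seeds):
    tables = {}
    for i, c in enumerate(("mrna", "lncrna")):
        tables[c] = diffexpr.stability_select(
            dataset.counts[c],
            dataset.samples,
            rounds=config.stability_rounds,
            fraction=config.stability_fraction,
            seed=seeds[3 + i],
            log2fc_threshold=config.de_log2fc,
            fdr_threshold=config.de_fdr,
        )
    # miRNA classes are small and sparse: single-pass, no subsampling
    t = diffexpr.test_differential(
        dataset.counts["mirna"], dataset.samples,
        log2fc_threshold=config.de_log2fc, fdr_threshold=config.de_fdr,
    )
    t["stable"] = t["direction"].to_numpy() != "none"
    tables["mirna"] = t
    return tables


def _run_network(dataset, de_tables, logab, config):
    stable = de_tables["mrna"].index[de_tables["mrna"]["stable"].astype(bool)]
    return network.build_interaction_graph(
        dataset.interactions,
        logab.loc[logab.index.intersection(stable)],
        conf_threshold=config.confidence,
        p_threshold=config.corr_p,
    )


def _run_classifier(logab, y, features, hidden_sizes, config, seed, prune):
    X = logab.loc[features].T
    spec = dnn.ModelSpec(
        n_features=len(features),
        hidden_sizes=tuple(hidden_sizes),
        use_regularization=config.use_regularization,
    )
    tcfg = dnn.TrainConfig(
        batch_size=config.batch_size,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        split_fraction=config.split_fraction,
        n_repeats=config.n_repeats,
        seed=seed,
    )
    model = dnn.build_model(spec, seed=seed)
    result = dnn.train(model, X.to_numpy(), y, tcfg)
    background = X.to_numpy()[result.train_idx]
    contrib = compute_attributions(
        model, X, background, seed=seed, max_background=config.background_size
    )
    if prune:
        kept, new_result, new_contrib = prune_and_retrain(
            spec, X, y, contrib, tcfg, seed=seed, max_background=config.background_size
        )
        if new_result is not None:
            logger.info("pruned %d zero-contribution features", len(features) - len(kept))
            return kept, new_result, new_contrib
        return kept, result, contrib
    return list(features), result, contrib


def _as_float(x):
    return None if x is None else float(x)


def _build_manifest(config, de_tables, graph, candidates, triplets, cerna_net, subnetwork, modules, mrna_result, cerna_result):
    try:
        version = importlib.metadata.version("cernamod")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    counts = {
        f"n_stable_de_{c}": int(de_tables[c]["stable"].astype(bool).sum()) for c in CLASSES
    }
    return {
        "package_version": version,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "config": config.to_dict(),
        **counts,
        "n_network_nodes": graph.number_of_nodes(),
        "n_network_edges": graph.number_of_edges(),
        "n_candidate_mrnas": len(candidates),
        "n_triplets": int(len(triplets)),
        "n_cerna_nodes": cerna_net.number_of_nodes(),
        "n_potential_cernas": subnetwork.number_of_nodes(),
        "n_modules": len(modules),
        "mrna_val_accuracy": _as_float((mrna_result.final or {}).get("val_acc")),
        "cerna_val_accuracy": _as_float((cerna_result.final or {}).get("val_acc")) if cerna_result else None,
    }


def write_results(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c, table in result.de_tables.items():
        table.to_csv(outdir / f"de_{c}.tsv", sep="\t", index_label="feature_id")
    edges = nx.to_pandas_edgelist(result.interaction_graph, source="node_a", target="node_b")
    cio.write_edge_list(edges.sort_values(["node_a", "node_b"], ignore_index=True), outdir / "interactions_filtered.tsv")
    result.centrality.rename("mcc").to_csv(outdir / "centrality.tsv", sep="\t", index_label="node")
    result.mrna_contrib.shap.to_csv(outdir / "contributions_mrna.tsv", sep="\t", index_label="feature_id")
    result.triplets.to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    if result.cerna_contrib is not None:
        result.cerna_contrib.shap.to_csv(outdir / "contributions_cerna.tsv", sep="\t", index_label="feature_id")
    sub_edges = nx.to_pandas_edgelist(result.subnetwork, source="node_a", target="node_b")
    if not sub_edges.empty:
        sub_edges = sub_edges.sort_values(["node_a", "node_b"], ignore_index=True)
    sub_edges.to_csv(outdir / "subnetwork_edges.tsv", sep="\t", index=False)
    cio.write_json([m.to_dict() for m in result.modules], outdir / "modules.json")
    cio.write_json(result.manifest, outdir / "manifest.json")


# ---------------------------------------------------------------------------
# recovery scoring against planted ground truth


def score_triplets(triplets: pd.DataFrame, truth: GroundTruth) -> dict:
    """Recall/precision of screened triplets against the planted list."""
    found = {tuple(t) for t in zip(triplets["mrna_id"], triplets["mirna_id"], triplets["lncrna_id"])}
    planted = {(t["mrna"], t["mirna"], t["lncrna"]) for t in truth.triplets}
    tp = len(found & planted)
    return {
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(found) if found else float("nan"),
        "n_found": len(found),
        "n_planted": len(planted),
    }


def score_modules(modules: list, truth: GroundTruth) -> dict:
    """Per-module member Jaccard and pooled member recall vs planted modules."""
    found = {}
    for m in modules:
        found.setdefault(m.mirna_id, set()).update(m.members)
    jaccard = {}
    pooled_tp = pooled_planted = 0
    for mirna, planted in truth.modules.items():
        pset = set(planted["mrna_ids"]) | set(planted["lncrna_ids"])
        fset = found.get(mirna, set())
        inter = len(pset & fset)
        jaccard[mirna] = inter / len(pset | fset) if (pset | fset) else float("nan")
        pooled_tp += inter
        pooled_planted += len(pset)
    return {
        "jaccard": jaccard,
        "pooled_recall": pooled_tp / pooled_planted if pooled_planted else float("nan"),
        "n_planted_mirnas": len(truth.modules),
        "n_recovered_mirnas": sum(1 for mi in truth.modules if found.get(mi)),
    }
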