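"""Seeded synthetic paired tumor/normal expression data with planted structure.

The generator emulates the statistical shape the module-discovery pipeline
assumes, so every downstream stage is testable without controlled-access data:

* paired case/control design (``n_pairs`` tumor/normal pairs);
* negative-binomial counts around lognormal per-feature baselines, with
  lognormally varying library sizes so between-sample normalization is
  non-trivial;
* planted differentially expressed features per RNA class with
  case mean = control mean x 2^(+-planted_log2fc);
* a planted protein-level interaction graph: same-direction DE mRNAs grouped
  into cliques with confidence scores above the retention threshold, plus
  sparse background edges;
* planted ceRNA triplets (mRNA, miRNA, lncRNA): each planted miRNA carries a
  per-sample latent factor that loads negatively on the miRNA and positively
  on its partner mRNAs/lncRNAs, so sample-wise Pearson correlations satisfy
  corr(miRNA, mRNA) < 0, corr(miRNA, lncRNA) < 0, corr(mRNA, lncRNA) > 0 with
  within-condition magnitude near ``triplet_strength``.

Abundance is reported FPKM-like (counts scaled per library and per fixed
synthetic feature length); counts feed differential expression, abundance
feeds correlation screens and classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio

CLASSES = ("mrna", "lncrna", "mirna")

_CLIQUE_SIZE = 5          # planted clique size among same-direction DE mRNAs
_TRIPLETS_PER_MIRNA = 5   # planted triplets sharing one miRNA (one module)
_DECOYS_PER_MIRNA = 10    # DE-agnostic decoy rows per DE miRNA per target table
_LIBSIZE_SIGMA = 0.3      # lognormal spread of library sizes (~ +-30%)


class ConfigError(ValueError):
    """A simulation parameter is out of range; the message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``planted_log2fc`` must be 0 (pure null, for calibration studies) or
    >= 1 so planted features clear the |log2FC| > 1 gate in expectation.
    """

    n_pairs: int = 100
    n_mrna: int = 1200
    n_lncrna: int = 400
    n_mirna: int = 150
    n_de_per_class: int = 60
    planted_log2fc: float = 2.0
    n_triplets: int = 50
    triplet_strength: float = 0.7
    dispersion: float = 0.1
    baseline_mean_range: tuple = (20.0, 500.0)
    edge_prob: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pairs", "n_mrna", "n_lncrna", "n_mirna"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_de_per_class < 0:
            raise ConfigError(f"n_de_per_class must be >= 0, got {self.n_de_per_class}")
        if self.n_de_per_class > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ConfigError("n_de_per_class exceeds the smallest class size")
        if self.planted_log2fc != 0 and self.planted_log2fc < 1:
            raise ConfigError(
                f"planted_log2fc must be 0 or >= 1, got {self.planted_log2fc}"
            )
        if self.n_triplets < 0 or self.n_triplets > self.n_de_per_class:
            raise ConfigError(
                "n_triplets must satisfy 0 <= n_triplets <= n_de_per_class "
                f"(got {self.n_triplets} with n_de_per_class={self.n_de_per_class})"
            )
        if self.n_triplets:
            need = math.ceil(self.n_triplets / _TRIPLETS_PER_MIRNA)
            if need > self.n_de_per_class:
                raise ConfigError("n_triplets requires more planted miRNAs than n_de_per_class")
        if not (0.0 < self.triplet_strength < 1.0):
            raise ConfigError(f"triplet_strength must lie in (0,1), got {self.triplet_strength}")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigError(f"baseline_mean_range must be 0 < lo <= hi, got {self.baseline_mean_range}")
        if not (0.0 <= self.edge_prob <= 1.0):
            raise ConfigError(f"edge_prob must lie in [0,1], got {self.edge_prob}")


@dataclass
class ExpressionDataset:
    """Counts and FPKM-like abundance per RNA class, plus study annotations."""

    counts: dict           # class -> DataFrame features x samples (ints)
    abundance: dict        # class -> DataFrame features x samples (floats)
    samples: pd.DataFrame  # sample_id, condition, pair_id
    interactions: pd.DataFrame  # node_a, node_b, confidence
    targets_mrna: pd.DataFrame  # mirna_id, target_id
    targets_lncrna: pd.DataFrame

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            all(self.counts[c].equals(other.counts[c]) for c in CLASSES)
            and all(self.abundance[c].equals(other.abundance[c]) for c in CLASSES)
            and self.samples.equals(other.samples)
            and self.interactions.equals(other.interactions)
            and self.targets_mrna.equals(other.targets_mrna)
            and self.targets_lncrna.equals(other.targets_lncrna)
        )


@dataclass
class GroundTruth:
    """Planted structure to score recovery against."""

    de_features: dict      # feature_id -> "up" | "down"
    triplets: list         # [{"mrna":..., "mirna":..., "lncrna":...}, ...]
    modules: dict          # mirna_id -> {"direction", "mrna_ids", "lncrna_ids"}
    graph_edges: list      # [[node_a, node_b, confidence], ...]

    def to_dict(self) -> dict:
        return {
            "de_features": self.de_features,
            "triplets": self.triplets,
            "modules": self.modules,
            "graph_edges": self.graph_edges,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_features=dict(d["de_features"]),
            triplets=list(d["triplets"]),
            modules=dict(d["modules"]),
            graph_edges=[list(e) for e in d["graph_edges"]],
        )


def _feature_ids(prefix: str, n: int) -> list:
    return [f"{prefix}{i:05d}" for i in range(n)]


def _residual_sd_log2(mu: np.ndarray, dispersion: float) -> np.ndarray:
    # delta-method sd of log2 NB counts around mean mu
    return np.sqrt(1.0 / mu + dispersion) / np.log(2.0)


def generate_dataset(config: SimulationConfig):
    """Generate one seeded dataset with its ground truth.

    Returns ``(ExpressionDataset, GroundTruth)``; identical configs produce
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = 2 * config.n_pairs

    pair_ids = [f"P{i:04d}" for i in range(config.n_pairs)]
    sample_ids = [f"T{i:04d}" for i in range(config.n_pairs)] + [
        f"N{i:04d}" for i in range(config.n_pairs)
    ]
    condition_sign = np.concatenate(
        [np.ones(config.n_pairs), -np.ones(config.n_pairs)]
    )  # +1 tumor, -1 normal
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": ["tumor"] * config.n_pairs + ["normal"] * config.n_pairs,
            "pair_id": pair_ids + pair_ids,
        }
    )

    sizes = {"mrna": config.n_mrna, "lncrna": config.n_lncrna, "mirna": config.n_mirna}
    prefixes = {"mrna": "MRNA", "lncrna": "LNC", "mirna": "MIR"}
    ids = {c: _feature_ids(prefixes[c], sizes[c]) for c in CLASSES}

    lo, hi = config.baseline_mean_range
    base_mean = {
        c: np.exp(rng.uniform(np.log(lo), np.log(hi), size=sizes[c])) for c in CLASSES
    }
    length_kb = {c: np.exp(rng.uniform(np.log(0.5), np.log(5.0), size=sizes[c])) for c in CLASSES}

    # planted DE features and their directions
    de_idx = {
        c: np.sort(rng.choice(sizes[c], size=config.n_de_per_class, replace=False))
        for c in CLASSES
    }
    direction = {c: np.zeros(sizes[c], dtype=int) for c in CLASSES}
    for c in CLASSES:
        direction[c][de_idx[c]] = rng.choice([-1, 1], size=config.n_de_per_class)

    # planted triplets: each planted miRNA drives one latent factor shared by
    # its partner mRNAs and its single partner lncRNA (one lncRNA per module,
    # mirroring the one-sponge structure of real ceRNA modules). Partners
    # share one direction, opposite the miRNA's. Because every partner of one
    # miRNA is coupled through the same factor, the set of planted triplets
    # equals the full (partner mRNA) x (partner lncRNA) cross product.
    triplets: list = []
    modules: dict = {}
    loading = {c: np.zeros(sizes[c]) for c in CLASSES}   # signed latent loadings
    factor_of = {c: np.full(sizes[c], -1, dtype=int) for c in CLASSES}
    n_factors = 0
    if config.n_triplets:
        n_factors = math.ceil(config.n_triplets / _TRIPLETS_PER_MIRNA)
        planted_mirna_idx = rng.choice(de_idx["mirna"], size=n_factors, replace=False)
        partner_mrna_idx = rng.choice(de_idx["mrna"], size=config.n_triplets, replace=False)
        partner_lnc_idx = rng.choice(de_idx["lncrna"], size=n_factors, replace=False)
        rho = config.triplet_strength
        gain = math.sqrt(rho / (1.0 - rho))
        for k, (mi, l) in enumerate(zip(planted_mirna_idx, partner_lnc_idx)):
            d_mi = int(rng.choice([-1, 1]))
            direction["mirna"][mi] = d_mi
            direction["lncrna"][l] = -d_mi
            for cls_, idx_, sign_ in (("mirna", mi, -1.0), ("lncrna", l, 1.0)):
                loading[cls_][idx_] = sign_ * gain * _residual_sd_log2(
                    base_mean[cls_][idx_], config.dispersion
                )
                factor_of[cls_][idx_] = k
            mirna_id = ids["mirna"][mi]
            lnc_id = ids["lncrna"][l]
            block = slice(k * _TRIPLETS_PER_MIRNA, min((k + 1) * _TRIPLETS_PER_MIRNA, config.n_triplets))
            mod_mrnas = []
            for m in partner_mrna_idx[block]:
                direction["mrna"][m] = -d_mi
                loading["mrna"][m] = gain * _residual_sd_log2(
                    base_mean["mrna"][m], config.dispersion
                )
                factor_of["mrna"][m] = k
                triplets.append(
                    {"mrna": ids["mrna"][m], "mirna": mirna_id, "lncrna": lnc_id}
                )
                mod_mrnas.append(ids["mrna"][m])
            modules[mirna_id] = {
                "direction": "up" if d_mi < 0 else "down",  # members' shared direction
                "mrna_ids": sorted(mod_mrnas),
                "lncrna_ids": [lnc_id],
            }

    latent = rng.standard_normal((max(n_factors, 1), n_samples)) if n_factors else np.zeros((1, n_samples))

    # per-class library factors: mRNA+lncRNA share the RNA-seq library,
    # miRNA-seq is a separate library
    lib_rna = np.exp(rng.normal(0.0, _LIBSIZE_SIGMA, size=n_samples))
    lib_mir = np.exp(rng.normal(0.0, _LIBSIZE_SIGMA, size=n_samples))
    lib_factor = {"mrna": lib_rna, "lncrna": lib_rna, "mirna": lib_mir}

    counts = {}
    for c in CLASSES:
        log2mu = (
            np.log2(base_mean[c])[:, None]
            + direction[c][:, None] * (config.planted_log2fc / 2.0) * condition_sign[None, :]
        )
        has_factor = factor_of[c] >= 0
        if has_factor.any():
            log2mu[has_factor] += (
                loading[c][has_factor, None]
                * latent[factor_of[c][has_factor], :]
            )
        mean = np.exp2(log2mu) * lib_factor[c][None, :]
        if config.dispersion > 0:
            n_nb = 1.0 / config.dispersion
            p_nb = n_nb / (n_nb + mean)
            mat = rng.negative_binomial(n_nb, p_nb)
        else:
            mat = rng.poisson(mean)
        counts[c] = pd.DataFrame(
            mat.astype(np.int64),
            index=pd.Index(ids[c], name="feature_id"),
            columns=sample_ids,
        )

    # FPKM-like abundance: RNA-seq classes share a library size
    rna_lib = counts["mrna"].to_numpy().sum(axis=0) + counts["lncrna"].to_numpy().sum(axis=0)
    mir_lib = counts["mirna"].to_numpy().sum(axis=0)
    lib_counts = {"mrna": rna_lib, "lncrna": rna_lib, "mirna": mir_lib}
    abundance = {}
    for c in CLASSES:
        denom = np.maximum(lib_counts[c], 1).astype(float)
        fpkm = counts[c].to_numpy() * 1.0e6 / denom[None, :] / length_kb[c][:, None]
        abundance[c] = pd.DataFrame(
            fpkm, index=pd.Index(ids[c], name="feature_id"), columns=sample_ids
        )

    interactions, graph_edges = _build_graph(config, rng, ids, de_idx, direction)
    targets_mrna, targets_lncrna = _build_targets(config, rng, ids, de_idx, triplets)

    dataset = ExpressionDataset(
        counts=counts,
        abundance=abundance,
        samples=samples,
        interactions=interactions,
        targets_mrna=targets_mrna,
        targets_lncrna=targets_lncrna,
    )
    truth = GroundTruth(
        de_features={
            ids[c][i]: ("up" if direction[c][i] > 0 else "down")
            for c in CLASSES
            for i in de_idx[c]
        },
        triplets=triplets,
        modules=modules,
        graph_edges=graph_edges,
    )
    return dataset, truth


def _build_graph(config, rng, ids, de_idx, direction):
    """Planted cliques among same-direction DE mRNAs + background edges."""
    edges = {}
    planted = []
    for sign in (1, -1):
        members = [i for i in de_idx["mrna"] if direction["mrna"][i] == sign]
        members = list(rng.permutation(members))
        starts = list(range(0, len(members), _CLIQUE_SIZE))
        # fold a short remainder into the previous clique so every planted
        # hub sits in a clique of at least _CLIQUE_SIZE nodes
        if len(starts) > 1 and len(members) - starts[-1] < _CLIQUE_SIZE:
            starts.pop()
        for i, start in enumerate(starts):
            end = starts[i + 1] if i + 1 < len(starts) else len(members)
            clique = members[start:end]
            for a in range(len(clique)):
                for b in range(a + 1, len(clique)):
                    u, v = sorted((ids["mrna"][clique[a]], ids["mrna"][clique[b]]))
                    conf = int(rng.integers(701, 1000))
                    edges[(u, v)] = conf
                    planted.append([u, v, conf])
    n_possible = config.n_mrna * (config.n_mrna - 1) // 2
    n_bg = rng.binomial(n_possible, config.edge_prob)
    if n_bg:
        a_idx = rng.integers(0, config.n_mrna, size=2 * n_bg)
        b_idx = rng.integers(0, config.n_mrna, size=2 * n_bg)
        added = 0
        for ai, bi in zip(a_idx, b_idx):
            if added >= n_bg or ai == bi:
                continue
            u, v = sorted((ids["mrna"][ai], ids["mrna"][bi]))
            if (u, v) in edges:
                continue
            edges[(u, v)] = int(rng.integers(150, 1000))
            added += 1
    rows = sorted((u, v, c) for (u, v), c in edges.items())
    interactions = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    return interactions, planted


def _build_targets(config, rng, ids, de_idx, triplets):
    """Planted target pairs plus DE-agnostic decoy rows per DE miRNA."""
    pairs_m = {(t["mirna"], t["mrna"]) for t in triplets}
    pairs_l = {(t["mirna"], t["lncrna"]) for t in triplets}
    for mi in de_idx["mirna"]:
        mirna_id = ids["mirna"][mi]
        for j in rng.integers(0, config.n_mrna, size=_DECOYS_PER_MIRNA):
            pairs_m.add((mirna_id, ids["mrna"][j]))
        for j in rng.integers(0, config.n_lncrna, size=_DECOYS_PER_MIRNA):
            pairs_l.add((mirna_id, ids["lncrna"][j]))
    targets_mrna = pd.DataFrame(sorted(pairs_m), columns=["mirna_id", "target_id"])
    targets_lncrna = pd.DataFrame(sorted(pairs_l), columns=["mirna_id", "target_id"])
    return targets_mrna, targets_lncrna


def write_dataset(dataset: ExpressionDataset, truth: GroundTruth, directory) -> list:
    """Write every table as TSV (+ ground-truth JSON); returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for c in CLASSES:
        p = directory / f"{c}_counts.tsv"
        cio.write_matrix(dataset.counts[c], p)
        written.append(p)
        p = directory / f"{c}_abundance.tsv"
        cio.write_matrix(dataset.abundance[c], p)
        written.append(p)
    cio.write_samples(dataset.samples, directory / "samples.tsv")
    cio.write_edge_list(dataset.interactions, directory / "interactions.tsv")
    cio.write_targets(dataset.targets_mrna, directory / "targets_mrna.tsv")
    cio.write_targets(dataset.targets_lncrna, directory / "targets_lncrna.tsv")
    cio.write_json(truth.to_dict(), directory / "ground_truth.json")
    written += [
        directory / "samples.tsv",
        directory / "interactions.tsv",
        directory / "targets_mrna.tsv",
        directory / "targets_lncrna.tsv",
        directory / "ground_truth.json",
    ]
    return written


def read_dataset(directory):
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    samples = cio.read_samples(directory / "samples.tsv")
    counts, abundance = {}, {}
    for c in CLASSES:
        counts[c] = cio.read_expression(directory / f"{c}_counts.tsv", samples)
        abundance[c] = cio.read_expression(directory / f"{c}_abundance.tsv", samples)
    dataset = ExpressionDataset(
        counts=counts,
        abundance=abundance,
        samples=samples,
        interactions=cio.read_edge_list(directory / "interactions.tsv"),
        targets_mrna=cio.read_targets(directory / "targets_mrna.tsv"),
        targets_lncrna=cio.read_targets(directory / "targets_lncrna.tsv"),
    )
    truth = GroundTruth.from_dict(cio.read_json(directory / "ground_truth.json"))
    return dataset, truth
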