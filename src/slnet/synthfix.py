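"""Seeded synthetic fixtures: scale-free-like signaling networks with a
cancer-gene subset, planted "bridge" pairs whose joint removal
disproportionately lengthens shortest paths, and companion annotation
tables (gene sets, drug targets, SL reference, drug sensitivity,
literature counts) in exactly the formats the readers accept.

The planted construction carves, for each planted pair (m cancer, n
non-cancer), a small satellite group whose members connect to the rest of
the network almost exclusively through m and n; one long backup route keeps
the graph connected when both are removed, so D_mn far exceeds D_m and
D_n while the pair sits at distance 2 (a shared neighbor) and n — chosen
among the highest-degree non-cancer hubs — stays on many cancer/non-cancer
shortest paths.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .graphcore import SignalingNetwork
from .netio import (DrugTargetRecord, GeneSetCollection, LiteratureCounts,
                    SensitivityRecord, SlnetError, canonical_pair, write_results)

log = logging.getLogger("slnet")

__all__ = ["FixtureBundle", "synth_network", "plant_bridge_pairs",
           "synth_annotations", "make_bundle"]

#: global study counts used by the synthetic literature tables
LITERATURE_GLOBALS = {"N": 10_000_000, "M_cancer": 500_000, "M_sl": 50_000}


def _subseed(seed: int, name: str) -> int:
    """Per-component sub-seed so adding a component never perturbs others."""
    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class FixtureBundle:
    network: SignalingNetwork
    planted_pairs: list            # (cancer, non_cancer) tuples
    gene_sets: GeneSetCollection
    drug_targets: list
    sl_reference: list             # canonical pairs
    sensitivity: list
    literature: list
    literature_globals: dict
    seed: int
    params: dict

    def write(self, outdir) -> dict:
        """Write the bundle as the plain-text files netio reads, plus a
        manifest with parameters and ground truth and a ready-to-run
        pipeline config.  Returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "network": "network.tsv", "cancer_genes": "cancer_genes.txt",
            "gene_sets": "gene_sets.gmt", "drug_targets": "drug_targets.tsv",
            "sl_reference": "sl_reference.tsv", "sensitivity": "sensitivity.tsv",
            "literature": "literature.tsv", "manifest": "manifest.json",
            "config": "config.yaml",
        }.items()}
        edges = sorted(canonical_pair(u, v) for u, v in self.network.graph.edges())
        with open(paths["network"], "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
        with open(paths["cancer_genes"], "w") as fh:
            fh.write("# synthetic cancer gene list\n")
            for g in sorted(self.network.cancer_genes):
                fh.write(g + "\n")
        with open(paths["gene_sets"], "w") as fh:
            for sid in sorted(self.gene_sets.sets):
                desc, members = self.gene_sets.sets[sid]
                fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")
        write_results(self.drug_targets, paths["drug_targets"])
        write_results(self.sl_reference, paths["sl_reference"])
        write_results(self.sensitivity, paths["sensitivity"])
        write_results(self.literature, paths["literature"])
        manifest = {
            "seed": self.seed,
            "params": self.params,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "literature_globals": self.literature_globals,
            "n_nodes": self.network.N,
            "n_edges": self.network.graph.number_of_edges(),
            "n_cancer": len(self.network.cancer_genes),
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        config = {
            "network": "network.tsv",
            "cancer_genes": "cancer_genes.txt",
            "gene_sets": "gene_sets.gmt",
            "drug_targets": "drug_targets.tsv",
            "sl_reference": "sl_reference.tsv",
            "sensitivity": "sensitivity.tsv",
            "literature": "literature.tsv",
            "literature_n": self.literature_globals["N"],
            "literature_m_cancer": self.literature_globals["M_cancer"],
            "literature_m_sl": self.literature_globals["M_sl"],
            "n_random": self.params.get("n_random", 100),
            "seed": self.seed,
        }
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------


def synth_network(n_nodes: int = 200, model: str = "barabasi_albert",
                  n_cancer: int = 20, seed: int = 1,
                  mean_degree: float = 6.0) -> SignalingNetwork:
    """A seeded, connected, simple synthetic signaling network with
    ``n_cancer`` nodes labeled as cancer genes uniformly at random.

    ``barabasi_albert`` (default) gives the heavy-tailed degree profile of
    real signaling networks; ``erdos_renyi`` is kept for null-calibration
    fixtures and is retried (with incremented internal seed, up to 50
    attempts) until connected.
    """
    if not (0 < n_cancer < n_nodes):
        raise SlnetError("need 0 < n_cancer < n_nodes")
    sub = _subseed(seed, "network")
    if model == "barabasi_albert":
        m = max(1, round(mean_degree / 2))
        G = nx.barabasi_albert_graph(n_nodes, m, seed=sub)
    elif model == "erdos_renyi":
        p = mean_degree / (n_nodes - 1)
        for attempt in range(50):
            G = nx.gnp_random_graph(n_nodes, p, seed=sub + attempt)
            if nx.is_connected(G):
                break
        else:
            raise SlnetError("could not draw a connected Erdos-Renyi graph "
                             "within 50 attempts; raise mean_degree")
    else:
        raise SlnetError(f"unknown network model {model!r}")
    width = len(str(n_nodes))
    mapping = {i: f"G{i:0{width}d}" for i in G.nodes()}
    G = nx.relabel_nodes(G, mapping)
    rng = np.random.default_rng(_subseed(seed, "cancer_labels"))
    cancer = frozenset(str(g) for g in
                       rng.choice(sorted(G.nodes()), size=n_cancer, replace=False))
    return SignalingNetwork(graph=G, cancer_genes=cancer)


def plant_bridge_pairs(net: SignalingNetwork, n_planted: int, seed: int,
                       group_size: int = 6):
    """Rewire the network so ``n_planted`` (cancer, non-cancer) pairs act as
    the two primary bridges to small satellite groups.

    Each planted non-cancer gene is taken from the highest-degree non-cancer
    hubs (so it also ranks high in shortest-path frequency); its satellite
    group loses all outside edges except links to the planted pair and one
    backup edge that keeps the graph connected.  Returns
    ``(modified network, planted pairs)``.
    """
    if n_planted < 1:
        raise SlnetError("n_planted must be >= 1")
    G = net.graph.copy()
    cancer = set(net.cancer_genes)
    rng = np.random.default_rng(_subseed(seed, "planting"))
    degree = dict(G.degree())
    non_cancer = sorted(net.non_cancer_genes, key=lambda g: (-degree[g], g))
    cancer_ranked = sorted(cancer, key=lambda g: (-degree[g], g))
    needed = n_planted * (group_size + 2) + n_planted  # groups + pairs + backups
    if needed > net.N:
        raise SlnetError(
            f"graph too small: {net.N} nodes cannot host {n_planted} planted "
            f"groups of size {group_size}")
    if n_planted > len(cancer_ranked):
        raise SlnetError("not enough cancer genes to plant")
    planted = []
    reserved: set = set()
    hubs = [g for g in non_cancer[:n_planted]]
    reserved.update(hubs)
    reserved.update(cancer_ranked[:n_planted])
    low_degree_pool = [g for g in sorted(net.non_cancer_genes,
                                         key=lambda g: (degree[g], g))
                       if g not in reserved]
    for i in range(n_planted):
        m = cancer_ranked[i]
        n = hubs[i]
        group = low_degree_pool[i * group_size:(i + 1) * group_size]
        if len(group) < group_size:
            raise SlnetError("graph too small to carve satellite groups")
        reserved.update(group)
        gset = set(group)
        for g in group:  # cut the group loose from the rest of the network
            for nb in list(G.neighbors(g)):
                if nb not in gset:
                    G.remove_edge(g, nb)
        for a, b in zip(group, group[1:]):  # internal path keeps group connected
            G.add_edge(a, b)
        for g in group:  # m and n become the group's two bridges
            G.add_edge(m, g)
            G.add_edge(n, g)
        planted.append((m, n))
    # one long backup route per group so removing {m, n} disconnects nothing
    backup_pool = [g for g in sorted(G.nodes(), key=lambda g: (-degree[g], g))
                   if g not in reserved and g not in cancer]
    for i, (m, n) in enumerate(planted):
        group = low_degree_pool[i * group_size:(i + 1) * group_size]
        b = backup_pool[i % len(backup_pool)]
        G.add_edge(group[-1], b)
    # repair any residual disconnection (nodes that only touched a group)
    if not nx.is_connected(G):
        comps = sorted(nx.connected_components(G), key=len, reverse=True)
        anchor = sorted(comps[0])[0]
        for comp in comps[1:]:
            G.add_edge(sorted(comp)[0], anchor)
        log.info("reconnected %d stray components after planting", len(comps) - 1)
    out = SignalingNetwork(graph=G, cancer_genes=net.cancer_genes,
                           directed=net.directed)
    return out, planted


def synth_annotations(net: SignalingNetwork, planted, seed: int,
                      fraction_with_drug: float = 0.8,
                      fraction_in_reference: float = 0.6,
                      n_decoy_sets: int = 8) -> dict:
    """Companion tables for a planted network: gene sets co-assigning every
    planted pair, drug targets covering ``fraction_with_drug`` of the
    planted non-cancer genes, an SL reference holding
    ``fraction_in_reference`` of the planted pairs plus decoys, sensitivity
    records (negative log-IC50 for planted combinations, non-negative for
    decoys) and literature counts with elevated relevant fractions for
    planted genes."""
    if not planted:
        raise SlnetError("no planted pairs given")
    rng = np.random.default_rng(_subseed(seed, "annotations"))
    nodes = sorted(net.nodes)
    planted_cancer = [m for m, _ in planted]
    planted_nc = [n for _, n in planted]
    planted_genes = sorted(set(planted_cancer) | set(planted_nc))

    sets = {"SL_CORE": ("planted synthetic-lethal core module",
                        frozenset(planted_genes))}
    for i in range(n_decoy_sets):
        members = rng.choice(nodes, size=15, replace=False)
        sets[f"DECOY_{i:02d}"] = (f"decoy pathway {i}",
                                  frozenset(str(g) for g in members))
    gene_sets = GeneSetCollection(sets=sets)

    k_drug = max(1, round(fraction_with_drug * len(planted_nc)))
    drug_genes = sorted(planted_nc)[:k_drug]
    drug_targets = [
        DrugTargetRecord(g, f"P{rng.integers(10_000, 99_999):05d}",
                         f"DRUG_{g}", "Anticancer drug target")
        for g in drug_genes
    ]
    decoy_drug_genes = [g for g in nodes if g not in set(planted_genes)]
    for g in rng.choice(decoy_drug_genes, size=10, replace=False):
        g = str(g)
        drug_targets.append(DrugTargetRecord(
            g, f"P{rng.integers(10_000, 99_999):05d}", f"DRUG_{g}", "other"))

    k_ref = round(fraction_in_reference * len(planted))
    sl_reference = {canonical_pair(m, n) for m, n in sorted(planted)[:k_ref]}
    cancer_pool = sorted(net.cancer_genes)
    nc_pool = [g for g in nodes if g not in net.cancer_genes
               and g not in set(planted_nc)]
    while len(sl_reference) < k_ref + 20:  # decoy reference pairs
        m = cancer_pool[rng.integers(len(cancer_pool))]
        g = nc_pool[rng.integers(len(nc_pool))]
        sl_reference.add(canonical_pair(m, g))

    sensitivity = []
    for i, (m, n) in enumerate(planted):
        if n not in set(drug_genes):
            continue
        sensitivity.append(SensitivityRecord(
            f"CL_{i:03d}", m, f"DRUG_{n}", n,
            round(-abs(rng.normal(2.0, 0.5)), 3)))
    for i in range(10):
        m = cancer_pool[rng.integers(len(cancer_pool))]
        g = nc_pool[rng.integers(len(nc_pool))]
        sensitivity.append(SensitivityRecord(
            f"CL_D{i:02d}", m, f"DRUG_{g}", g,
            round(abs(rng.normal(1.0, 0.5)), 3)))

    N = LITERATURE_GLOBALS["N"]
    rate_cancer = LITERATURE_GLOBALS["M_cancer"] / N
    rate_sl = LITERATURE_GLOBALS["M_sl"] / N
    literature = []
    for g in planted_nc:
        K = int(rng.integers(150, 300))
        literature.append(LiteratureCounts(g, K, max(1, int(0.4 * K)), "cancer"))
        literature.append(LiteratureCounts(g, K, max(1, int(0.3 * K)), "SL"))
    for g in rng.choice(nc_pool, size=10, replace=False):
        g = str(g)
        K = int(rng.integers(50, 200))
        literature.append(LiteratureCounts(
            g, K, int(rng.binomial(K, rate_cancer)), "cancer"))
        literature.append(LiteratureCounts(
            g, K, int(rng.binomial(K, rate_sl)), "SL"))

    return {
        "gene_sets": gene_sets,
        "drug_targets": drug_targets,
        "sl_reference": sorted(sl_reference),
        "sensitivity": sensitivity,
        "literature": literature,
    }


def make_bundle(seed: int = 1, n_nodes: int = 200, n_cancer: int = 20,
                n_planted: int = 5, model: str = "barabasi_albert",
                mean_degree: float = 6.0, group_size: int = 6,
                fraction_with_drug: float = 0.8,
                fraction_in_reference: float = 0.6,
                n_random: int = 100) -> FixtureBundle:
    """The default end-to-end fixture: a 200-node scale-free network with
    20 cancer genes and 5 planted bridge pairs, plus companion tables."""
    net = synth_network(n_nodes=n_nodes, model=model, n_cancer=n_cancer,
                        seed=seed, mean_degree=mean_degree)
    net, planted = plant_bridge_pairs(net, n_planted=n_planted, seed=seed,
                                      group_size=group_size)
    ann = synth_annotations(net, planted, seed=seed,
                            fraction_with_drug=fraction_with_drug,
                            fraction_in_reference=fraction_in_reference)
    params = {
        "n_nodes": n_nodes, "n_cancer": n_cancer, "n_planted": n_planted,
        "model": model, "mean_degree": mean_degree, "group_size": group_size,
        "fraction_with_drug": fraction_with_drug,
        "fraction_in_reference": fraction_in_reference,
        "n_random": n_random,
    }
    return FixtureBundle(network=net, planted_pairs=planted, seed=seed,
                         literature_globals=dict(LITERATURE_GLOBALS),
                         params=params, **ann)
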