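"""Stage orchestration: build -> screen -> annotate -> validate.

Every stage writes plain TSV/JSON artifacts under the output directory and
updates ``manifest.json`` (config, seed, row counts per stage), so any
stage can be inspected or re-run in isolation.  All randomness flows from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .graphcore import (SignalingNetwork, avg_shortest_path_length,
                        candidate_pairs, clean_network, path_frequencies,
                        select_top_fraction)
from .netio import (SCHEMA_COLUMNS, SlnetError, load_config, read_gene_list,
                    read_gmt, read_network, read_table, write_results)

_STABILITY_COLUMNS = SCHEMA_COLUMNS["stability"] + ["degenerate"]
from .screening import (NetworkStabilityScreen, auto_distance_threshold,
                        cumulative_frequency_cutoff, distance_screen, enrich,
                        frequency_screen, function_screen)
from .targets_validation import (annotate_targets, compile_report,
                                 literature_pvalue, reference_overlap,
                                 sensitivity_validate)

log = logging.getLogger("slnet")

__all__ = ["PipelineConfig", "build_stage", "screen_stage", "annotate_stage",
           "validate_stage", "run_all"]


@dataclass
class PipelineConfig:
    """All pipeline inputs and tunables.  Path fields are resolved relative
    to ``base_dir`` (the config file's directory when loaded from YAML)."""

    network: str | None = None
    cancer_genes: str | None = None
    gene_sets: str | None = None
    drug_targets: str | None = None
    sl_reference: str | None = None
    sensitivity: str | None = None
    literature: str | None = None
    directed: bool = False
    prune_leaves: bool = False
    top_fraction: float = 0.30
    mass_fraction: float = 0.50
    n_random: int = 1000
    alpha_network: float = 0.05
    distance_mode: str | int = "auto"
    alpha_enrich: float = 0.05
    ic50_cut: float = 0.0
    swaps_per_edge: int = 10
    null_own_baseline: bool = True
    pseudocount: bool = False
    literature_n: int = 10_000_000
    literature_m_cancer: int = 500_000
    literature_m_sl: int = 50_000
    seed: int = 0
    jobs: int = 1
    base_dir: str = "."

    def validate(self):
        for name in ("top_fraction", "mass_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise SlnetError(f"config field {name} must be in (0, 1], got {v}")
        for name in ("alpha_network", "alpha_enrich"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise SlnetError(f"config field {name} must be in (0, 1), got {v}")
        if self.n_random < 1:
            raise SlnetError("config field n_random must be >= 1")
        if self.distance_mode != "auto":
            try:
                self.distance_mode = int(self.distance_mode)
            except (TypeError, ValueError):
                raise SlnetError(
                    f"config field distance_mode must be 'auto' or an integer, "
                    f"got {self.distance_mode!r}") from None
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = load_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SlnetError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        data.setdefault("base_dir", str(Path(path).parent))
        return cls(**data).validate()

    def path(self, name: str) -> Path:
        value = getattr(self, name)
        if value is None:
            raise SlnetError(f"required input {name!r} not configured")
        p = Path(value)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _update_manifest(outdir: Path, stage: str, payload: dict, config: PipelineConfig):
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config": config.as_dict(), "seed": config.seed,
        "slnet_version": __version__, "stages": {},
    }
    manifest["stages"][stage] = payload
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _require(outdir: Path, relpath: str, producer: str) -> Path:
    p = outdir / relpath
    if not p.exists():
        raise SlnetError(f"missing {p}; run the '{producer}' stage first")
    return p


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def build_stage(config: PipelineConfig, outdir, plot: bool = False) -> dict:
    """Clean the network, map cancer genes, count shortest-path
    frequencies, select the top-fraction non-cancer genes and form the
    candidate pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = read_network(config.path("network"), directed=config.directed)
    cancer = read_gene_list(config.path("cancer_genes"))
    net = clean_network(net, prune_leaves=config.prune_leaves)
    net = net.with_cancer_genes(cancer)
    if not net.cancer_genes:
        raise SlnetError("no cancer genes mapped onto the cleaned network")
    freq = path_frequencies(net)
    top = select_top_fraction(freq, config.top_fraction)
    pairs = candidate_pairs(top, sorted(net.cancer_genes))

    edges = sorted(tuple(sorted(e)) for e in net.graph.edges())
    with open(outdir / "hcsn.tsv", "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    with open(outdir / "hcsn_cancer_genes.txt", "w") as fh:
        for g in sorted(net.cancer_genes):
            fh.write(g + "\n")
    write_results(freq, outdir / "frequencies.tsv")
    with open(outdir / "top_genes.txt", "w") as fh:
        for g in top:
            fh.write(g + "\n")
    write_results(pairs, outdir / "pairs.tsv")
    if plot:
        plot_cumulative_frequency(freq, outdir / "frequency_curve.png",
                                  mass_fraction=config.mass_fraction)
    payload = {
        "nodes": net.N,
        "edges": net.graph.number_of_edges(),
        "cancer_genes": len(net.cancer_genes),
        "top_non_cancer_genes": len(top),
        "candidate_pairs": len(pairs),
        "D0": avg_shortest_path_length(net),
    }
    _update_manifest(outdir, "build", payload, config)
    return payload


def _load_built_network(config: PipelineConfig, outdir: Path) -> SignalingNetwork:
    net = read_network(_require(outdir, "hcsn.tsv", "build"),
                       directed=config.directed)
    cancer = read_gene_list(_require(outdir, "hcsn_cancer_genes.txt", "build"))
    return net.with_cancer_genes(cancer)


def screen_stage(config: PipelineConfig, outdir) -> dict:
    """The 3-step screen over the built candidate pairs."""
    outdir = Path(outdir)
    net = _load_built_network(config, outdir)
    import pandas as pd

    pairs_df = pd.read_csv(_require(outdir, "pairs.tsv", "build"), sep="\t")
    pairs = list(pairs_df.itertuples(index=False, name=None))
    freq_df = pd.read_csv(_require(outdir, "frequencies.tsv", "build"), sep="\t")
    freq = dict(zip(freq_df.gene, freq_df["count"]))
    top_genes = [l.strip() for l in
                 open(_require(outdir, "top_genes.txt", "build")) if l.strip()]

    model = NetworkStabilityScreen(
        net, pairs=pairs, n_random=config.n_random,
        swaps_per_edge=config.swaps_per_edge,
        null_own_baseline=config.null_own_baseline,
        pseudocount=config.pseudocount)
    results = model.fit(seed=config.seed, progress=True)
    write_results(results.valid_records, outdir / "stability_all.tsv")
    step1 = results.significant(config.alpha_network)
    all_distances = [r.distance for r in results.valid_records]
    step1 = distance_screen(step1, threshold=config.distance_mode,
                            all_distances=all_distances)
    write_results(step1, outdir / "step1_pairs.tsv", columns=_STABILITY_COLUMNS)

    kept = cumulative_frequency_cutoff({g: freq[g] for g in top_genes},
                                       config.mass_fraction)
    with open(outdir / "kept_genes.txt", "w") as fh:
        for g in kept:
            fh.write(g + "\n")
    step2 = frequency_screen(step1, kept)
    write_results(step2, outdir / "step2_pairs.tsv", columns=_STABILITY_COLUMNS)

    collection = read_gmt(config.path("gene_sets"))
    background = set(net.nodes)
    query = {r.cancer_gene for r in step2} | {r.non_cancer_gene for r in step2}
    enrichment = enrich(query, collection, background) if query else []
    write_results(enrichment, outdir / "enrichment.tsv",
                  columns=["set_id"])
    step3 = function_screen(step2, enrichment, collection,
                            alpha=config.alpha_enrich)
    write_results(step3, outdir / "final_pairs.tsv", columns=_STABILITY_COLUMNS)

    if config.distance_mode == "auto":
        threshold = auto_distance_threshold(all_distances)
    else:
        threshold = int(config.distance_mode)
    payload = {
        "candidate_pairs": len(pairs),
        "significant_pairs": len(results.significant(config.alpha_network)),
        "after_distance": len(step1),
        "after_frequency": len(step2),
        "after_function": len(step3),
        "distance_threshold": threshold,
        "kept_high_frequency_genes": len(kept),
        "significant_gene_sets": sum(e.q < config.alpha_enrich for e in enrichment),
        "degenerate_pairs": sum(r.degenerate for r in results.records),
    }
    _update_manifest(outdir, "screen", payload, config)
    return payload


def annotate_stage(config: PipelineConfig, outdir) -> dict:
    """Annotate the final non-cancer genes with drug-target records."""
    outdir = Path(outdir)
    final = read_table(_require(outdir, "final_pairs.tsv", "screen"), "stability")
    drug_targets = read_table(config.path("drug_targets"), "drug_targets")
    targets, unannotated = annotate_targets(final, drug_targets)
    write_results(targets, outdir / "targets.tsv", columns=["gene"])
    with open(outdir / "unannotated_candidates.txt", "w") as fh:
        for g in unannotated:
            fh.write(g + "\n")
    payload = {"targets": len(targets), "unannotated": len(unannotated)}
    _update_manifest(outdir, "annotate", payload, config)
    return payload


def validate_stage(config: PipelineConfig, outdir) -> dict:
    """Run the three validation channels over the annotated targets."""
    outdir = Path(outdir)
    final = read_table(_require(outdir, "final_pairs.tsv", "screen"), "stability")
    drug_targets = read_table(config.path("drug_targets"), "drug_targets")
    targets, _ = annotate_targets(final, drug_targets)

    reference = read_table(config.path("sl_reference"), "sl_reference")
    ref_stats = reference_overlap(final, set(reference))

    sens = read_table(config.path("sensitivity"), "sensitivity")
    sens_supported = sensitivity_validate(targets, sens,
                                          ic50_cut=config.ic50_cut)

    lit_records = read_table(config.path("literature"), "literature_counts")
    lit_results: dict = {}
    m_by_context = {"cancer": config.literature_m_cancer,
                    "SL": config.literature_m_sl}
    for rec in lit_records:
        p = literature_pvalue(rec.x, rec.K, m_by_context[rec.context],
                              config.literature_n)
        lit_results.setdefault(rec.gene, {})[rec.context] = p

    report = compile_report(targets, ref_stats, sens_supported, lit_results)
    report.to_json(outdir / "validation.json")
    report.summary_frame().to_csv(outdir / "validation_summary.tsv",
                                  sep="\t", index=False, lineterminator="\n")
    with open(outdir / "reference_overlap.json", "w") as fh:
        json.dump(dataclasses.asdict(ref_stats), fh, indent=1,
                  sort_keys=True, default=list)
        fh.write("\n")
    payload = {
        "targets": report.n_targets,
        "reference_supported": report.n_reference_supported,
        "sensitivity_supported": report.n_sensitivity_supported,
        "literature_supported": report.n_literature_supported,
        "triple_validated": len(report.triple_validated),
        "pct_pairs_in_reference": ref_stats.pct_pairs_in_reference,
    }
    _update_manifest(outdir, "validate", payload, config)
    return payload


def run_all(config: PipelineConfig, outdir, plot: bool = False) -> dict:
    """build -> screen -> annotate -> validate, returning merged counts."""
    out = {}
    out["build"] = build_stage(config, outdir, plot=plot)
    out["screen"] = screen_stage(config, outdir)
    out["annotate"] = annotate_stage(config, outdir)
    out["validate"] = validate_stage(config, outdir)
    return out


def plot_cumulative_frequency(freq: dict, path, mass_fraction: float = 0.5):
    """Cumulative traversal-frequency percentage curve (gene rank on x,
    cumulative fraction of total counts on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    counts = sorted(freq.values(), reverse=True)
    total = sum(counts)
    if total <= 0:
        raise SlnetError("total frequency mass is zero")
    cum = np.cumsum(counts) / total
    k = int(np.searchsorted(cum, mass_fraction) + 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(range(1, len(cum) + 1), cum, lw=1.5)
    ax.axhline(mass_fraction, ls="--", c="grey", lw=0.8)
    ax.axvline(k, ls="--", c="grey", lw=0.8)
    ax.annotate(f"({k}, {mass_fraction:g})", (k, mass_fraction),
                textcoords="offset points", xytext=(6, -12))
    ax.set_xlabel("number of non-cancer genes (frequency-ranked)")
    ax.set_ylabel("cumulative fraction of traversal counts")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
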