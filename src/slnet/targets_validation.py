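"""Drug-target annotation of the surviving non-cancer genes and the three
validation channels: overlap with a synthetic-lethality reference database,
drug-sensitivity support, and a literature hypergeometric test."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .netio import (DrugTargetRecord, LiteratureCounts, SensitivityRecord,
                    SlnetError, canonical_pair)

log = logging.getLogger("slnet")

__all__ = [
    "AnnotatedTarget",
    "OverlapStats",
    "ValidationReport",
    "percent",
    "annotate_targets",
    "reference_overlap",
    "sensitivity_validate",
    "literature_pvalue",
    "compile_report",
]


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals
    (e.g. 7088/16976 -> 41.75)."""
    if denominator <= 0:
        raise SlnetError("percentage denominator must be positive")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnnotatedTarget:
    """A candidate anticancer drug target: a non-cancer gene from the final
    SL pair list with at least one known drug."""

    gene: str
    target_accession: str
    drugs: tuple
    category: str
    sl_partners: tuple  # its cancer-gene partners among the final pairs


@dataclass(frozen=True)
class OverlapStats:
    """Overlap between predicted SL pairs and a reference pair set."""

    n_predicted_pairs: int
    n_reference_pairs: int
    pairs_in_reference: tuple
    pct_pairs_in_reference: float          # of predicted pairs
    predicted_genes: int
    predicted_genes_in_reference: int
    pct_genes_in_reference: float
    supported_targets: tuple               # non-cancer genes with a confirmed pair


@dataclass
class ValidationReport:
    per_target: dict       # gene -> channel flags / p-values
    n_targets: int
    n_reference_supported: int
    n_sensitivity_supported: int
    n_literature_supported: int
    triple_validated: list

    def to_json(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True, default=list)
            fh.write("\n")

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, **flags} for g, flags in sorted(self.per_target.items())]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def annotate_targets(final_pairs, drug_targets) -> tuple[list, list]:
    """Annotate the distinct non-cancer genes of the final SL pairs with
    drug-target information.

    Returns ``(targets, unannotated)``: one :class:`AnnotatedTarget` per
    gene with at least one drug record, plus the sorted list of candidate
    genes absent from the drug table.
    """
    if not final_pairs:
        raise SlnetError("no final SL pairs to annotate")
    partners: dict = {}
    for rec in final_pairs:
        partners.setdefault(rec.non_cancer_gene, set()).add(rec.cancer_gene)
    by_gene: dict = {}
    for dt in drug_targets:
        by_gene.setdefault(dt.gene, []).append(dt)
    targets, unannotated = [], []
    for gene in sorted(partners):
        recs = by_gene.get(gene)
        if not recs:
            unannotated.append(gene)
            continue
        drugs = tuple(sorted({r.drug for r in recs}))
        accession = sorted({r.target_accession for r in recs})[0]
        category = ";".join(sorted({r.category for r in recs}))
        targets.append(AnnotatedTarget(gene, accession, drugs, category,
                                       tuple(sorted(partners[gene]))))
    log.info("annotated %d targets; %d candidates without drug records",
             len(targets), len(unannotated))
    return targets, unannotated


def reference_overlap(pairs, reference, reference_genes=None) -> OverlapStats:
    """Compare predicted (cancer, non-cancer) pairs with a reference set of
    canonical unordered pairs.

    ``reference_genes`` defaults to the genes spanned by the reference
    pairs.  All percentages are rounded half-up to 2 decimals.
    """
    reference = set(reference)
    if not reference:
        raise SlnetError("empty reference pair set")
    if reference_genes is None:
        reference_genes = {g for pair in reference for g in pair}
    reference_genes = set(reference_genes)
    pred = [(m, n, canonical_pair(m, n)) for m, n in
            {(r.cancer_gene, r.non_cancer_gene) if hasattr(r, "cancer_gene") else tuple(r)
             for r in pairs}]
    if not pred:
        raise SlnetError("no predicted pairs")
    hits = sorted({c for _, _, c in pred if c in reference})
    supported = sorted({n for _, n, c in pred if c in reference})
    genes = {g for m, n, _ in pred for g in (m, n)}
    genes_hit = genes & reference_genes
    return OverlapStats(
        n_predicted_pairs=len(pred),
        n_reference_pairs=len(reference),
        pairs_in_reference=tuple(hits),
        pct_pairs_in_reference=percent(len(hits), len(pred)),
        predicted_genes=len(genes),
        predicted_genes_in_reference=len(genes_hit),
        pct_genes_in_reference=percent(len(genes_hit), len(genes)),
        supported_targets=tuple(supported),
    )


def sensitivity_validate(targets, sensitivity, ic50_cut: float = 0.0,
                         require_partner: bool = True) -> list:
    """Targets supported by drug-sensitivity data.

    A target is supported iff some sensitivity record hits its gene with
    log-IC50 below ``ic50_cut`` in a cell line whose mutated cancer gene is
    one of the target's SL partners (set ``require_partner=False`` for the
    looser target-only criterion).
    """
    supported = []
    for t in targets:
        for rec in sensitivity:
            if rec.target_gene != t.gene or rec.log_ic50 >= ic50_cut:
                continue
            if require_partner and rec.mutated_cancer_gene not in t.sl_partners:
                continue
            supported.append(t.gene)
            break
    return sorted(supported)


def literature_pvalue(x: int, K: int, M: int, N: int) -> float:
    """P[at least x of the K gene-mentioning studies are context-relevant]
    under a hypergeometric null: population N studies of which M are
    relevant, K drawn.

    P = 1 - sum_{i=0}^{x-1} C(M, i) C(N-M, K-i) / C(N, K), evaluated by
    scipy's log-space survival function so large PubMed-scale counts are
    safe.
    """
    if not (0 <= x <= K <= N and 0 <= M <= N):
        raise SlnetError(
            f"invalid literature counts: x={x}, K={K}, M={M}, N={N}")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, M, K))


def compile_report(targets, ref_result: OverlapStats, sens_result,
                   lit_results, alpha: float = 0.05) -> ValidationReport:
    """Combine the three validation channels into one per-target report.

    ``lit_results`` maps gene -> {"cancer": p, "SL": p} (missing genes get
    no literature support).  A target passes the literature channel iff
    both contexts are significant; the triple-validated list is the
    intersection of the three channels and is invariant to channel order.
    """
    ref_supported = set(ref_result.supported_targets) if ref_result else set()
    sens_supported = set(sens_result or [])
    per_target: dict = {}
    triple = []
    for t in sorted(targets, key=lambda t: t.gene):
        lit = (lit_results or {}).get(t.gene, {})
        p_cancer = lit.get("cancer")
        p_sl = lit.get("SL")
        lit_ok = (p_cancer is not None and p_cancer < alpha
                  and p_sl is not None and p_sl < alpha)
        flags = {
            "in_sl_reference": t.gene in ref_supported,
            "sensitivity_supported": t.gene in sens_supported,
            "literature_cancer_p": p_cancer,
            "literature_sl_p": p_sl,
            "literature_supported": lit_ok,
        }
        per_target[t.gene] = flags
        if flags["in_sl_reference"] and flags["sensitivity_supported"] and lit_ok:
            triple.append(t.gene)
    return ValidationReport(
        per_target=per_target,
        n_targets=len(per_target),
        n_reference_supported=sum(f["in_sl_reference"] for f in per_target.values()),
        n_sensitivity_supported=sum(f["sensitivity_supported"] for f in per_target.values()),
        n_literature_supported=sum(f["literature_supported"] for f in per_target.values()),
        triple_validated=triple,
    )
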