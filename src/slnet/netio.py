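"""Readers and writers for every table and format the pipeline touches.

All gene identifiers pass through :func:`normalize_symbol` (uppercase,
whitespace-stripped) on the way in; no alias/synonym mapping is attempted —
resolving gene aliases is a data-preparation concern upstream of this
package.  Every reader logs how many rows it dropped or collapsed so that
data loss is always visible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

log = logging.getLogger("slnet")

__all__ = [
    "SlnetError",
    "ParseError",
    "SchemaError",
    "GeneSetCollection",
    "DrugTargetRecord",
    "SensitivityRecord",
    "LiteratureCounts",
    "normalize_symbol",
    "canonical_pair",
    "read_network",
    "read_gene_list",
    "read_gmt",
    "read_table",
    "write_results",
    "load_config",
]


class SlnetError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SlnetError):
    """A malformed line in an input file; carries the path and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class SchemaError(SlnetError):
    """An input table does not match its declared schema."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace and uppercase.

    Idempotent by construction; raises :class:`SlnetError` on empty input.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise SlnetError("empty gene symbol")
    return s


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) form of an unordered gene pair."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """A GMT-style collection of named gene sets.

    ``sets`` maps a unique set ID to ``(description, frozenset of member
    symbols)``; ``background`` optionally names the gene universe the sets
    were defined on.
    """

    sets: Mapping[str, tuple[str, frozenset]]
    background: frozenset | None = None

    def members(self, set_id: str) -> frozenset:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class DrugTargetRecord:
    gene: str
    target_accession: str
    drug: str
    category: str


@dataclass(frozen=True)
class SensitivityRecord:
    cell_line: str
    mutated_cancer_gene: str
    drug: str
    target_gene: str
    log_ic50: float


@dataclass(frozen=True)
class LiteratureCounts:
    """Per-gene text-mining counts: K studies mention the gene, x of those
    are also cancer-related (or SL-related, per ``context``)."""

    gene: str
    K: int
    x: int
    context: str  # "cancer" or "SL"

    def __post_init__(self):
        if not (0 <= self.x <= self.K):
            raise SchemaError(
                f"literature counts for {self.gene}: need 0 <= x <= K, "
                f"got x={self.x}, K={self.K}"
            )
        if self.context not in ("cancer", "SL"):
            raise SchemaError(f"unknown literature context {self.context!r}")


# ---------------------------------------------------------------------------
# Network input
# ---------------------------------------------------------------------------

_NETWORK_FORMATS = ("tsv", "sif", "graphml")


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("sif",):
        return "sif"
    if ext in ("graphml", "xml"):
        return "graphml"
    return "tsv"


def read_network(path, format: str | None = None, directed: bool = False):
    """Read a signaling network from an edge-list TSV, SIF or GraphML file.

    Returns a :class:`slnet.graphcore.SignalingNetwork` with normalized
    symbols, duplicate rows collapsed to single edges, and (for TSV) any
    third interaction-type column ignored.  SIF rows fan out: ``A pp B C``
    yields edges A–B and A–C.
    """
    from .graphcore import SignalingNetwork

    path = Path(path)
    if not path.exists():
        raise SlnetError(f"network file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _NETWORK_FORMATS:
        raise SlnetError(f"unknown network format {fmt!r}")

    G = nx.DiGraph() if directed else nx.Graph()
    n_rows = 0
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        for u, v in raw.edges():
            G.add_edge(normalize_symbol(u), normalize_symbol(v))
            n_rows += 1
        for u in raw.nodes():
            G.add_node(normalize_symbol(u))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t") if fmt == "tsv" else line.split()
                fields = [f.strip() for f in fields]
                if fmt == "tsv":
                    if len(fields) < 2 or not fields[0] or not fields[1]:
                        raise ParseError(path, lineno, "expected at least 2 columns")
                    G.add_edge(normalize_symbol(fields[0]), normalize_symbol(fields[1]))
                    n_rows += 1
                else:  # sif: node [relation target1 target2 ...]
                    fields = [f for f in fields if f]
                    if len(fields) == 1:
                        G.add_node(normalize_symbol(fields[0]))
                        n_rows += 1
                    elif len(fields) >= 3:
                        src = normalize_symbol(fields[0])
                        for tgt in fields[2:]:
                            G.add_edge(src, normalize_symbol(tgt))
                        n_rows += 1
                    else:
                        raise ParseError(
                            path, lineno, "SIF row needs 1 or >=3 fields"
                        )
    if G.number_of_nodes() == 0:
        raise SlnetError(f"empty network file: {path}")
    log.info(
        "read %s: %d rows -> %d nodes, %d edges (%d duplicate rows collapsed)",
        path, n_rows, G.number_of_nodes(), G.number_of_edges(),
        max(0, n_rows - G.number_of_edges()),
    )
    return SignalingNetwork(graph=G, cancer_genes=frozenset(), directed=directed)


def read_gene_list(path) -> set:
    """Read one gene symbol per line; blank lines and ``#`` comments skipped.

    Returns a set of normalized symbols (so duplicates after normalization
    collapse).  An empty result is a warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise SlnetError(f"gene list not found: {path}")
    genes: set = set()
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(normalize_symbol(line))
            n_rows += 1
    if not genes:
        log.warning("gene list %s is empty", path)
    else:
        log.info("read %s: %d rows -> %d unique genes", path, n_rows, len(genes))
    return genes


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set ID, description, member genes, tab-separated)."""
    path = Path(path)
    if not path.exists():
        raise SlnetError(f"GMT file not found: {path}")
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line needs >=3 tab-separated fields")
            set_id = fields[0].strip()
            if set_id in sets:
                raise ParseError(path, lineno, f"duplicate gene-set ID {set_id!r}")
            members = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not members:
                raise ParseError(path, lineno, f"gene set {set_id!r} has no members")
            sets[set_id] = (fields[1].strip(), members)
    log.info("read %s: %d gene sets", path, len(sets))
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Typed tables
# ---------------------------------------------------------------------------

#: required columns per typed-table schema (also the header used for
#: empty outputs of that schema)
SCHEMA_COLUMNS = _SCHEMA_COLUMNS = {
    "drug_targets": ["gene", "target_accession", "drug", "category"],
    "sl_reference": ["gene_a", "gene_b"],
    "sensitivity": ["cell_line", "mutated_cancer_gene", "drug", "target_gene", "log_ic50"],
    "literature_counts": ["gene", "K", "x", "context"],
    "stability": [
        "cancer_gene", "non_cancer_gene", "D0", "Dm", "Dn", "Dmn",
        "S", "distance", "p", "n_random",
    ],
}


def _load_frame(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SlnetError(f"table not found: {path}")
    if schema not in _SCHEMA_COLUMNS:
        raise SlnetError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMA_COLUMNS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def _to_float(value: str, path, lineno: int, column: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {column}: {value!r}") from None
    if out != out or out in (float("inf"), float("-inf")):
        raise ParseError(path, lineno, f"non-finite {column}: {value!r}")
    return out


def _to_int(value: str, path, lineno: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {column}: {value!r}") from None


def read_table(path, schema: str, unordered_pairs: bool = True) -> list:
    """Read a typed TSV table.  ``schema`` selects the record type:

    - ``drug_targets`` -> list of :class:`DrugTargetRecord` (gene/drug deduplicated)
    - ``sl_reference`` -> sorted list of canonical (gene_a, gene_b) tuples
    - ``sensitivity``  -> list of :class:`SensitivityRecord`
    - ``literature_counts`` -> list of :class:`LiteratureCounts`
    - ``stability``    -> list of :class:`slnet.screening.StabilityRecord`
    """
    path = Path(path)
    df = _load_frame(path, schema)
    records: list = []
    if schema == "drug_targets":
        seen = set()
        for i, row in enumerate(df.itertuples(index=False), 2):
            gene = normalize_symbol(row.gene)
            key = (gene, row.drug.strip())
            if key in seen:
                continue
            seen.add(key)
            records.append(DrugTargetRecord(gene, row.target_accession.strip(),
                                            row.drug.strip(), row.category.strip()))
        dropped = len(df) - len(records)
        if dropped:
            log.info("%s: collapsed %d duplicate (gene, drug) rows", path, dropped)
    elif schema == "sl_reference":
        pairs = set()
        for row in df.itertuples(index=False):
            if unordered_pairs:
                pairs.add(canonical_pair(row.gene_a, row.gene_b))
            else:
                pairs.add((normalize_symbol(row.gene_a), normalize_symbol(row.gene_b)))
        records = sorted(pairs)
        if len(records) < len(df):
            log.info("%s: collapsed %d duplicate/mirrored pairs", path, len(df) - len(records))
    elif schema == "sensitivity":
        for i, row in enumerate(df.itertuples(index=False), 2):
            records.append(SensitivityRecord(
                row.cell_line.strip(),
                normalize_symbol(row.mutated_cancer_gene),
                row.drug.strip(),
                normalize_symbol(row.target_gene),
                _to_float(row.log_ic50, path, i, "log_ic50"),
            ))
    elif schema == "literature_counts":
        for i, row in enumerate(df.itertuples(index=False), 2):
            rec = LiteratureCounts(
                normalize_symbol(row.gene),
                _to_int(row.K, path, i, "K"),
                _to_int(row.x, path, i, "x"),
                row.context.strip(),
            )
            records.append(rec)
    elif schema == "stability":
        from .screening import StabilityRecord

        for i, row in enumerate(df.itertuples(index=False), 2):
            records.append(StabilityRecord(
                cancer_gene=normalize_symbol(row.cancer_gene),
                non_cancer_gene=normalize_symbol(row.non_cancer_gene),
                D0=_to_float(row.D0, path, i, "D0"),
                Dm=_to_float(row.Dm, path, i, "Dm"),
                Dn=_to_float(row.Dn, path, i, "Dn"),
                Dmn=_to_float(row.Dmn, path, i, "Dmn"),
                S=_to_float(row.S, path, i, "S"),
                distance=_to_int(row.distance, path, i, "distance"),
                p=_to_float(row.p, path, i, "p"),
                n_random=_to_int(row.n_random, path, i, "n_random"),
            ))
    log.info("read %s (%s): %d records", path, schema, len(records))
    return records


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

# primary sort key per record type, so output files are deterministic
_SORT_KEYS = {
    "StabilityRecord": ("cancer_gene", "non_cancer_gene"),
    "EnrichmentRecord": ("set_id",),
    "DrugTargetRecord": ("gene", "drug"),
    "SensitivityRecord": ("cell_line", "drug", "target_gene"),
    "LiteratureCounts": ("gene", "context"),
    "AnnotatedTarget": ("gene",),
}


def _records_frame(records: Sequence) -> pd.DataFrame:
    first = records[0]
    if dataclasses.is_dataclass(first):
        cols = [f.name for f in dataclasses.fields(first)]
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
        key = _SORT_KEYS.get(type(first).__name__)
        if key:
            df = df.sort_values(list(key), kind="mergesort").reset_index(drop=True)
        for c in cols:  # lists (e.g. drugs, sl_partners) serialize as ';'-joined
            if df[c].map(lambda v: isinstance(v, (list, tuple))).any():
                df[c] = df[c].map(lambda v: ";".join(map(str, v)))
        return df
    if isinstance(first, tuple):  # e.g. canonical gene pairs
        ncol = len(first)
        cols = ["gene_a", "gene_b"] if ncol == 2 else [f"col{i}" for i in range(ncol)]
        return pd.DataFrame(sorted(records), columns=cols)
    raise SlnetError(f"cannot serialize records of type {type(first).__name__}")


def write_results(records, path, format: str = "tsv", columns: Sequence[str] | None = None):
    """Write pipeline records to TSV or JSON with deterministic row and
    column order; writing the same records twice yields byte-identical files.

    ``records`` may be a list of dataclass records, a list of tuples
    (gene pairs), or a mapping (e.g. a frequency table, written as
    two-column TSV sorted by count descending then symbol).
    An empty list writes a header-only file (``columns`` supplies the
    header in that case).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, Mapping):
        rows = sorted(records.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(rows, columns=["gene", "count"])
    elif len(records) == 0:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    else:
        df = _records_frame(list(records))
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "json":
        payload = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise SlnetError(f"unknown output format {format!r}")
    log.info("wrote %d records to %s", len(df), path)


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    path = Path(path)
    if not path.exists():
        raise SlnetError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SlnetError(f"config {path} must be a YAML mapping")
    return data
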