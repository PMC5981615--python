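"""The 3-step synthetic-lethality screen.

Step 1 (network-based): for each (cancer gene m, non-cancer gene n) pair,
the stability score

    S = (2 * D_mn - D_m - D_n) / D_0

where D_0 is the average shortest path length of the intact network and
D_m, D_n, D_mn are the same functional after deleting m, n, or both.  S
measures how much *more* the joint knockout stretches the network than the
two single knockouts combined — the network analogue of a synthetic-lethal
interaction.  Significance comes from an ensemble of degree-preserving
randomized networks: the empirical p-value is the fraction of randomized
networks whose score exceeds the observed one.  Pairs farther apart than
the (floored) average pair distance are then discarded.

Step 2 (frequency-based): non-cancer genes are ranked by how often they sit
on cancer/non-cancer shortest paths; the smallest top prefix carrying a
given fraction of the total traversal mass is kept.

Step 3 (function-based): hypergeometric gene-set enrichment over the
surviving genes; a pair survives only if *both* its genes belong to at
least one significantly enriched set (Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graphcore import DegenerateGraphError, DistanceEngine, SignalingNetwork
from .netio import GeneSetCollection, SlnetError

log = logging.getLogger("slnet")

__all__ = [
    "StabilityRecord",
    "EnrichmentRecord",
    "NetworkStabilityScreen",
    "StabilityScreenResults",
    "stability_score",
    "degree_preserving_randomize",
    "empirical_pvalue",
    "network_screen",
    "distance_screen",
    "auto_distance_threshold",
    "cumulative_frequency_cutoff",
    "frequency_screen",
    "enrich",
    "function_screen",
]


@dataclass(frozen=True)
class StabilityRecord:
    """One scored (cancer gene, non-cancer gene) pair."""

    cancer_gene: str
    non_cancer_gene: str
    D0: float
    Dm: float
    Dn: float
    Dmn: float
    S: float
    distance: int
    p: float = math.nan
    n_random: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric enrichment of one gene set against a query."""

    set_id: str
    overlap: int        # k: query genes in the set
    set_size: int       # K: set members inside the background
    query_size: int     # n: query genes (draws)
    background_size: int  # N: population
    p: float
    q: float = math.nan   # BH-adjusted


# ---------------------------------------------------------------------------
# Stability score
# ---------------------------------------------------------------------------


def _score_pair(eng: DistanceEngine, m: str, n: str, D0: float,
                dm_cache: dict, dn_cache: dict, distance: int) -> StabilityRecord:
    try:
        if m not in dm_cache:
            dm_cache[m] = eng.mean_shortest_path(removed=(m,))
        if n not in dn_cache:
            dn_cache[n] = eng.mean_shortest_path(removed=(n,))
        Dmn = eng.mean_shortest_path(removed=(m, n))
    except DegenerateGraphError:
        return StabilityRecord(m, n, D0, math.nan, math.nan, math.nan,
                               math.nan, distance, degenerate=True)
    Dm, Dn = dm_cache[m], dn_cache[n]
    S = (2.0 * Dmn - Dm - Dn) / D0
    return StabilityRecord(m, n, D0, Dm, Dn, Dmn, S, distance)


def stability_score(net: SignalingNetwork, m: str, n: str,
                    D0: float | None = None) -> StabilityRecord:
    """Score a single pair on ``net`` (p-value left unset).

    ``m`` must be a labeled cancer gene and ``n`` a non-cancer node.  A
    removal that leaves no reachable pair yields a record flagged
    ``degenerate`` (excluded downstream).
    """
    if m not in net.cancer_genes:
        raise SlnetError(f"{m!r} is not a labeled cancer gene")
    if n in net.cancer_genes or n not in net.nodes:
        raise SlnetError(f"{n!r} is not a non-cancer node of the network")
    if m == n:
        raise SlnetError("m and n must differ")
    eng = DistanceEngine(net)
    if D0 is None:
        D0 = eng.mean_shortest_path()
    from .graphcore import pair_distance

    d = pair_distance(net, m, n)
    dist = int(d) if math.isfinite(d) else -1
    return _score_pair(eng, m, n, D0, {}, {}, dist)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------


def degree_preserving_randomize(net: SignalingNetwork, seed: int,
                                swaps_per_edge: int = 10) -> SignalingNetwork:
    """A degree-preserving randomization of ``net`` via double edge swaps.

    The node set and the exact degree sequence are preserved and the result
    stays simple (swaps that would create self-loops or parallel edges are
    rejected).  The same seed always yields the same network.  Graphs with
    fewer than 2 edges — or graphs admitting no legal swap, like K3 — come
    back unchanged.
    """
    import networkx as nx

    if swaps_per_edge < 1:
        raise SlnetError("swaps_per_edge must be >= 1")
    G = net.graph.copy()
    n_edges = G.number_of_edges()
    if n_edges < 2:
        log.warning("graph has <2 edges; returning it unchanged")
        return replace(net, graph=G)
    nswap = swaps_per_edge * n_edges
    try:
        nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXAlgorithmError:
        # no further legal swap found; whatever swaps were applied are valid
        log.warning("edge-swap attempts exhausted; returning partial rewiring")
    except nx.NetworkXError:
        log.warning("graph too small to swap; returning it unchanged")
    return replace(net, graph=G)


def empirical_pvalue(s_obs: float, s_random, pseudocount: bool = False) -> float:
    """p = #(S_random > S_obs) / n_random, the strict-inequality empirical
    p-value.  With ``pseudocount`` the (r+1)/(n+1) correction is applied so
    p can never be exactly 0."""
    s_random = np.asarray(list(s_random), dtype=float)
    if s_random.size == 0:
        raise SlnetError("empty null sample")
    r = int(np.sum(s_random > s_obs))
    if pseudocount:
        return (r + 1) / (s_random.size + 1)
    return r / s_random.size


# ---------------------------------------------------------------------------
# Model / Results for the network screen
# ---------------------------------------------------------------------------


class NetworkStabilityScreen:
    """Stability-score screen of candidate pairs with a degree-preserving
    randomization null.

    Parameters
    ----------
    network : SignalingNetwork
        The (cleaned) signaling network with cancer genes labeled.
    pairs : list of (cancer_gene, non_cancer_gene), optional
        Candidate pairs; defaults to the full cross product from
        :func:`slnet.graphcore.candidate_pairs`.
    n_random : int
        Size of the null ensemble (1000 by default).
    swaps_per_edge : int
        Double-edge-swap attempts per edge when randomizing.
    null_own_baseline : bool
        If True (default) each randomized network's score uses its own
        average path length as D_0 — the self-consistent application of the
        score; if False the observed network's D_0 is reused.
    pseudocount : bool
        Apply the (r+1)/(n+1) correction to empirical p-values.
    """

    def __init__(self, network: SignalingNetwork, pairs=None, n_random: int = 1000,
                 swaps_per_edge: int = 10, null_own_baseline: bool = True,
                 pseudocount: bool = False):
        if n_random < 1:
            raise SlnetError("n_random must be >= 1 (the null is undefined otherwise)")
        self.network = network
        if pairs is None:
            from .graphcore import candidate_pairs

            pairs = candidate_pairs(sorted(network.non_cancer_genes),
                                    sorted(network.cancer_genes))
        self.pairs = list(pairs)
        for m, n in self.pairs:
            if m not in network.cancer_genes:
                raise SlnetError(f"pair ({m}, {n}): {m!r} is not a cancer gene")
            if n in network.cancer_genes or n not in network.nodes:
                raise SlnetError(f"pair ({m}, {n}): {n!r} is not a non-cancer node")
        self.n_random = int(n_random)
        self.swaps_per_edge = int(swaps_per_edge)
        self.null_own_baseline = bool(null_own_baseline)
        self.pseudocount = bool(pseudocount)

    # -- scoring helpers ---------------------------------------------------

    def _score_network(self, net: SignalingNetwork, D0_override=None):
        """Score every candidate pair on one network; returns (records,
        dict pair -> S or nan)."""
        eng = DistanceEngine(net)
        try:
            D0 = eng.mean_shortest_path() if D0_override is None else D0_override
        except DegenerateGraphError:
            return None, {p: math.nan for p in self.pairs}
        dm_cache: dict = {}
        dn_cache: dict = {}
        D, nodes = eng.distance_matrix()
        idx = {g: i for i, g in enumerate(nodes)}
        records = []
        scores = {}
        for m, n in self.pairs:
            d = D[idx[m], idx[n]]
            dist = int(d) if math.isfinite(d) else -1
            rec = _score_pair(eng, m, n, D0, dm_cache, dn_cache, dist)
            records.append(rec)
            scores[(m, n)] = rec.S if not rec.degenerate else math.nan
        return records, scores

    def fit(self, seed: int = 0, progress: bool = False) -> "StabilityScreenResults":
        """Score all pairs on the observed network and on ``n_random``
        degree-preserving randomizations; attach empirical p-values."""
        obs_records, _ = self._score_network(self.network)
        if obs_records is None:
            raise DegenerateGraphError("observed network has no reachable pair")
        null_scores = {p: [] for p in self.pairs}
        for i in range(self.n_random):
            rnet = degree_preserving_randomize(
                self.network, seed=_subseed(seed, f"rand{i}"),
                swaps_per_edge=self.swaps_per_edge)
            _, scores = self._score_network(
                rnet, None if self.null_own_baseline else obs_records[0].D0)
            for pair, s in scores.items():
                if not math.isnan(s):
                    null_scores[pair].append(s)
            if progress and (i + 1) % 50 == 0:
                log.info("randomization %d/%d", i + 1, self.n_random)
        final = []
        n_degenerate = 0
        for rec in obs_records:
            null = null_scores[(rec.cancer_gene, rec.non_cancer_gene)]
            if rec.degenerate or not null:
                n_degenerate += 1
                final.append(replace(rec, degenerate=True))
                continue
            p = empirical_pvalue(rec.S, null, pseudocount=self.pseudocount)
            final.append(replace(rec, p=p, n_random=len(null)))
        if n_degenerate:
            log.info("excluded %d degenerate pairs", n_degenerate)
        return StabilityScreenResults(self, final, seed=seed)


class StabilityScreenResults:
    """Results of a fitted :class:`NetworkStabilityScreen`.

    Carries one :class:`StabilityRecord` per candidate pair (degenerate
    pairs flagged), exposes them as a DataFrame, and filters to the
    significant pairs at a chosen level.
    """

    def __init__(self, model: NetworkStabilityScreen, records, seed: int):
        self.model = model
        self.records = list(records)
        self.seed = seed

    @property
    def valid_records(self):
        return [r for r in self.records if not r.degenerate]

    def frame(self) -> pd.DataFrame:
        import dataclasses

        cols = [f.name for f in dataclasses.fields(StabilityRecord)]
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records],
                            columns=cols)

    def significant(self, alpha: float = 0.05) -> list:
        """Records with empirical p < alpha (degenerate pairs excluded)."""
        if not (0 < alpha < 1):
            raise SlnetError(f"alpha must be in (0, 1), got {alpha}")
        return [r for r in self.valid_records if r.p < alpha]

    def summary(self, alpha: float = 0.05) -> str:
        df = self.frame()
        ok = df[~df.degenerate]
        lines = [
            "Network stability screen",
            "========================",
            f"nodes: {self.model.network.N}   "
            f"cancer genes: {len(self.model.network.cancer_genes)}",
            f"candidate pairs: {len(self.records)}   "
            f"degenerate: {int(df.degenerate.sum())}",
            f"null ensemble: {self.model.n_random} degree-preserving "
            f"randomizations (seed {self.seed})",
            f"D0 (observed): {self.records[0].D0:.4f}" if self.records else "",
            f"S: mean {ok.S.mean():.4f}  min {ok.S.min():.4f}  "
            f"max {ok.S.max():.4f}" if len(ok) else "",
            f"significant at p < {alpha}: {len(self.significant(alpha))}",
        ]
        top = ok.sort_values(["p", "S"], ascending=[True, False]).head(10)
        if len(top):
            lines.append("")
            lines.append(top.to_string(
                index=False,
                columns=["cancer_gene", "non_cancer_gene", "S", "distance", "p"],
                float_format=lambda v: f"{v:.4f}"))
        return "\n".join(filter(None, lines))


def _subseed(seed: int, name: str) -> int:
    """Stable per-component sub-seed below 2**31."""
    import zlib

    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


def network_screen(net: SignalingNetwork, pairs, n_random: int, alpha: float,
                   seed: int, swaps_per_edge: int = 10,
                   null_own_baseline: bool = True,
                   pseudocount: bool = False) -> list:
    """Step-1 screen: returns the StabilityRecords with p < alpha.

    Thin functional wrapper over :class:`NetworkStabilityScreen`; use the
    class directly to keep all scored pairs.
    """
    model = NetworkStabilityScreen(net, pairs=pairs, n_random=n_random,
                                   swaps_per_edge=swaps_per_edge,
                                   null_own_baseline=null_own_baseline,
                                   pseudocount=pseudocount)
    return model.fit(seed=seed).significant(alpha)


# ---------------------------------------------------------------------------
# Distance screen
# ---------------------------------------------------------------------------


def auto_distance_threshold(distances) -> int:
    """Floor of the mean pair distance (e.g. mean 2.90 -> threshold 2).
    Unreachable pairs (distance < 1) are ignored."""
    ds = [d for d in distances if d >= 1]
    if not ds:
        raise SlnetError("no finite pair distances")
    return math.floor(sum(ds) / len(ds))


def distance_screen(records, threshold="auto", all_distances=None) -> list:
    """Keep records whose pair distance is <= threshold.

    In ``auto`` mode the threshold is the floored mean pair distance over
    *all* candidate pairs — pass ``all_distances`` (the distances of the
    full candidate set) to reproduce that; otherwise the mean is taken over
    the records given.
    """
    if threshold == "auto":
        pool = all_distances if all_distances is not None else [r.distance for r in records]
        threshold = auto_distance_threshold(pool)
        log.info("distance screen: auto threshold = %d", threshold)
    out = [r for r in records if 1 <= r.distance <= threshold]
    log.info("distance screen: %d -> %d pairs (threshold %d)",
             len(records), len(out), threshold)
    return out


# ---------------------------------------------------------------------------
# Frequency screen
# ---------------------------------------------------------------------------


def cumulative_frequency_cutoff(freq: dict, mass_fraction: float) -> list:
    """The shortest count-descending prefix of genes whose cumulative count
    reaches ``mass_fraction`` of the total (ties broken by symbol)."""
    if not (0 < mass_fraction <= 1):
        raise SlnetError(f"mass_fraction must be in (0, 1], got {mass_fraction}")
    total = sum(freq.values())
    if total <= 0:
        raise SlnetError("total frequency mass is zero")
    ranked = sorted(freq, key=lambda g: (-freq[g], g))
    acc = 0
    out = []
    for g in ranked:
        out.append(g)
        acc += freq[g]
        if acc >= mass_fraction * total:
            break
    return out


def frequency_screen(records, kept_genes) -> list:
    """Keep records whose non-cancer gene is in ``kept_genes``."""
    kept = set(kept_genes)
    out = [r for r in records if r.non_cancer_gene in kept]
    log.info("frequency screen: %d -> %d pairs (%d genes kept)",
             len(records), len(out), len(kept))
    return out


# ---------------------------------------------------------------------------
# Function screen
# ---------------------------------------------------------------------------


def enrich(genes, collection: GeneSetCollection, background) -> list:
    """One-sided hypergeometric enrichment of every set in ``collection``
    against the query ``genes``, with Benjamini-Hochberg adjustment across
    the tested sets.

    Population N = |background|, successes K = |set ∩ background|, draws
    n = |genes|, observed k = |genes ∩ set|; p = P[X >= k] (p = 1 when
    k = 0).  The query must be a subset of the background.
    """
    background = set(background)
    if not background:
        raise SlnetError("empty enrichment background")
    genes = set(genes)
    if not genes <= background:
        missing = sorted(genes - background)[:5]
        raise SlnetError(f"query genes outside background: {', '.join(missing)}")
    N, n = len(background), len(genes)
    records = []
    for set_id in sorted(collection.sets):
        members = collection.members(set_id) & background
        K = len(members)
        k = len(genes & members)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichmentRecord(set_id, k, K, n, N, min(p, 1.0)))
    if records:
        qs = multipletests([r.p for r in records], method="fdr_bh")[1]
        records = [replace(r, q=float(q)) for r, q in zip(records, qs)]
    return records


def function_screen(records, enrichment, collection: GeneSetCollection,
                    alpha: float = 0.05) -> list:
    """Keep pairs whose *both* genes belong to at least one significantly
    enriched set (q < alpha)."""
    if not (0 < alpha < 1):
        raise SlnetError(f"alpha must be in (0, 1), got {alpha}")
    significant_sets = [e.set_id for e in enrichment if e.q < alpha]
    surviving: set = set()
    for sid in significant_sets:
        surviving |= collection.members(sid)
    out = [r for r in records
           if r.cancer_gene in surviving and r.non_cancer_gene in surviving]
    log.info("function screen: %d -> %d pairs (%d significant sets)",
             len(records), len(out), len(significant_sets))
    return out
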