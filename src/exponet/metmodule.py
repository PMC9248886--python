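"""Metabolic-feature-based dysregulated module detection.

Untargeted metabolic features (m/z values) that correlate with the
exposome are matched to metabolites of a reference metabolic network by
adduct mass within a ppm tolerance.  The matched ("significant")
metabolites, together with "hidden" metabolites that connect two of
them within three reactions, form a subnetwork in which modules are
found by random-walk (Walktrap) clustering.  Each module M is scored
with an activity score combining an adjusted Newman-Girvan modularity
with input-metabolite enrichment:

    Q_adj = (N_I / N_M) * ( E_M / m  -  sum_{i<j in M} (k_i/2m)(k_j/2m) )
    S     = Q_adj * N_IM / N_M

where m and the degrees k are taken from the FULL metabolic network,
N_M is the module size, E_M its internal edge count, N_IM the input
metabolites inside it and N_I the total number of input metabolites.
Significance comes from a resampling null: random feature sets of the
same size are pushed through the same pipeline 100 times, the pooled
null scores are fitted with a Gamma distribution by maximum likelihood,
and module p-values are upper Gamma tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

from .core_io import AdductTable, MetabolicNetwork, logger


@dataclass
class FeatureMatch:
    mz: float
    polarity: str
    metabolite: str
    adduct: str
    ppm_error: float


@dataclass
class FeatureMatchSet:
    matches: list[FeatureMatch]

    @property
    def metabolites(self) -> set[str]:
        """The matched metabolite set I."""
        return {m.metabolite for m in self.matches}


@dataclass
class CandidateModule:
    """A connected candidate module in the significant subnetwork."""

    members: list[str]
    significant_members: list[str]

    @property
    def n_m(self) -> int:
        return len(self.members)

    @property
    def n_im(self) -> int:
        return len(self.significant_members)


@dataclass
class ScoredModule:
    module: CandidateModule
    q_adj: float
    s: float
    e_m: int
    p: float | None = None


@dataclass
class NullModel:
    """Gamma-fitted resampling null of module activity scores."""

    s_null: np.ndarray
    gamma_shape: float
    gamma_scale: float
    n_resamples: int


# ---------------------------------------------------------------------------
# Step 1: adduct matching
# ---------------------------------------------------------------------------


def match_features(
    features: list[tuple[float, str]],
    network: MetabolicNetwork,
    adducts: AdductTable | None = None,
    ppm_tol: float = 10.0,
) -> FeatureMatchSet:
    """Match (m/z, polarity) features to network metabolites by adduct mass.

    A feature matches metabolite with neutral mass M under adduct
    (shift s, charge z) when the relative error between the feature m/z
    and (M + s)/|z| is within ``ppm_tol`` parts per million, with the
    polarity of the adduct matching the feature's.
    """
    if adducts is None:
        from .core_io import DEFAULT_ADDUCTS
        adducts = DEFAULT_ADDUCTS
    if not adducts.rows:
        raise ValueError("empty adduct table")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    ids = network.nodes_with_mass()
    masses = np.array([network.masses[i] for i in ids], dtype=float)
    matches: list[FeatureMatch] = []
    for mz, polarity in features:
        for name, shift, charge, pol in adducts.for_polarity(polarity):
            theo = (masses + shift) / abs(charge)
            ppm = np.abs(mz - theo) / theo * 1e6
            for idx in np.flatnonzero(ppm <= ppm_tol):
                matches.append(FeatureMatch(mz=float(mz), polarity=polarity,
                                            metabolite=ids[idx], adduct=name,
                                            ppm_error=float(ppm[idx])))
    return FeatureMatchSet(matches=matches)


# ---------------------------------------------------------------------------
# Step 2: subnetwork extraction and module detection
# ---------------------------------------------------------------------------


def extract_subnetwork(
    network: MetabolicNetwork,
    significant: set[str],
    max_steps: int = 3,
) -> nx.Graph:
    """Subnetwork of significant metabolites plus connecting hidden ones.

    A non-significant metabolite h is included when it lies on a path of
    at most ``max_steps`` edges between two distinct significant
    metabolites, i.e. min over significant pairs of d(s1,h) + d(h,s2)
    is <= max_steps with both legs >= 1.  Node attribute ``significant``
    flags the input metabolites; edges are induced from the network.
    """
    if not significant:
        raise ValueError("significant metabolite set is empty")
    g = network.graph
    sig_in = sorted(s for s in significant if s in g)
    if not sig_in:
        raise ValueError("empty subnetwork: no significant metabolite maps into the network")
    # distances from every significant node, truncated at max_steps - 1
    dists = {s: nx.single_source_shortest_path_length(g, s, cutoff=max_steps - 1) for s in sig_in}
    hidden: set[str] = set()
    for node in g.nodes:
        if node in significant:
            continue
        reach = sorted(
            (d[node], s) for s, d in dists.items() if node in d and d[node] >= 1
        )
        if len(reach) >= 2 and reach[0][0] + reach[1][0] <= max_steps:
            hidden.add(node)
    keep = set(sig_in) | hidden
    sn = g.subgraph(keep).copy()
    nx.set_node_attributes(sn, {n: (n in significant) for n in sn.nodes}, "significant")
    return sn


def detect_modules(sn: nx.Graph, min_size: int = 3) -> list[CandidateModule]:
    """Random-walk (Walktrap, t=4) modules of the subnetwork.

    The dendrogram is cut at maximal standard modularity; modules with
    fewer than ``min_size`` nodes are discarded.  The procedure is
    deterministic: walk distances are computed exactly, no sampling.
    """
    nodes = sorted(sn.nodes)
    if len(nodes) < min_size or sn.number_of_edges() == 0:
        return []
    modules: list[CandidateModule] = []
    # cluster each connected component separately; igraph's walktrap
    # handles disconnected graphs but per-component runs keep merges local
    for comp in sorted(nx.connected_components(sn), key=lambda c: sorted(c)[0]):
        comp = sorted(comp)
        if len(comp) < min_size:
            continue
        sub = sn.subgraph(comp)
        cidx = {n: i for i, n in enumerate(comp)}
        g = ig.Graph(
            n=len(comp),
            edges=[(cidx[u], cidx[v]) for u, v in sorted(sub.edges(), key=lambda e: (str(e[0]), str(e[1])))],
        )
        dendrogram = g.community_walktrap(steps=4)
        clustering = dendrogram.as_clustering()
        for cluster in clustering:
            members = sorted(comp[i] for i in cluster)
            if len(members) < min_size:
                continue
            sig = [n for n in members if sn.nodes[n].get("significant", False)]
            modules.append(CandidateModule(members=members, significant_members=sig))
    modules.sort(key=lambda mod: mod.members)
    return modules


# ---------------------------------------------------------------------------
# Step 3: activity score
# ---------------------------------------------------------------------------


def activity_score(
    module: CandidateModule,
    network: MetabolicNetwork,
    n_input: int,
    pair_convention: str = "unordered",
) -> tuple[float, float]:
    """Adjusted modularity Q_adj and activity score S of a module.

    ``n_input`` is N_I, the total number of matched input metabolites.
    The null-expectation sum runs over unordered distinct member pairs
    i<j by default; ``pair_convention="ordered_with_diagonal"`` switches
    to the ordered sum including i=j.
    """
    if module.n_m == 0:
        raise ValueError("empty module")
    if n_input < module.n_im:
        raise ValueError("n_input (N_I) cannot be smaller than the module's input count (N_IM)")
    missing = [n for n in module.members if n not in network.graph]
    if missing:
        raise ValueError(f"module members absent from the network: {missing}")
    m = network.m
    deg = network.graph.degree
    k = np.array([deg(n) for n in module.members], dtype=float) / (2.0 * m)
    e_m = network.graph.subgraph(module.members).number_of_edges()
    if pair_convention == "unordered":
        expectation = (np.sum(k) ** 2 - np.sum(k**2)) / 2.0
    elif pair_convention == "ordered_with_diagonal":
        expectation = np.sum(k) ** 2
    else:
        raise ValueError(f"unknown pair_convention {pair_convention!r}")
    q_adj = (n_input / module.n_m) * (e_m / m - expectation)
    s = q_adj * module.n_im / module.n_m
    return float(q_adj), float(s)


def score_modules(
    modules: list[CandidateModule],
    network: MetabolicNetwork,
    n_input: int,
    pair_convention: str = "unordered",
) -> list[ScoredModule]:
    """Score every candidate module; S is floored at 0 for null modeling."""
    out = []
    for mod in modules:
        q_adj, s = activity_score(mod, network, n_input, pair_convention)
        e_m = network.graph.subgraph(mod.members).number_of_edges()
        out.append(ScoredModule(module=mod, q_adj=q_adj, s=max(s, 0.0), e_m=e_m))
    return out


# ---------------------------------------------------------------------------
# Steps 4-5: resampling null and p-values
# ---------------------------------------------------------------------------


def _run_detection(
    features: list[tuple[float, str]],
    network: MetabolicNetwork,
    adducts: AdductTable | None,
    ppm_tol: float,
    pair_convention: str = "unordered",
) -> list[ScoredModule]:
    """match -> subnetwork -> modules -> scores for one feature list."""
    matched = match_features(features, network, adducts, ppm_tol)
    sig = matched.metabolites
    if not sig:
        return []
    try:
        sn = extract_subnetwork(network, sig)
    except ValueError:
        return []
    modules = detect_modules(sn)
    return score_modules(modules, network, n_input=len(sig & set(network.graph)),
                         pair_convention=pair_convention)


def null_distribution(
    all_features: list[tuple[float, str]],
    significant_features: list[tuple[float, str]],
    network: MetabolicNetwork,
    adducts: AdductTable | None = None,
    ppm_tol: float = 10.0,
    n_resamples: int = 100,
    seed: int = 0,
    min_scores: int = 30,
) -> NullModel:
    """Gamma null of activity scores from resampled decoy feature sets.

    Each resample draws |significant| features uniformly without
    replacement from the non-significant pool and runs the full
    detection pipeline; the pooled positive scores are fitted with a
    Gamma distribution by maximum likelihood (location fixed at 0).
    """
    sig_set = set(significant_features)
    pool = [f for f in all_features if f not in sig_set]
    n_draw = len(significant_features)
    if len(pool) < n_draw:
        raise ValueError("non-significant feature pool smaller than the significant set")
    rng = np.random.default_rng(seed)
    scores: list[float] = []
    for _ in range(n_resamples):
        idx = rng.choice(len(pool), size=n_draw, replace=False)
        null_feats = [pool[i] for i in idx]
        for sm in _run_detection(null_feats, network, adducts, ppm_tol):
            scores.append(sm.s)
    s_null = np.array(scores, dtype=float)
    if s_null.size < min_scores:
        raise ValueError(
            f"only {s_null.size} pooled null scores (< {min_scores}); increase n_resamples"
        )
    positive = s_null[s_null > 0]
    if positive.size < 2 or np.ptp(positive) == 0:
        raise ValueError("degenerate null scores: cannot fit a Gamma distribution")
    shape, scale = fit_gamma_mle(positive)
    return NullModel(s_null=s_null, gamma_shape=shape, gamma_scale=scale,
                     n_resamples=n_resamples)


def fit_gamma_mle(x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gamma(shape, scale) fit with location fixed at 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Gamma MLE requires strictly positive data")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all values equal")
    shape, _loc, scale = stats.gamma.fit(x, floc=0)
    return float(shape), float(scale)


def module_pvalues(
    scored: list[ScoredModule],
    null: NullModel,
    alpha: float = 0.05,
) -> list[ScoredModule]:
    """Upper-tail Gamma p-values; modules with p < alpha are retained."""
    kept = []
    for sm in scored:
        p = float(stats.gamma.sf(sm.s, a=null.gamma_shape, scale=null.gamma_scale))
        sm.p = min(max(p, 0.0), 1.0)
        if sm.p < alpha:
            kept.append(sm)
    return kept


def detect_dysregulated_modules(
    all_features: list[tuple[float, str]],
    significant_features: list[tuple[float, str]],
    network: MetabolicNetwork,
    adducts: AdductTable | None = None,
    ppm_tol: float = 10.0,
    n_resamples: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    null: NullModel | None = None,
) -> tuple[list[ScoredModule], NullModel]:
    """Full workflow: detection on the significant features, resampling
    null on decoys, Gamma p-values, and the p < alpha filter.

    A prefitted ``null`` can be supplied to reuse one null model across
    several feature lists drawn from the same pool.
    """
    scored = _run_detection(significant_features, network, adducts, ppm_tol)
    if null is None:
        null = null_distribution(all_features, significant_features, network,
                                 adducts, ppm_tol, n_resamples, seed)
    kept = module_pvalues(scored, null, alpha)
    logger.info("detect_dysregulated_modules: %d/%d modules at p < %g", len(kept), len(scored), alpha)
    return kept, null
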