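"""Thresholded Spearman/FDR correlation networks across omic blocks.

For every requested pair of omic blocks (a block may be paired with
itself), all feature pairs are correlated with Spearman's rho on the
window-aligned samples, p-values come from the t-approximation, and
Benjamini-Hochberg adjustment is applied across all tests of the
block-pair analysis.  Edges survive when |rho| > r_min and q < q_max
(both strict), the thresholds of the study being |rho| > 0.9 and
q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OmicsBlock, logger
from .preprocess import AlignmentMap

Node = tuple[str, str]  # (ome_label, feature_id)


@dataclass
class CorrelationEdge:
    source: Node
    target: Node
    rho: float
    n_obs: int
    p: float
    q: float


@dataclass
class CorrelationNetwork:
    """Significant correlation edges plus per-node degrees."""

    edges: list[CorrelationEdge]
    block_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def node_degrees(self) -> dict[Node, int]:
        deg: dict[Node, int] = {}
        for e in self.edges:
            deg[e.source] = deg.get(e.source, 0) + 1
            deg[e.target] = deg.get(e.target, 0) + 1
        return deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: Node) -> list[Node]:
        out = []
        for e in self.edges:
            if e.source == node:
                out.append(e.target)
            elif e.target == node:
                out.append(e.source)
        return out


def spearman_rho(x: np.ndarray, y: np.ndarray, min_n: int = 5) -> tuple[float, float, int]:
    """Spearman correlation with pairwise deletion of missing values.

    Returns ``(rho, p, n_obs)``.  rho is the Pearson correlation of
    midranks; the two-sided p-value uses the t-approximation with
    ``n_obs - 2`` degrees of freedom.  Raises on constant input or when
    fewer than ``min_n`` complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    n = xs.size
    if n < min_n:
        raise ValueError(f"only {n} complete pairs, need at least {min_n}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = _t_pvalue(np.array([rho]), n)[0]
    return rho, float(p), int(n)


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation; |rho|=1 gives p=0."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j>=i} p_(j) * N / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pair_correlations(
    a: np.ndarray,
    b: np.ndarray,
    *,
    intra: bool,
    min_n: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman between rows of ``a`` and rows of ``b``.

    Returns index arrays (i, j), rho, p and n_obs for the valid pairs
    (constant or under-sampled pairs are skipped).  ``intra`` restricts to
    unordered pairs i < j.
    """
    na, nb = a.shape[0], b.shape[0]
    has_missing = np.isnan(a).any() or np.isnan(b).any()
    ii, jj, rhos, ps, ns = [], [], [], [], []
    if not has_missing:
        n = a.shape[1]
        if n >= min_n:
            ra = np.apply_along_axis(stats.rankdata, 1, a)
            rb = np.apply_along_axis(stats.rankdata, 1, b)
            sa = ra.std(axis=1)
            sb = rb.std(axis=1)
            za = (ra - ra.mean(axis=1, keepdims=True))
            zb = (rb - rb.mean(axis=1, keepdims=True))
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = (za @ zb.T) / n / np.outer(sa, sb)
            for i in range(na):
                if sa[i] == 0:
                    continue
                j_start = i + 1 if intra else 0
                for j in range(j_start, nb):
                    if sb[j] == 0:
                        continue
                    rho = float(np.clip(corr[i, j], -1.0, 1.0))
                    ii.append(i)
                    jj.append(j)
                    rhos.append(rho)
                    ns.append(n)
            ps = list(_t_pvalue(np.array(rhos), n)) if rhos else []
    else:
        for i in range(na):
            j_start = i + 1 if intra else 0
            for j in range(j_start, nb):
                try:
                    rho, p, n_obs = spearman_rho(a[i], b[j], min_n=min_n)
                except ValueError:
                    continue
                ii.append(i)
                jj.append(j)
                rhos.append(rho)
                ps.append(p)
                ns.append(n_obs)
    return (np.array(ii, dtype=int), np.array(jj, dtype=int),
            np.array(rhos, dtype=float), np.array(ps, dtype=float), np.array(ns, dtype=int))


def build_network(
    blocks: dict[str, OmicsBlock],
    pairs: list[tuple[str, str]],
    alignments: dict[tuple[str, str], AlignmentMap] | None = None,
    r_min: float = 0.9,
    q_max: float = 0.05,
    min_n: int = 5,
    fdr_scope: str = "pair",
) -> CorrelationNetwork:
    """Build the thresholded correlation network over the requested block pairs.

    Parameters
    ----------
    blocks
        Mapping ome label -> preprocessed block.
    pairs
        Block pairs to analyse; ``(x, x)`` computes intra-block
        correlations over unordered feature pairs.
    alignments
        Per-pair sample alignment; optional when the two blocks share
        identical sample ids (then identity alignment is used).
    fdr_scope
        ``"pair"`` (default) adjusts p-values across all tests of one
        block-pair analysis, ``"per_variable"`` adjusts within each source
        feature's tests, ``"global"`` pools every test of the run.
    """
    if fdr_scope not in ("pair", "per_variable", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    per_pair: list[dict] = []
    for label_a, label_b in pairs:
        ba, bb = blocks[label_a], blocks[label_b]
        intra = label_a == label_b
        if intra:
            sa = sb = ba.sample_ids
        elif alignments is not None and (label_a, label_b) in alignments:
            amap = alignments[(label_a, label_b)]
            sa = [p[0] for p in amap.pairs]
            sb = [p[1] for p in amap.pairs]
        elif alignments is not None and (label_b, label_a) in alignments:
            amap = alignments[(label_b, label_a)]
            sa = [p[1] for p in amap.pairs]
            sb = [p[0] for p in amap.pairs]
        else:
            shared = [s for s in ba.sample_ids if s in set(bb.sample_ids)]
            if not shared:
                raise ValueError(f"no alignment for block pair ({label_a}, {label_b}) and no shared sample ids")
            sa = sb = shared
        if len(sa) == 0:
            raise ValueError(f"empty alignment for block pair ({label_a}, {label_b})")
        a = ba.data[sa].to_numpy(dtype=float)
        b = bb.data[sb].to_numpy(dtype=float)
        ii, jj, rhos, ps, ns = _pair_correlations(a, b, intra=intra, min_n=min_n)
        per_pair.append(
            dict(label_a=label_a, label_b=label_b, block_a=ba, block_b=bb,
                 ii=ii, jj=jj, rhos=rhos, ps=ps, ns=ns)
        )

    # FDR adjustment at the configured scope
    if fdr_scope == "global":
        all_p = np.concatenate([d["ps"] for d in per_pair]) if per_pair else np.array([])
        all_q = bh_adjust(all_p)
        offset = 0
        for d in per_pair:
            k = d["ps"].size
            d["qs"] = all_q[offset:offset + k]
            offset += k
    else:
        for d in per_pair:
            if fdr_scope == "pair":
                d["qs"] = bh_adjust(d["ps"])
            else:  # per_variable: adjust within each source feature's family
                qs = np.empty_like(d["ps"])
                for i in np.unique(d["ii"]):
                    sel = d["ii"] == i
                    qs[sel] = bh_adjust(d["ps"][sel])
                d["qs"] = qs

    edges: list[CorrelationEdge] = []
    seen: set[frozenset[Node]] = set()
    for d in per_pair:
        feats_a = d["block_a"].feature_ids
        feats_b = d["block_b"].feature_ids
        for i, j, rho, p, q, n_obs in zip(d["ii"], d["jj"], d["rhos"], d["ps"], d["qs"], d["ns"]):
            if not (abs(rho) > r_min and q < q_max):
                continue
            src: Node = (d["label_a"], feats_a[i])
            tgt: Node = (d["label_b"], feats_b[j])
            if src == tgt:
                continue
            key = frozenset((src, tgt))
            if key in seen:
                continue
            seen.add(key)
            edges.append(CorrelationEdge(source=src, target=tgt, rho=float(rho),
                                         n_obs=int(n_obs), p=float(p), q=float(q)))
    edges.sort(key=lambda e: (e.source, e.target))
    logger.info("build_network: %d significant edges across %d block pair(s)", len(edges), len(pairs))
    return CorrelationNetwork(edges=edges, block_pairs=list(pairs))


def degree_table(network: CorrelationNetwork, min_degree: int = 0) -> pd.DataFrame:
    """Nodes with degree strictly above ``min_degree``.

    Sorted by degree descending, then node id ascending (stable ties).
    """
    rows = [
        {"ome": n[0], "feature": n[1], "degree": d}
        for n, d in network.node_degrees.items()
        if d > min_degree
    ]
    df = pd.DataFrame(rows, columns=["ome", "feature", "degree"])
    if len(df):
        df = df.sort_values(["degree", "ome", "feature"], ascending=[False, True, True],
                            kind="mergesort").reset_index(drop=True)
    return df
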