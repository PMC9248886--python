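"""Hypergeometric over-representation tests with FDR control.

Pathways come from GMT files (GO/KEGG/Reactome-style for proteins, KEGG
for metabolites).  Each pathway is intersected with the measured
universe before counting; the p-value is the upper tail P(X >= k) of a
hypergeometric draw, Benjamini-Hochberg adjustment runs across the
tested pathways, and the protein analysis additionally requires more
than ``min_hits`` hits per pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core_io import PathwaySet, logger
from .corrnet import bh_adjust


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    n_universe: int
    n_pathway: int
    n_selected: int
    n_hits: int
    p: float
    q: float


def hypergeom_test(n_universe: int, n_pathway: int, n_selected: int, n_hits: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= n_hits).

    X counts pathway members in a draw of ``n_selected`` from a universe
    of ``n_universe`` containing ``n_pathway`` members.  Computed via
    log-binomial survival function for numerical stability.
    """
    if not (0 <= n_hits <= min(n_pathway, n_selected) <= n_universe):
        raise ValueError(
            f"inconsistent counts: N={n_universe}, K={n_pathway}, n={n_selected}, k={n_hits}"
        )
    if n_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_hits - 1, n_universe, n_pathway, n_selected))


def enrich(
    selected: set[str],
    universe: set[str],
    pathways: list[PathwaySet],
    min_hits: int = 3,
    q_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of ``selected`` within each pathway.

    Pathways disjoint from the universe are skipped (logged).  Retained
    results satisfy q < q_max and n_hits > min_hits, both strict; set
    ``min_hits=0`` for metabolite mode where the hit filter is k >= 1.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = selected - universe
    if stray:
        raise ValueError(f"selected ids outside the universe: {sorted(stray)[:5]}")
    n_u = len(universe)
    n_s = len(selected)
    tested: list[tuple[PathwaySet, int, int, float]] = []
    skipped = 0
    for pw in pathways:
        members = pw.members & universe
        if not members:
            skipped += 1
            continue
        hits = len(members & selected)
        p = hypergeom_test(n_u, len(members), n_s, hits)
        tested.append((pw, len(members), hits, p))
    if skipped:
        logger.info("enrich: skipped %d pathways disjoint from the universe", skipped)
    if not tested:
        return []
    qs = bh_adjust([t[3] for t in tested])
    results = []
    for (pw, n_pw, hits, p), q in zip(tested, qs):
        if q < q_max and hits > min_hits:
            results.append(EnrichmentResult(
                pathway_id=pw.pathway_id, pathway_name=pw.pathway_name,
                n_universe=n_u, n_pathway=n_pw, n_selected=n_s, n_hits=hits,
                p=p, q=float(q),
            ))
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
                "N": r.n_universe, "K": r.n_pathway, "n": r.n_selected,
                "k": r.n_hits, "p": r.p, "q": r.q,
            }
            for r in results
        ],
        columns=["pathway_id", "pathway_name", "N", "K", "n", "k", "p", "q"],
    )
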