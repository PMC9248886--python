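"""Seeded generators emulating the longitudinal study's data structure.

Everything here is a pure function of a :class:`SimulationSpec` (which
carries the seed), so outputs are bitwise reproducible.  Three study
layouts are generated:

* ``simulate_blocks`` — per-ome abundance matrices over ~18 collection
  windows.  Unplanted features are i.i.d. log-normal over time; features
  of an exposome category can co-load on a latent category factor (a
  shared seasonal/behavioural driver); planted cross-ome pairs are tied
  through a Gaussian copula on ranks so their population Spearman
  correlation hits a prescribed target.
* ``simulate_metabolic_study`` — a small metabolite reaction network
  (Erdos-Renyi background plus one planted dense module) with
  well-separated monoisotopic masses, and [M+H]+ feature m/z lists in
  which the "significant" features are the planted module's ions.
* ``simulate_outcomes`` — clinical outcomes generated as linear
  functions of category factor components plus Gaussian noise, with the
  true explained variance and category shares recorded.

Two preset specs, :func:`correlation_study_spec` and
:func:`contribution_study_spec`, freeze the default conditions used to
exercise the network-recovery and contribution-recovery stages.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import MetabolicNetwork, OmicsBlock

#: Proton mass shift of the [M+H]+ adduct (Da).
PROTON = 1.007276

STUDY_START = _dt.date(2016, 1, 15)


@dataclass
class SimulationSpec:
    """Parameters of a synthetic study.

    Defaults mirror the longitudinal single-subject design: ~18
    collection windows of 1-3 days, tens of features per ome, planted
    cross-ome monotone pairs at population Spearman 0.97, a 60-node
    metabolite network with one dense 8-member module, and outcomes
    driven by the chemical category with population R^2 = 0.6.
    """

    seed: int = 0
    n_timepoints: int = 18
    feature_counts: dict[str, int] = field(
        default_factory=lambda: {"chemical": 40, "metabolome": 40}
    )
    # planted cross-ome monotone pairs
    n_planted_pairs: int = 20
    planted_rho: float = 0.97
    planted_sign: int = 1
    planted_pair_blocks: tuple[str, str] = ("chemical", "metabolome")
    # latent within-category factor (0 disables)
    category_factor_loading: float = 0.0
    # metabolic study
    n_metabolites: int = 60
    background_edge_p: float = 0.05
    module_size: int = 8
    module_density: float = 1.0
    module_input_fraction: float = 1.0
    n_decoy_features: int = 40
    # outcomes
    outcome_betas: dict[str, float] = field(
        default_factory=lambda: {"chemical": 0.8, "biological": 0.0, "environmental": 0.0}
    )
    n_outcomes: int = 5
    target_outcome_r2: float = 0.6
    missing_rate: float = 0.0
    lognormal_mu: float = 10.0
    lognormal_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.planted_rho <= 1):
            raise ValueError("planted |rho| target must lie in (0, 1]")
        if self.n_planted_pairs > 0 and self.n_timepoints < 3:
            raise ValueError("cannot plant correlated pairs with fewer than 3 time points")
        if any(c <= 0 for c in self.feature_counts.values()):
            raise ValueError("feature counts must be positive")
        if not (0 < self.module_density <= 1):
            raise ValueError("module density must lie in (0, 1]")
        if self.module_size < 3:
            raise ValueError("planted module size must be >= 3")

    @property
    def outcome_noise_sd(self) -> float:
        """Noise SD giving the target population R^2 for the outcome model."""
        ss_beta = sum(b**2 for b in self.outcome_betas.values())
        if ss_beta == 0 or self.target_outcome_r2 <= 0:
            return 1.0
        return float(np.sqrt(ss_beta * (1 - self.target_outcome_r2) / self.target_outcome_r2))


def correlation_study_spec(seed: int = 0) -> SimulationSpec:
    """Conditions of the network-recovery study: 20 planted pairs at
    population Spearman 0.97 between two 40-feature blocks (20 planted +
    20 null features each, hence 400 null-null pairs), n = 18."""
    return SimulationSpec(seed=seed)


def contribution_study_spec(seed: int = 0) -> SimulationSpec:
    """Conditions of the contribution-recovery study: three 20-feature
    exposome category blocks whose features share a strong latent
    category driver (loading 0.9), outcomes driven by the chemical
    factor at population R^2 = 0.6."""
    return SimulationSpec(
        seed=seed,
        feature_counts={"chemical": 20, "biological": 20, "environmental": 20},
        n_planted_pairs=0,
        category_factor_loading=0.9,
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _copula_rho(target_spearman: float) -> float:
    """Latent Gaussian correlation giving a population Spearman target.

    For a bivariate Gaussian copula, rho_S = (6/pi) * arcsin(rho_G / 2).
    """
    return float(2.0 * np.sin(np.pi * target_spearman / 6.0))


def sample_windows(spec: SimulationSpec) -> dict[str, tuple[_dt.date, _dt.date]]:
    """Consecutive 1-3 day collection windows starting 2016-01-15."""
    rng = np.random.default_rng(spec.seed + 10_007)
    windows = {}
    start = STUDY_START
    for t in range(spec.n_timepoints):
        length = int(rng.integers(1, 4))  # 1-3 days
        end = start + _dt.timedelta(days=length - 1)
        windows[f"S{t + 1:02d}"] = (start, end)
        start = end + _dt.timedelta(days=1)
    return windows


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_blocks(spec: SimulationSpec) -> tuple[dict[str, OmicsBlock], list[tuple]]:
    """Generate per-ome abundance blocks and the planted-pair ground truth.

    Returns ``(blocks, truth)`` where ``truth`` lists
    ``(ome_a, feature_a, ome_b, feature_b, target_rho, sign)`` for every
    planted pair.  Planted features occupy the first
    ``n_planted_pairs`` rows of each of the two paired blocks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_timepoints
    windows = sample_windows(spec)
    sample_ids = list(windows)

    latent: dict[str, np.ndarray] = {}
    for ome, count in spec.feature_counts.items():
        z = rng.standard_normal((count, n))
        if spec.category_factor_loading > 0:
            lam = spec.category_factor_loading
            factor = rng.standard_normal(n)
            z = lam * factor + np.sqrt(1 - lam**2) * z
        latent[ome] = z

    truth: list[tuple] = []
    if spec.n_planted_pairs > 0:
        ome_a, ome_b = spec.planted_pair_blocks
        for ome in (ome_a, ome_b):
            if spec.feature_counts.get(ome, 0) < spec.n_planted_pairs:
                raise ValueError(f"block '{ome}' too small for {spec.n_planted_pairs} planted pairs")
        rho_g = _copula_rho(spec.planted_rho)
        for i in range(spec.n_planted_pairs):
            zx = rng.standard_normal(n)
            eps = rng.standard_normal(n)
            zy = spec.planted_sign * (rho_g * zx + np.sqrt(1 - rho_g**2) * eps)
            latent[ome_a][i] = zx
            latent[ome_b][i] = zy
            truth.append((ome_a, f"{ome_a}_F{i + 1:03d}", ome_b, f"{ome_b}_F{i + 1:03d}",
                          spec.planted_rho, spec.planted_sign))

    blocks: dict[str, OmicsBlock] = {}
    for ome, z in latent.items():
        values = np.exp(spec.lognormal_mu + spec.lognormal_sigma * z)
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) < spec.missing_rate
            values = values.copy()
            values[mask] = np.nan
        feature_ids = [f"{ome}_F{i + 1:03d}" for i in range(values.shape[0])]
        data = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
        blocks[ome] = OmicsBlock(ome_label=ome, data=data, sample_windows=dict(windows))
    return blocks, truth


def simulate_metabolic_study(
    spec: SimulationSpec,
) -> tuple[MetabolicNetwork, list[tuple[float, str]], list[tuple[float, str]], list[str]]:
    """Metabolite network with one planted dense module and its ion features.

    Returns ``(network, all_features, significant_features, module_members)``.
    The background is Erdos-Renyi; the planted module's internal edges are
    added at the requested density (plus a spanning path so it is always
    connected).  Monoisotopic masses sit on a 0.05 Da grid in 80-600 Da,
    so every [M+H]+ ion matches exactly one metabolite at 10 ppm.
    ``significant_features`` are the [M+H]+ m/z of the module members
    designated as input; ``all_features`` adds one decoy ion per sampled
    non-member metabolite.
    """
    rng = np.random.default_rng(spec.seed + 20_011)
    n = spec.n_metabolites
    ids = [f"M{i + 1:04d}" for i in range(n)]
    grid = np.round(np.arange(80.0, 600.0, 0.05), 6)
    masses = dict(zip(ids, np.sort(rng.choice(grid, size=n, replace=False))))

    g = nx.from_numpy_array(
        np.triu(rng.random((n, n)) < spec.background_edge_p, k=1).astype(int)
    )
    g = nx.relabel_nodes(g, {i: ids[i] for i in range(n)})
    g.remove_edges_from(nx.selfloop_edges(g))

    members = [ids[i] for i in sorted(rng.choice(n, size=spec.module_size, replace=False))]
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            if b == a + 1 or rng.random() < spec.module_density:
                g.add_edge(members[a], members[b])

    network = MetabolicNetwork(graph=g, masses=masses)

    n_input = max(1, int(round(spec.module_input_fraction * len(members))))
    input_members = members[:n_input]
    significant = [(round(masses[mid] + PROTON, 6), "+") for mid in input_members]
    non_members = [i for i in ids if i not in set(members)]
    decoy_ids = [non_members[i] for i in
                 sorted(rng.choice(len(non_members),
                                   size=min(spec.n_decoy_features, len(non_members)),
                                   replace=False))]
    decoys = [(round(masses[mid] + PROTON, 6), "+") for mid in decoy_ids]
    return network, significant + decoys, significant, members


def simulate_outcomes(
    spec: SimulationSpec,
    blocks: dict[str, OmicsBlock],
) -> tuple[pd.DataFrame, dict]:
    """Outcomes as linear functions of category factor components plus noise.

    Each outcome is ``sum_c beta_c * u_c + sd * eps`` where ``u_c`` is the
    unit-variance first principal direction of category c's features
    (log2, z-scored).  Returns the outcomes (outcome x sample DataFrame)
    and the ground truth: population R^2 and per-category shares.
    """
    rng = np.random.default_rng(spec.seed + 30_013)
    sample_ids = None
    components: dict[str, np.ndarray] = {}
    for cat, beta in spec.outcome_betas.items():
        if cat not in blocks:
            continue
        block = blocks[cat]
        sample_ids = block.sample_ids
        X = np.log2(block.data.to_numpy(dtype=float) + 1.0).T  # samples x features
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        X = X[:, sd > 0] / sd[sd > 0]
        u_, s_, _ = np.linalg.svd(X, full_matrices=False)
        pc1 = u_[:, 0] * s_[0]
        pc1 = pc1 / pc1.std(ddof=1)
        if pc1[np.argmax(np.abs(pc1))] < 0:
            pc1 = -pc1
        components[cat] = pc1
    if sample_ids is None:
        raise ValueError("no outcome-relevant category blocks present")

    sd_noise = spec.outcome_noise_sd
    n = len(sample_ids)
    rows = {}
    for j in range(spec.n_outcomes):
        y = sd_noise * rng.standard_normal(n)
        for cat, beta in spec.outcome_betas.items():
            if beta != 0 and cat in components:
                y = y + beta * components[cat]
        rows[f"outcome_{j + 1:02d}"] = y
    outcomes = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)

    ss_beta = sum(b**2 for b in spec.outcome_betas.values())
    denom = ss_beta + sd_noise**2
    true_r2 = ss_beta / denom if denom > 0 else 0.0
    true_shares = {
        cat: (b**2 / ss_beta) * true_r2 if ss_beta > 0 else 0.0
        for cat, b in spec.outcome_betas.items()
    }
    truth = {"r2": true_r2, "shares": true_shares, "noise_sd": sd_noise}
    return outcomes, truth
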