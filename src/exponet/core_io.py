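"""Data model and file I/O for the exposome-network pipeline.

All tabular formats are plain TSV/CSV: feature-by-sample abundance
matrices (first column = feature id, header = sample ids), sample-window
metadata tables, GMT pathway collections, metabolic-network edge lists
with a companion monoisotopic-mass table, and adduct tables.

Conventions fixed here and relied on everywhere else:

* matrices are oriented features x samples and never transposed by guess;
* dates are ISO-8601 (``YYYY-MM-DD``) only;
* missing values are serialized as ``NA`` and held as ``NaN`` in memory.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("exponet")

#: Omic layers the study design recognises. Readers accept any label but
#: the canonical names are used by the CLI and the simulator.
OME_LABELS = (
    "chemical",
    "biological",
    "environmental",
    "microbiome",
    "proteome",
    "metabolome",
    "cytokine",
    "blood_test",
)

MISSING_TOKEN = "NA"


def configure_logging(level: str = "INFO") -> None:
    """Initialise the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OmicsBlock:
    """One omic layer: a features x samples abundance matrix.

    Parameters
    ----------
    ome_label
        Name of the omic layer (e.g. ``"metabolome"``).
    data
        DataFrame with feature ids as index and sample ids as columns.
        Missing measurements are ``NaN``.
    sample_windows
        Optional mapping ``sample_id -> (start_date, end_date)`` giving the
        calendar window over which the sample was collected.
    feature_annotations
        Optional mapping ``feature_id -> class label`` (chemical class,
        genus kingdom, ...).
    """

    ome_label: str
    data: pd.DataFrame
    sample_windows: dict[str, tuple[_dt.date, _dt.date]] | None = None
    feature_annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        feats = list(self.data.index)
        samps = list(self.data.columns)
        dup_f = _duplicates(feats)
        if dup_f:
            raise ValueError(f"duplicate feature ids in block '{self.ome_label}': {sorted(dup_f)}")
        dup_s = _duplicates(samps)
        if dup_s:
            raise ValueError(f"duplicate sample ids in block '{self.ome_label}': {sorted(dup_s)}")
        if self.sample_windows is not None:
            missing = [s for s in samps if s not in self.sample_windows]
            if missing:
                raise ValueError(
                    f"sample windows missing for samples of block '{self.ome_label}': {missing}"
                )
            for sid, (start, end) in self.sample_windows.items():
                if start > end:
                    raise ValueError(f"sample '{sid}': start_date {start} after end_date {end}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: pd.DataFrame) -> "OmicsBlock":
        """New block with the same metadata and replaced matrix."""
        windows = None
        if self.sample_windows is not None:
            windows = {s: self.sample_windows[s] for s in data.columns}
        return OmicsBlock(
            ome_label=self.ome_label,
            data=data,
            sample_windows=windows,
            feature_annotations=self.feature_annotations,
        )


@dataclass
class AdductTable:
    """Ion adducts relating a measured m/z to a neutral monoisotopic mass.

    Each row is ``(name, mass_shift [Da], charge, polarity)``, e.g.
    ``[M+H]+`` has shift +1.00728 Da, charge +1, polarity ``+``.
    """

    rows: list[tuple[str, float, int, str]]

    def __post_init__(self) -> None:
        names = [r[0] for r in self.rows]
        dup = _duplicates(names)
        if dup:
            raise ValueError(f"duplicate adduct names: {sorted(dup)}")
        for name, _shift, charge, polarity in self.rows:
            if charge == 0:
                raise ValueError(f"adduct '{name}' has charge 0")
            if polarity not in ("+", "-"):
                raise ValueError(f"adduct '{name}' polarity must be '+' or '-', got {polarity!r}")

    def for_polarity(self, polarity: str) -> list[tuple[str, float, int, str]]:
        return [r for r in self.rows if r[3] == polarity]


#: Default adduct table: the common ESI adducts in positive and negative mode.
DEFAULT_ADDUCTS = AdductTable(
    rows=[
        ("[M+H]+", 1.007276, 1, "+"),
        ("[M+Na]+", 22.989218, 1, "+"),
        ("[M+NH4]+", 18.033823, 1, "+"),
        ("[M-H]-", -1.007276, -1, "-"),
        ("[M+CH3COO]-", 59.013851, -1, "-"),
        ("[M+Cl]-", 34.969402, -1, "-"),
    ]
)


@dataclass
class PathwaySet:
    """A named pathway with its member feature identifiers."""

    pathway_id: str
    pathway_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway '{self.pathway_id}' has no members")


@dataclass
class MetabolicNetwork:
    """Undirected metabolite reaction graph with monoisotopic masses.

    ``graph`` is a simple :class:`networkx.Graph`; nodes may carry a
    ``mass`` attribute (Da). Nodes without a known mass stay in the graph
    but are excluded from adduct matching.
    """

    graph: nx.Graph
    masses: dict[str, float] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Total edge count of the network."""
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def nodes_with_mass(self) -> list[str]:
        return [n for n in self.graph.nodes if n in self.masses]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def parse_iso_date(text: str) -> _dt.date:
    """Parse an ISO-8601 calendar date, rejecting any other layout."""
    try:
        return _dt.date.fromisoformat(str(text).strip())
    except ValueError as exc:
        raise ValueError(f"date {text!r} is not ISO-8601 (YYYY-MM-DD)") from exc


def read_sample_windows(path: str) -> dict[str, tuple[_dt.date, _dt.date]]:
    """Read a sample-window metadata table.

    Expects columns ``sample_id``, ``start_date``, ``end_date`` (ISO dates).
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = {"sample_id", "start_date", "end_date"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata file {path} must have columns {sorted(required)}")
    windows: dict[str, tuple[_dt.date, _dt.date]] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in windows:
            raise ValueError(f"metadata file {path}: duplicate sample id '{sid}'")
        windows[sid] = (parse_iso_date(row["start_date"]), parse_iso_date(row["end_date"]))
    return windows


def read_omics_matrix(
    path: str,
    ome_label: str,
    metadata_path: str | None = None,
) -> OmicsBlock:
    """Read a features x samples abundance matrix from TSV/CSV.

    The first column holds feature ids, the header row sample ids.
    Non-numeric cells (including the literal ``NA``) become missing values.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup_f = _duplicates(list(df.index))
    if dup_f:
        raise ValueError(f"{path}: duplicate feature ids: {sorted(dup_f)}")
    dup_s = _duplicates(list(df.columns))
    if dup_s:
        raise ValueError(f"{path}: duplicate sample ids: {sorted(dup_s)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    windows = None
    if metadata_path is not None:
        windows = read_sample_windows(metadata_path)
        missing = [s for s in numeric.columns if s not in windows]
        if missing:
            raise ValueError(
                f"{metadata_path}: no collection window for samples {missing} of {path}"
            )
        windows = {s: windows[s] for s in numeric.columns}
    return OmicsBlock(ome_label=ome_label, data=numeric, sample_windows=windows)


def write_omics_matrix(block: OmicsBlock, path: str) -> None:
    """Write a block back to TSV/CSV with ``NA`` for missing cells."""
    block.data.to_csv(path, sep=_sep_for(path), na_rep=MISSING_TOKEN, index_label="feature_id")


def read_gmt(path: str) -> list[PathwaySet]:
    """Read a GMT pathway file: ``id <TAB> description <TAB> member...``."""
    pathways: list[PathwaySet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            pid, pname = fields[0], fields[1]
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id '{pid}'")
            seen.add(pid)
            members = frozenset(m for m in fields[2:] if m)
            pathways.append(PathwaySet(pathway_id=pid, pathway_name=pname, members=members))
    return pathways


def read_adduct_table(path: str) -> AdductTable:
    """Read an adduct table with columns name, mass_shift, charge, polarity."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"name", "mass_shift", "charge", "polarity"}
    if not required.issubset(df.columns):
        raise ValueError(f"adduct table {path} must have columns {sorted(required)}")
    rows = [
        (str(r["name"]), float(r["mass_shift"]), int(r["charge"]), str(r["polarity"]))
        for _, r in df.iterrows()
    ]
    return AdductTable(rows=rows)


def read_metabolic_network(path: str, masses_path: str | None = None) -> MetabolicNetwork:
    """Read a metabolite-reaction edge list plus a monoisotopic-mass table.

    Self-loops and duplicate edges are dropped (with a logged count).
    Metabolites present in the edge list but absent from the mass table are
    kept in the graph with unknown mass and a warning.
    """
    edges_df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if edges_df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least two columns")
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    for _, row in edges_df.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info("read_metabolic_network: dropped %d self-loops, %d duplicate edges", n_self, n_dup)
    masses: dict[str, float] = {}
    if masses_path is not None:
        mass_df = pd.read_csv(masses_path, sep=_sep_for(masses_path))
        id_col, mass_col = mass_df.columns[0], mass_df.columns[1]
        for _, row in mass_df.iterrows():
            masses[str(row[id_col])] = float(row[mass_col])
        unknown = [n for n in graph.nodes if n not in masses]
        if unknown:
            logger.warning(
                "read_metabolic_network: %d metabolites lack a monoisotopic mass "
                "and are excluded from adduct matching", len(unknown)
            )
    return MetabolicNetwork(graph=graph, masses=masses)


def write_edge_table(network, path: str) -> None:
    """Write a correlation network's edges as a deterministic TSV.

    Columns: source, source_ome, target, target_ome, rho, p, q.
    Rows sorted by (source, target) so a re-run is byte-identical.
    """
    rows = [
        {
            "source": e.source[1],
            "source_ome": e.source[0],
            "target": e.target[1],
            "target_ome": e.target[0],
            "rho": e.rho,
            "p": e.p,
            "q": e.q,
        }
        for e in network.edges
    ]
    df = pd.DataFrame(rows, columns=["source", "source_ome", "target", "target_ome", "rho", "p", "q"])
    if len(df):
        df = df.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(network, path: str) -> None:
    """Export a correlation network to GraphML for external viewers."""
    g = nx.Graph()
    for e in network.edges:
        g.add_node(f"{e.source[0]}:{e.source[1]}", ome=e.source[0], feature=e.source[1])
        g.add_node(f"{e.target[0]}:{e.target[1]}", ome=e.target[0], feature=e.target[1])
        g.add_edge(
            f"{e.source[0]}:{e.source[1]}",
            f"{e.target[0]}:{e.target[1]}",
            rho=float(e.rho),
            p=float(e.p),
            q=float(e.q),
        )
    nx.write_graphml(g, path)
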