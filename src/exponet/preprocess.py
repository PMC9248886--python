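"""Transformations applied before any correlation analysis.

The longitudinal abundance matrices are log2-transformed, filtered on
prevalence (a feature must be observed in more than a configurable
fraction of samples), imputed with a feature-wise K-nearest-neighbour
scheme, and residualized against known covariates (here: two dietary
fiber interventions taken during the sampling period).  Because every
omic layer is collected on its own calendar, blocks are paired sample-to-
sample by overlapping collection windows before any cross-ome analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .core_io import OmicsBlock, logger

#: Dietary fiber intervention periods of the study participant.
FIBER_PERIODS = {
    "arabinoxylan": (_dt.date(2016, 1, 15), _dt.date(2016, 1, 31)),
    "guar_gum": (_dt.date(2016, 2, 22), _dt.date(2016, 3, 17)),
}


@dataclass
class AlignmentMap:
    """One-to-one pairing of samples from two blocks by window overlap.

    ``pairs`` is a list of ``(sample_id_A, sample_id_B, overlap_days)``;
    ``overlap_days`` is 0 when the pairing was made through the gap
    tolerance rather than a true overlap.
    """

    block_a: str
    block_b: str
    pairs: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        a_ids = [p[0] for p in self.pairs]
        b_ids = [p[1] for p in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("alignment map is not one-to-one")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def log2_transform(block: OmicsBlock, pseudocount: float = 1.0) -> OmicsBlock:
    """log2(x + pseudocount) per cell; missing values stay missing.

    Raises on any negative abundance, naming the offending cell.
    """
    values = block.values
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative abundance at feature '{block.feature_ids[i]}', "
            f"sample '{block.sample_ids[j]}' cannot be log2-transformed"
        )
    out = pd.DataFrame(
        np.log2(values + pseudocount), index=block.data.index, columns=block.data.columns
    )
    return block.copy_with(out)


def prevalence_filter(block: OmicsBlock, min_fraction: float = 1.0 / 3.0) -> OmicsBlock:
    """Keep features observed in strictly more than ``min_fraction`` of samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    frac = block.data.notna().sum(axis=1) / block.n_samples
    keep = frac > min_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence_filter(%s): dropped %d/%d features", block.ome_label, dropped, block.n_features)
    return block.copy_with(block.data.loc[keep])


def knn_impute(block: OmicsBlock, k: int = 5) -> OmicsBlock:
    """Impute missing cells from the k nearest features.

    A missing cell (feature f, sample s) is replaced by the mean over the
    k features closest to f in Euclidean distance on their shared observed
    samples.  Features are the KNN rows, so this is the classic
    expression-matrix KNN imputation (not sample-wise).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    data = block.data
    if not data.isna().any().any():
        return block.copy_with(data.copy())
    all_missing = data.index[data.isna().all(axis=1)]
    if len(all_missing):
        raise ValueError(f"cannot impute features with no observed values: {list(all_missing)}")
    n_candidates = block.n_features - 1
    if k > n_candidates:
        raise ValueError(f"k={k} exceeds the {n_candidates} available neighbour features")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(data.to_numpy(dtype=float))
    return block.copy_with(pd.DataFrame(filled, index=data.index, columns=data.columns))


def fiber_covariates(block: OmicsBlock) -> pd.DataFrame:
    """Binary fiber-intake indicators per sample, from collection windows.

    A sample is flagged for a fiber period when its collection window
    overlaps the dosing period by at least one day.
    """
    if block.sample_windows is None:
        raise ValueError("block carries no sample collection windows")
    rows = {}
    for sid in block.sample_ids:
        start, end = block.sample_windows[sid]
        rows[sid] = {
            name: float(start <= p_end and end >= p_start)
            for name, (p_start, p_end) in FIBER_PERIODS.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[block.sample_ids]


def residualize(block: OmicsBlock, covariates: pd.DataFrame) -> OmicsBlock:
    """Remove covariate effects per feature by OLS; preserve feature means.

    Covariates are centered before fitting so the intercept estimate is the
    feature mean; the returned matrix is residuals + feature mean.
    Constant covariate columns carry no information beyond the intercept
    and are dropped; the remaining design must be full rank.
    """
    missing = [s for s in block.sample_ids if s not in covariates.index]
    if missing:
        raise ValueError(f"covariate table lacks samples: {missing}")
    C = covariates.loc[block.sample_ids].to_numpy(dtype=float)
    keep = C.std(axis=0) > 0
    C = C[:, keep]
    if C.shape[1] == 0:
        return block.copy_with(block.data.copy())
    C = C - C.mean(axis=0)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    Y = block.values.T  # samples x features
    if np.isnan(Y).any():
        raise ValueError("residualize requires a complete matrix; impute first")
    beta, *_ = np.linalg.lstsq(C, Y - Y.mean(axis=0), rcond=None)
    resid = (Y - Y.mean(axis=0)) - C @ beta
    out = (resid + Y.mean(axis=0)).T
    return block.copy_with(pd.DataFrame(out, index=block.data.index, columns=block.data.columns))


def _overlap_days(a: tuple[_dt.date, _dt.date], b: tuple[_dt.date, _dt.date]) -> int:
    """Calendar days (inclusive) shared by two windows; <=0 means disjoint."""
    start = max(a[0], b[0])
    end = min(a[1], b[1])
    return (end - start).days + 1


def _gap_days(a: tuple[_dt.date, _dt.date], b: tuple[_dt.date, _dt.date]) -> int:
    if a[0] > b[1]:
        return (a[0] - b[1]).days
    if b[0] > a[1]:
        return (b[0] - a[1]).days
    return 0


def align_blocks(block_a: OmicsBlock, block_b: OmicsBlock, tolerance_days: int = 2) -> AlignmentMap:
    """Pair samples of two blocks whose collection windows overlap.

    Candidate pairs overlap by >= 1 day, or lie within ``tolerance_days``
    of each other.  A greedy matching ordered by (overlap desc, gap asc,
    earliest B start, earliest A start) yields a deterministic one-to-one
    map; ties that never fire leave the matching symmetric in A and B.
    """
    if block_a.sample_windows is None or block_b.sample_windows is None:
        raise ValueError("both blocks must carry sample collection windows")
    candidates = []
    for sa in block_a.sample_ids:
        wa = block_a.sample_windows[sa]
        for sb in block_b.sample_ids:
            wb = block_b.sample_windows[sb]
            ov = _overlap_days(wa, wb)
            if ov >= 1:
                candidates.append((-ov, 0, wb[0], wa[0], sa, sb, ov))
            else:
                gap = _gap_days(wa, wb)
                if gap <= tolerance_days:
                    candidates.append((0, gap, wb[0], wa[0], sa, sb, 0))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3], c[4], c[5]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str, int]] = []
    for _negov, _gap, _bstart, _astart, sa, sb, ov in candidates:
        if sa in used_a or sb in used_b:
            continue
        used_a.add(sa)
        used_b.add(sb)
        pairs.append((sa, sb, ov))
    if not pairs:
        raise ValueError(
            "no sample windows overlap between blocks "
            f"'{block_a.ome_label}' and '{block_b.ome_label}'; increase tolerance_days"
        )
    pairs.sort(key=lambda p: (p[0], p[1]))
    return AlignmentMap(block_a=block_a.ome_label, block_b=block_b.ome_label, pairs=pairs)
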