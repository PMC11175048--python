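"""Kennard-Stone sample selection: calibration/validation splitting and the
EPO training-subset choice.

Kennard-Stone picks, deterministically, a subset that covers the feature
space: the first two picks are the most distant pair, every later pick
maximizes its minimum distance to the points already chosen.  Ties break to
the lexicographically smallest sample id, so the output is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .datatypes import SpectraSet


@dataclass
class SplitPlan:
    """Calibration/validation partition plus the EPO training subset.

    Invariants: calibration and validation are disjoint and jointly cover
    all ids; ``epo_ids`` is a subset of the calibration side.
    """

    calibration_ids: list[str]
    validation_ids: list[str]
    epo_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cal, val = set(self.calibration_ids), set(self.validation_ids)
        if cal & val:
            raise ValueError("calibration and validation sets overlap")
        if set(self.epo_ids) - cal:
            raise ValueError("epo_ids must be drawn from the calibration set")

    @property
    def all_ids(self) -> list[str]:
        return list(self.calibration_ids) + list(self.validation_ids)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "calibration_ids": list(self.calibration_ids),
                    "validation_ids": list(self.validation_ids),
                    "epo_ids": list(self.epo_ids),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def kennard_stone(
    features: np.ndarray,
    ids: np.ndarray,
    n_select: int,
    preselected: list[str] | None = None,
) -> list[str]:
    """Ordered Kennard-Stone selection of ``n_select`` sample ids.

    ``preselected`` ids (if given) are taken as the already-chosen seed set
    and the max-min rule continues from them.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    ids = np.asarray(ids, dtype=object)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_select < 2:
        raise ValueError("n_select must be >= 2")
    if n_select > n:
        raise ValueError("n_select exceeds the number of samples")
    d2 = _pairwise_sq_dists(X)
    id_order = np.argsort(ids.astype(str))  # for lexicographic tie-breaks
    rank = np.empty(n, dtype=int)
    rank[id_order] = np.arange(n)

    if preselected:
        lookup = {sid: i for i, sid in enumerate(ids)}
        chosen = [lookup[s] for s in preselected]
    else:
        # most distant pair; ties -> lexicographically smallest id pair
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = (i, j) if rank[i] < rank[j] else (j, i)
                key = (-d2[i, j], rank[a], rank[b])
                if best is None or key < best[0]:
                    best = (key, [a, b])
        chosen = best[1]
    chosen = chosen[:n_select]
    remaining = [i for i in range(n) if i not in set(chosen)]
    min_d2 = (
        np.min(d2[np.ix_(remaining, chosen)], axis=1)
        if remaining
        else np.empty(0)
    )
    while len(chosen) < n_select:
        # max-min pick; tie -> smallest id
        keys = [(-min_d2[k], rank[i]) for k, i in enumerate(remaining)]
        k_best = min(range(len(remaining)), key=keys.__getitem__)
        pick = remaining.pop(k_best)
        min_d2 = np.delete(min_d2, k_best)
        chosen.append(pick)
        if remaining:
            min_d2 = np.minimum(min_d2, d2[remaining, pick])
    return [ids[i] for i in chosen]


def make_split(spectra: SpectraSet, ratio: float = 0.70) -> SplitPlan:
    """Kennard-Stone calibration/validation split on a processed spectra set
    (one row per sample).  ``ceil(ratio * n)`` samples go to calibration;
    the same id split is reused for every treatment of the instrument."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    n = spectra.n_spectra
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    n_cal = int(np.ceil(ratio * n))
    cal = kennard_stone(spectra.values, spectra.ids, n_cal)
    cal_set = set(cal)
    val = [sid for sid in spectra.ids if sid not in cal_set]
    return SplitPlan(calibration_ids=cal, validation_ids=val)


def select_epo_subset(
    reference: pd.DataFrame,
    calibration_ids: list[str],
    n: int = 10,
) -> list[str]:
    """Choose the samples the EPO difference matrix is built from.

    Selection runs in the 2-D space of min-max-normalized (SOC, clay),
    restricted to the calibration side.  The four per-variable extremes are
    seeded first (deduplicated, deterministic order: min/max SOC, min/max
    clay) so the subset is guaranteed to span the full SOC and clay range;
    Kennard-Stone max-min picks fill the rest.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if n > len(calibration_ids):
        raise ValueError("n exceeds the calibration set size")
    sub = reference.loc[reference["sample_id"].isin(calibration_ids)]
    sub = sub.set_index("sample_id").loc[list(calibration_ids)].reset_index()
    X = sub[["soc", "clay"]].to_numpy(dtype=float)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = (X - X.min(axis=0)) / span
    ids = sub["sample_id"].to_numpy(dtype=object)

    seeds: list[str] = []
    for col, reducer in ((0, np.argmin), (0, np.argmax), (1, np.argmin), (1, np.argmax)):
        target = X[:, col].min() if reducer is np.argmin else X[:, col].max()
        tied = ids[X[:, col] == target]
        pick = sorted(tied.astype(str))[0]
        if pick not in seeds:
            seeds.append(pick)
    seeds = seeds[:n]
    if len(seeds) >= n:
        return seeds
    return kennard_stone(Xn, ids, n, preselected=seeds)
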