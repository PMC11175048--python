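"""External parameter orthogonalization (EPO).

EPO removes an unwanted source of spectral variation (here: soil moisture)
by projecting spectra onto the orthogonal complement of the subspace that
the unwanted factor spans.  The decomposition is

    X = X P + X Q + R,        X* = X P = X (I - Q),

where Q projects onto the unwanted subspace and P = I - Q onto the useful
one.  The unwanted subspace is estimated from the difference matrix D of
matched moist-minus-dry spectra: its first ``g`` right singular vectors
V_g (D taken raw, uncentred - every row is already a difference) give
Q = V_g V_g^T.

The factor count ``g`` is chosen by maximizing Wilk's lambda between the
corrected moist and corrected dry groups: lambda near 1 means the groups
are no longer separable, i.e. the moisture effect is gone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .datatypes import SpectraSet
from .exceptions import ExcessFactorsError, GridMismatchError

#: tolerance within which two lambda values count as tied (smaller g wins).
LAMBDA_TIE_TOL = 1e-9

#: ridge added to both scatter determinants for numerical safety.
SCATTER_RIDGE = 1e-10


@dataclass
class DifferenceMatrix:
    """Matched moist-minus-dry spectral differences (rows = EPO subset)."""

    values: np.ndarray
    grid: np.ndarray
    pairing: str  # moist_minus_sieved | moist_minus_fine
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference matrix contains non-finite entries")
        if self.values.shape[1] != len(self.grid):
            raise ValueError("difference matrix width != grid length")
        if self.ids and len(self.ids) != self.values.shape[0]:
            raise ValueError("id list length != row count")


@dataclass
class EPOModel:
    """Fitted EPO correction.

    ``V`` holds the first ``g`` right singular vectors of D as columns
    (p x g); the projection matrices are derived on demand as Q = V V^T and
    P = I - Q, so only the compact basis is stored and serialized.
    """

    grid: np.ndarray
    g: int
    V: np.ndarray  # p x g orthonormal basis of the unwanted subspace
    pairing: str = ""
    lambda_trace: dict = field(default_factory=dict)
    residual_norm: float = 0.0

    @property
    def Q(self) -> np.ndarray:
        if self.g == 0:
            p = len(self.grid)
            return np.zeros((p, p))
        return self.V @ self.V.T

    @property
    def P(self) -> np.ndarray:
        return np.eye(len(self.grid)) - self.Q

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "grid": self.grid.tolist(),
                    "g": int(self.g),
                    "pairing": self.pairing,
                    "lambda_trace": {str(k): float(v) for k, v in self.lambda_trace.items()},
                    "V": self.V.tolist(),
                    "residual_norm": float(self.residual_norm),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "EPOModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            grid=np.asarray(payload["grid"], dtype=float),
            g=int(payload["g"]),
            V=np.asarray(payload["V"], dtype=float).reshape(len(payload["grid"]), -1),
            pairing=payload.get("pairing", ""),
            lambda_trace={int(k): v for k, v in payload.get("lambda_trace", {}).items()},
            residual_norm=payload.get("residual_norm", 0.0),
        )


def difference_matrix(
    moist: SpectraSet,
    dry: SpectraSet,
    epo_ids: list[str],
    pairing: str = "moist_minus_sieved",
) -> DifferenceMatrix:
    """Row i = moist spectrum - dry spectrum of epo_ids[i]."""
    moist.require_same_grid(dry)
    m = moist.reorder_by_ids(epo_ids)
    d = dry.reorder_by_ids(epo_ids)
    return DifferenceMatrix(
        values=m.values - d.values,
        grid=moist.grid.copy(),
        pairing=pairing,
        ids=list(epo_ids),
    )


def fit_epo(D: DifferenceMatrix, g: int) -> EPOModel:
    """Fit the projection from the first ``g`` right singular vectors of D
    (raw, uncentred).  ``g = 0`` yields the identity correction."""
    n, p = D.values.shape
    if g < 0 or g > min(n, p):
        raise ExcessFactorsError(
            f"g={g} outside [0, {min(n, p)}] for a {n}x{p} difference matrix"
        )
    if g == 0:
        V = np.zeros((p, 0))
        residual = float(np.linalg.norm(D.values))
    else:
        _, s, Vt = np.linalg.svd(D.values, full_matrices=False)
        if s[g - 1] <= 1e-12 * max(s[0], 1e-300):
            raise ExcessFactorsError(
                f"g={g} exceeds the numerical rank of the difference matrix"
            )
        V = Vt[:g].T
        corrected = D.values - (D.values @ V) @ V.T
        residual = float(np.linalg.norm(corrected))
    return EPOModel(grid=D.grid.copy(), g=g, V=V, pairing=D.pairing,
                    residual_norm=residual)


def apply_epo(spectra: SpectraSet, model: EPOModel) -> SpectraSet:
    """Multiply every spectrum by P = I - V V^T (metadata preserved)."""
    if len(spectra.grid) != len(model.grid) or not np.allclose(
        spectra.grid, model.grid, atol=1e-9
    ):
        raise GridMismatchError("spectra grid does not match the EPO model grid")
    if model.g == 0:
        return spectra.with_values(spectra.values.copy())
    corrected = spectra.values - (spectra.values @ model.V) @ model.V.T
    return spectra.with_values(corrected)


def wilks_lambda(
    corrected_moist: np.ndarray,
    corrected_dry: np.ndarray,
    k_scores: int = 5,
) -> float:
    """Wilk's lambda between two spectra groups on pooled-PCA scores.

    Both groups are pooled, column-centred, and projected onto the first
    ``k_scores`` principal-component scores; lambda = det(W) / det(W + B)
    with W the within-group and B the between-group scatter (a small ridge
    stabilizes both determinants).  lambda in (0, 1]; 1 means the groups are
    indistinguishable.
    """
    A = np.atleast_2d(np.asarray(corrected_moist, dtype=float))
    Bm = np.atleast_2d(np.asarray(corrected_dry, dtype=float))
    if A.shape[0] < 2 or Bm.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows")
    pooled = np.vstack([A, Bm])
    n_total = pooled.shape[0]
    if k_scores > min(n_total - 2, pooled.shape[1]):
        raise ValueError("k_scores too large for the pooled matrix")
    centred = pooled - pooled.mean(axis=0)
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = U[:, :k_scores] * s[:k_scores]
    grand = scores.mean(axis=0)
    W = np.zeros((k_scores, k_scores))
    B = np.zeros((k_scores, k_scores))
    for grp in (scores[: A.shape[0]], scores[A.shape[0]:]):
        mu = grp.mean(axis=0)
        dev = grp - mu
        W += dev.T @ dev
        gap = (mu - grand)[:, None]
        B += grp.shape[0] * (gap @ gap.T)
    ridge = SCATTER_RIDGE * np.eye(k_scores)
    sign_w, logdet_w = np.linalg.slogdet(W + ridge)
    sign_t, logdet_t = np.linalg.slogdet(W + B + ridge)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("scatter matrices are not positive definite")
    return float(min(np.exp(logdet_w - logdet_t), 1.0))


def select_factors(
    moist: SpectraSet,
    dry: SpectraSet,
    epo_ids: list[str],
    g_max: int = 10,
    k_scores: int = 5,
    pairing: str = "moist_minus_sieved",
) -> EPOModel:
    """Scan g = 0..g_max, correcting both groups and scoring the separation
    with Wilk's lambda; return the model at the maximum (ties within
    ``LAMBDA_TIE_TOL`` go to the smallest g)."""
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    D = difference_matrix(moist, dry, epo_ids, pairing)
    m = moist.reorder_by_ids(epo_ids)
    d = dry.reorder_by_ids(epo_ids)
    _, s, _ = np.linalg.svd(D.values, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * max(s[0], 1e-300)))
    g_hi = min(g_max, rank)
    k_eff = min(k_scores, m.n_spectra + d.n_spectra - 2, len(moist.grid))
    trace: dict[int, float] = {}
    models: dict[int, EPOModel] = {}
    for g in range(0, g_hi + 1):
        model = fit_epo(D, g)
        cm = apply_epo(m, model).values
        cd = apply_epo(d, model).values
        trace[g] = wilks_lambda(cm, cd, k_eff)
        models[g] = model
    best_lambda = max(trace.values())
    g_star = min(g for g, lam in trace.items() if lam >= best_lambda - LAMBDA_TIE_TOL)
    chosen = models[g_star]
    chosen.lambda_trace = trace
    return chosen
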