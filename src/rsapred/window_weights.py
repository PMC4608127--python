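"""Least-squares model of a residue's RSA as a function of its window neighbours.

Fitting RSA_i ~ b + sum_k w_k * RSA_{i+k} over all residues with a complete
window quantifies how strongly each neighbour position influences the
central residue; the fitted coefficients drive the weighted sliding-window
feature scheme. Residues whose window crosses a chain end are excluded from
the design (no pseudo padding in the regression).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, SingularFitError


def _offsets(n: int) -> list[int]:
    half = (n - 1) // 2
    return [k for k in range(-half, half + 1) if k != 0]


@dataclass
class WindowWeights:
    """Fitted neighbour coefficients w_k (k = -half..-1, +1..+half) + intercept."""

    window: int
    coefficients: np.ndarray
    intercept: float
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError(f"window must be odd and >= 3, got {self.window}")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.window - 1,):
            raise ConfigurationError(
                f"expected {self.window - 1} coefficients, got {self.coefficients.shape}"
            )

    @property
    def offsets(self) -> list[int]:
        return _offsets(self.window)

    def to_json(self) -> str:
        return json.dumps(
            {
                "window": self.window,
                "offsets": self.offsets,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "fit_stats": self.fit_stats,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "WindowWeights":
        doc = json.loads(text)
        return cls(
            window=doc["window"],
            coefficients=np.array(doc["coefficients"], dtype=float),
            intercept=doc["intercept"],
            fit_stats=doc.get("fit_stats", {}),
        )


def build_neighbor_design(rsa_tracks, n: int):
    """Stack (neighbours, centre) rows for every residue with a complete window.

    ``rsa_tracks`` is an iterable of per-chain RSA arrays. Columns are ordered
    by offset -half..-1, +1..+half; y holds the central RSA. Chains shorter
    than the window contribute nothing; if all are too short an
    :class:`InsufficientDataError` is raised.
    """
    if n < 3 or n % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 3, got {n}")
    half = (n - 1) // 2
    offs = _offsets(n)
    x_rows, y_rows = [], []
    for track in rsa_tracks:
        arr = np.asarray(track, dtype=float)
        L = arr.shape[0]
        if L < n:
            continue
        centres = np.arange(half, L - half)
        x_rows.append(np.stack([arr[centres + k] for k in offs], axis=1))
        y_rows.append(arr[centres])
    if not x_rows:
        raise InsufficientDataError(f"no chain is long enough for window {n}")
    return np.concatenate(x_rows), np.concatenate(y_rows)


def fit_window_weights(rsa_tracks, n: int) -> WindowWeights:
    """Ordinary least squares for the neighbour coefficients and intercept.

    Raises :class:`SingularFitError` when the design is rank deficient (e.g.
    constant RSA everywhere) and :class:`InsufficientDataError` when there are
    no more rows than parameters.
    """
    X, y = build_neighbor_design(rsa_tracks, n)
    M, p = X.shape
    if M <= p + 1:
        raise InsufficientDataError(
            f"{M} design rows are too few to fit {p + 1} parameters"
        )
    A = np.column_stack([X, np.ones(M)])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        raise SingularFitError("rank-deficient neighbour design (constant RSA?)")
    residuals = y - A @ coef
    stats = {
        "n_samples": int(M),
        "residual_variance": float(np.var(residuals, ddof=p + 1)),
    }
    return WindowWeights(
        window=n, coefficients=coef[:p], intercept=float(coef[p]), fit_stats=stats
    )


def predict_rsa_linear(weights: WindowWeights, neighbor_rsa_values) -> float:
    """dot(w, neighbours) + intercept for one window, neighbours ordered as fit."""
    vec = np.asarray(neighbor_rsa_values, dtype=float)
    if vec.shape != (weights.window - 1,):
        raise ConfigurationError(
            f"expected {weights.window - 1} neighbour values, got {vec.shape}"
        )
    return float(vec @ weights.coefficients + weights.intercept)


def weight_profile_report(weights: WindowWeights) -> dict:
    """Tabulate (offset, coefficient) plus symmetry and monotonicity diagnostics.

    symmetry_score is max_k |w_k - w_{-k}|; monotone_toward_center reports
    whether coefficient magnitude increases toward the centre on each side.
    """
    half = (weights.window - 1) // 2
    table = list(zip(weights.offsets, weights.coefficients.tolist()))
    by_offset = dict(table)
    symmetry = max(abs(by_offset[k] - by_offset[-k]) for k in range(1, half + 1))
    left = [abs(by_offset[-k]) for k in range(half, 0, -1)]  # -half .. -1
    right = [abs(by_offset[k]) for k in range(1, half + 1)]  # +1 .. +half
    monotone = all(np.diff(left) >= 0) and all(np.diff(right) <= 0)
    return {
        "table": table,
        "symmetry_score": float(symmetry),
        "monotone_toward_center": bool(monotone),
    }
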