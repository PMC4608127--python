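"""Scoring of predicted against true RSA.

Metrics operate on percent-scale RSA unless noted: mean absolute error
(MAE), Pearson correlation (PCC), two-state buried/exposed accuracy at a
threshold, per-residue-type summaries and an absolute-error histogram.

The default MAE is the plain mean |x - y| on the percent scale — the
quantity this field's predictors report (headline values around 14%). A
"relative" mode, mean |x - y| / x with zero-RSA positions skipped, is also
provided since some formulations divide by the true value; it diverges for
buried residues and is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedCorrelationError

DEFAULT_THRESHOLDS = (5, 10, 20, 25, 30, 40, 50, 60, 70, 80, 90)
DEFAULT_BAND_EDGES = tuple(range(0, 101, 10))


def _pair(true_rsa, pred_rsa):
    x = np.asarray(true_rsa, dtype=float)
    y = np.asarray(pred_rsa, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError(f"mismatched metric inputs {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ConfigurationError("empty metric input")
    return x, y


def mae(true_rsa, pred_rsa, mode: str = "absolute") -> float:
    """Mean absolute deviation between true and predicted RSA.

    mode 'absolute': mean |x - y|. mode 'relative': mean |x - y| / x, skipping
    positions with x == 0 (a warning reports how many were skipped).
    """
    x, y = _pair(true_rsa, pred_rsa)
    if mode == "absolute":
        return float(np.mean(np.abs(x - y)))
    if mode == "relative":
        keep = x != 0
        skipped = int(np.sum(~keep))
        if skipped:
            warnings.warn(
                f"relative MAE skipped {skipped} position(s) with zero true RSA",
                stacklevel=2,
            )
        if not np.any(keep):
            raise ConfigurationError("relative MAE undefined: all true values are zero")
        return float(np.mean(np.abs(x[keep] - y[keep]) / x[keep]))
    raise ConfigurationError(f"unknown MAE mode {mode!r}")


def pcc(true_rsa, pred_rsa) -> float:
    """Pearson correlation coefficient; +1/-1 for perfect (anti)correlation."""
    x, y = _pair(true_rsa, pred_rsa)
    if x.size < 2:
        raise ConfigurationError("PCC needs at least two points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("PCC undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def two_state_accuracy(true_rsa, pred_rsa, threshold: float) -> float:
    """Percent of residues whose buried/exposed state is predicted correctly.

    A residue is exposed when its RSA (percent scale) is no less than the
    threshold; the same rule binarises truth and prediction.
    """
    if not 0 < threshold < 100:
        raise ConfigurationError(f"threshold must be in (0,100), got {threshold}")
    x, y = _pair(true_rsa, pred_rsa)
    return float(np.mean((x >= threshold) == (y >= threshold)) * 100.0)


def per_type_summary(chains, predictions) -> tuple[pd.DataFrame, float]:
    """Residue-type table of mean RSA, prediction error and RSA variability.

    ``chains`` provide sequences and true RSA tracks; ``predictions`` is a
    parallel list of predicted percent-scale arrays. Returns a DataFrame
    indexed by amino-acid letter with columns (true_mean, pred_mean, mae,
    true_std) on the percent scale, plus the Pearson correlation between
    per-type error and per-type RSA standard deviation. Letters with no
    residues are omitted with a warning.
    """
    if len(chains) != len(predictions):
        raise ConfigurationError("one prediction track per chain required")
    letters, truths, preds = [], [], []
    for chain, pred in zip(chains, predictions):
        pred = np.asarray(pred, dtype=float)
        if chain.rsa is None:
            raise ConfigurationError(f"chain {chain.chain_id} has no true RSA")
        if pred.shape[0] != chain.length:
            raise ConfigurationError(f"chain {chain.chain_id}: prediction length mismatch")
        letters.extend(chain.sequence)
        truths.append(chain.rsa.as_percent())
        preds.append(pred)
    letters = np.array(letters)
    truth = np.concatenate(truths)
    pred = np.concatenate(preds)
    rows = {}
    from .io_formats import AA_ALPHABET

    for aa in AA_ALPHABET:
        mask = letters == aa
        if not np.any(mask):
            warnings.warn(f"no residues of type {aa}; row omitted", stacklevel=2)
            continue
        rows[aa] = {
            "true_mean": float(np.mean(truth[mask])),
            "pred_mean": float(np.mean(pred[mask])),
            "mae": float(np.mean(np.abs(truth[mask] - pred[mask]))),
            "true_std": float(np.std(truth[mask])),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    try:
        corr = pcc(table["mae"].to_numpy(), table["true_std"].to_numpy())
    except (UndefinedCorrelationError, ConfigurationError):
        corr = float("nan")  # degenerate: constant errors or a single type
    return table, corr


def error_band_histogram(true_rsa, pred_rsa, band_edges=DEFAULT_BAND_EDGES) -> np.ndarray:
    """Residue counts per absolute-error interval (percent scale).

    Edges must be strictly increasing and cover [0, 100]; the final bin is
    closed on the right, so the counts always sum to the residue count.
    """
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigurationError("band edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 100:
        raise ConfigurationError("band edges must cover [0, 100]")
    x, y = _pair(true_rsa, pred_rsa)
    counts, _ = np.histogram(np.abs(x - y), bins=edges)
    return counts


@dataclass
class EvalReport:
    """Bundle of all evaluation outputs for one prediction run."""

    mae: float
    pcc: float
    two_state: dict = field(default_factory=dict)
    per_type: pd.DataFrame | None = None
    error_std_correlation: float | None = None
    error_bands: np.ndarray | None = None
    band_edges: tuple = DEFAULT_BAND_EDGES
    n_residues: int = 0

    def to_dict(self) -> dict:
        doc = {
            "mae_percent": self.mae,
            "pcc": self.pcc,
            "two_state_accuracy_percent": {str(k): v for k, v in self.two_state.items()},
            "n_residues": self.n_residues,
        }
        if self.per_type is not None:
            doc["per_type"] = self.per_type.to_dict(orient="index")
            doc["error_std_correlation"] = self.error_std_correlation
        if self.error_bands is not None:
            doc["error_bands"] = {
                f"{int(self.band_edges[i])}-{int(self.band_edges[i + 1])}": int(c)
                for i, c in enumerate(self.error_bands)
            }
        return doc


def evaluate(chains, predictions, thresholds=DEFAULT_THRESHOLDS) -> EvalReport:
    """Full report over pooled residues of all chains (percent scale).

    ``predictions`` are per-chain fraction- or percent-scale arrays matching
    each chain's RSA track unit; both are pooled on the percent scale.
    """
    truths, preds = [], []
    for chain, pred in zip(chains, predictions):
        truths.append(chain.rsa.as_percent())
        pred = np.asarray(pred, dtype=float)
        if chain.rsa.unit_scale == "fraction":
            pred = pred * 100.0
        preds.append(pred)
    truth = np.concatenate(truths)
    pred = np.concatenate(preds)
    table, corr = per_type_summary(
        chains, [p if c.rsa.unit_scale == "percent" else p * 100 for c, p in zip(chains, predictions)]
    )
    return EvalReport(
        mae=mae(truth, pred),
        pcc=pcc(truth, pred),
        two_state={t: two_state_accuracy(truth, pred, t) for t in thresholds},
        per_type=table,
        error_std_correlation=corr,
        error_bands=error_band_histogram(truth, pred),
        n_residues=int(truth.size),
    )
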