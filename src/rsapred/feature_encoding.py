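"""Per-residue feature construction from the five sequence-derived sources.

Each residue i is represented by a sliding window of N positions centred on
it. The full layout concatenates, in order:

==============  =====  =============================================
block           width  content per window position / chain
==============  =====  =============================================
pssm_window     21N    20 logistic-normalised PSSM scores + terminal flag
ss_local        3N     (C,H,E) secondary-structure probabilities
ss_global       6      chain-level SS content and segment fractions
disorder        3N     (p_disorder, p_order, state)
seq_len         1      chain length / 1000
seq_pos         1      triangular distance-from-terminus feature
physchem        6N     six normalised physicochemical propensities
==============  =====  =============================================

giving D = 33N + 8 columns. Window positions outside the chain are pseudo
residues: their windowed features are all zero except the PSSM terminal
flag, which is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError, MissingInputError
from .io_formats import AA_ALPHABET, ChainRecord

SCALE_NAMES = (
    "hydrophilicity",
    "flexibility",
    "accessibility",
    "polarity",
    "exposed_surface",
    "turns",
)

ALL_BLOCKS = (
    "pssm_window",
    "ss_local",
    "ss_global",
    "disorder",
    "seq_len",
    "seq_pos",
    "physchem",
)

#: Blocks that are windowed (width divisible by N) and eligible for weighting.
WINDOWED_BLOCKS = ("pssm_window", "ss_local", "disorder", "physchem")


@dataclass(frozen=True)
class WindowSpec:
    """Odd-length sliding window centred on the target residue."""

    n: int = 9

    def __post_init__(self) -> None:
        if self.n < 1 or self.n % 2 == 0:
            raise ConfigurationError(f"window length must be odd and >= 1, got {self.n}")

    @property
    def half(self) -> int:
        return (self.n - 1) // 2

    @property
    def offsets(self) -> range:
        return range(-self.half, self.half + 1)


class PhysChemScales:
    """Six amino-acid propensity scales, min-max normalised to [0, 1].

    X maps to each scale's mean (over the 20 standard letters, after
    normalisation).
    """

    def __init__(self, raw: dict):
        missing = set(SCALE_NAMES) - set(raw)
        if missing:
            raise ConfigurationError(f"scale file missing scales {sorted(missing)}")
        self.normalized: dict[str, dict[str, float]] = {}
        for name in SCALE_NAMES:
            table = {k: float(v) for k, v in raw[name].items()}
            absent = set(AA_ALPHABET) - set(table)
            if absent:
                raise ConfigurationError(f"scale {name!r} missing letters {sorted(absent)}")
            vals = np.array([table[a] for a in AA_ALPHABET])
            lo, hi = vals.min(), vals.max()
            if hi == lo:
                raise ConfigurationError(f"scale {name!r} is constant")
            norm = {a: (table[a] - lo) / (hi - lo) for a in AA_ALPHABET}
            norm["X"] = float(np.mean(list(norm.values())))
            self.normalized[name] = norm
        # per-letter vector cache in SCALE_NAMES order
        self._vectors = {
            a: np.array([self.normalized[s][a] for s in SCALE_NAMES])
            for a in AA_ALPHABET + "X"
        }

    def vector(self, letter: str) -> np.ndarray:
        """The six normalised values for one residue letter (order SCALE_NAMES)."""
        try:
            return self._vectors[letter]
        except KeyError:
            raise ConfigurationError(f"no physicochemical values for {letter!r}") from None


def load_physchem_scales(path: Optional[str] = None) -> PhysChemScales:
    """Load the scale set; default is the packaged classical six-scale file."""
    if path is None:
        text = resources.files("rsapred.data").joinpath("physchem_scales.yaml").read_text()
    else:
        text = Path(path).read_text()
    return PhysChemScales(yaml.safe_load(text))


@dataclass
class FeatureMatrix:
    """L x D matrix with a named block layout (list of (name, width))."""

    values: np.ndarray
    layout: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        """View of one named block's columns."""
        start = 0
        for bname, bwidth in self.layout:
            if bname == name:
                return self.values[:, start : start + bwidth]
            start += bwidth
        raise ConfigurationError(f"no block named {name!r}")

    def column_names(self) -> list[str]:
        names = []
        for bname, bwidth in self.layout:
            names.extend(f"{bname}[{j}]" for j in range(bwidth))
        return names


def logistic_normalize(x):
    """Standard logistic squashing of raw PSSM scores into (0, 1)."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError("logistic_normalize requires finite input")
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _require(profile, chain: ChainRecord, what: str):
    if profile is None:
        raise MissingInputError(f"chain {chain.chain_id}: {what} profile is missing")
    return profile


def encode_pssm_window(
    chain: ChainRecord,
    i: int,
    spec: WindowSpec,
    flag_real_terminals: bool = False,
) -> np.ndarray:
    """(20+1)-wide sub-block per window position: normalised PSSM + terminal flag.

    Pseudo positions (outside the chain) emit literal zeros for the 20
    evolutionary values — bypassing the logistic, which would map a zero raw
    score to 0.5 — and a terminal flag of 1. Real residues carry flag 0 unless
    ``flag_real_terminals`` also marks the chain's first and last residue.
    """
    pssm = _require(chain.pssm, chain, "PSSM")
    L = chain.length
    out = np.zeros(21 * spec.n)
    for w, k in enumerate(spec.offsets):
        j = i + k
        base = 21 * w
        if 0 <= j < L:
            out[base : base + 20] = logistic_normalize(pssm.scores[j])
            if flag_real_terminals and (j == 0 or j == L - 1):
                out[base + 20] = 1.0
        else:
            out[base + 20] = 1.0  # pseudo terminal residue
    return out


def encode_ss_local(chain: ChainRecord, i: int, spec: WindowSpec) -> np.ndarray:
    """(C,H,E) probability triple per window position; pseudo positions are zero."""
    ss3 = _require(chain.ss3, chain, "secondary-structure")
    out = np.zeros(3 * spec.n)
    for w, k in enumerate(spec.offsets):
        j = i + k
        if 0 <= j < chain.length:
            out[3 * w : 3 * w + 3] = ss3.probs[j]
    return out


def _replace_short_helices(states: str, max_len: int = 2) -> str:
    """Rewrite maximal H-runs of length <= max_len to C (too short for a helix)."""
    out = list(states)
    i = 0
    while i < len(states):
        if states[i] == "H":
            j = i
            while j < len(states) and states[j] == "H":
                j += 1
            if j - i <= max_len:
                out[i:j] = "C" * (j - i)
            i = j
        else:
            i += 1
    return "".join(out)


def _count_runs(states: str) -> dict[str, int]:
    counts = {"H": 0, "E": 0, "C": 0}
    prev = None
    for s in states:
        if s != prev:
            counts[s] += 1
        prev = s
    return counts


def encode_ss_global(chain: ChainRecord) -> np.ndarray:
    """Six chain-level features: SS content fractions and segment fractions.

    Content uses the raw state string. For segment counting, H-runs of length
    one or two are first rewritten to coil (they cannot form a helix segment);
    E and C runs are never rewritten. Each (H, E, C) triple sums to 1.
    """
    ss3 = _require(chain.ss3, chain, "secondary-structure")
    states = ss3.states
    L = len(states)
    content = np.array([states.count(a) / L for a in "HEC"])
    runs = _count_runs(_replace_short_helices(states))
    total = sum(runs.values())
    assert total > 0  # every residue of a non-empty chain belongs to some run
    segment = np.array([runs[a] / total for a in "HEC"])
    return np.concatenate([content, segment])


def encode_disorder_window(chain: ChainRecord, i: int, spec: WindowSpec) -> np.ndarray:
    """(p_disorder, p_order, state) per window position; pseudo positions zero."""
    dis = _require(chain.disorder, chain, "disorder")
    out = np.zeros(3 * spec.n)
    for w, k in enumerate(spec.offsets):
        j = i + k
        if 0 <= j < chain.length:
            out[3 * w : 3 * w + 3] = (dis.p_disorder[j], dis.p_order[j], dis.state[j])
    return out


def encode_sequence_features(chain: ChainRecord, i: int) -> np.ndarray:
    """(length/1000, position) with the triangular position feature.

    position = 1 − |i₁ − (L+1)/2| / (L/2) for the 1-based index i₁: 1 at the
    chain centre, approaching 0 at the termini.
    """
    L = chain.length
    if not 0 <= i < L:
        raise ConfigurationError(f"residue index {i} out of range for length {L}")
    i1 = i + 1
    position = 1.0 - abs(i1 - (L + 1) / 2.0) / (L / 2.0)
    return np.array([L / 1000.0, position])


def encode_physchem_window(
    chain: ChainRecord, i: int, spec: WindowSpec, scales: PhysChemScales
) -> np.ndarray:
    """Six normalised propensity values per window position; pseudo positions zero."""
    out = np.zeros(6 * spec.n)
    for w, k in enumerate(spec.offsets):
        j = i + k
        if 0 <= j < chain.length:
            out[6 * w : 6 * w + 6] = scales.vector(chain.sequence[j])
    return out


def window_multipliers(spec: WindowSpec, weights, mode: str = "max") -> np.ndarray:
    """Per-position multipliers m_k derived from fitted neighbour coefficients.

    mode 'max': m_k = w_k / max_j(w_j) for k != 0 (the centre keeps m_0 = 1),
    so the most influential neighbours keep near-full magnitude. mode 'raw'
    uses the coefficients directly; mode 'none' is the identity.
    """
    if mode == "none" or weights is None:
        return np.ones(spec.n)
    if mode not in ("raw", "max"):
        raise ConfigurationError(f"unknown weighting mode {mode!r}")
    if weights.window != spec.n:
        raise ConfigurationError(
            f"weights fitted for window {weights.window}, feature window is {spec.n}"
        )
    coeffs = np.asarray(weights.coefficients, dtype=float)
    m = np.empty(spec.n)
    m[spec.half] = 1.0
    side = coeffs if mode == "raw" else coeffs / np.max(np.abs(coeffs))
    m[: spec.half] = side[: spec.half]
    m[spec.half + 1 :] = side[spec.half :]
    return m


def apply_window_weighting(block_vector, spec: WindowSpec, weights, mode: str = "max"):
    """Scale each window position's sub-block by its multiplier m_k (centre 1)."""
    vec = np.asarray(block_vector, dtype=float)
    if vec.shape[-1] % spec.n != 0:
        raise ConfigurationError(
            f"block width {vec.shape[-1]} not divisible by window {spec.n}"
        )
    per = vec.shape[-1] // spec.n
    m = window_multipliers(spec, weights, mode)
    shaped = vec.reshape(vec.shape[:-1] + (spec.n, per))
    return (shaped * m[:, None]).reshape(vec.shape)


def assemble_features(
    chain: ChainRecord,
    spec: WindowSpec,
    scales: PhysChemScales,
    weights=None,
    blocks=ALL_BLOCKS,
    weighting_mode: str = "max",
    flag_real_terminals: bool = False,
) -> FeatureMatrix:
    """Concatenate the enabled feature blocks for every residue of a chain.

    With all blocks enabled the width is 33N + 8. If ``weights`` is given,
    every windowed block is rescaled by :func:`apply_window_weighting`.
    """
    unknown = set(blocks) - set(ALL_BLOCKS)
    if unknown:
        raise ConfigurationError(f"unknown feature blocks {sorted(unknown)}")
    L = chain.length
    n = spec.n
    columns: dict[str, np.ndarray] = {}
    if "pssm_window" in blocks:
        columns["pssm_window"] = np.stack(
            [encode_pssm_window(chain, i, spec, flag_real_terminals) for i in range(L)]
        )
    if "ss_local" in blocks:
        columns["ss_local"] = np.stack([encode_ss_local(chain, i, spec) for i in range(L)])
    if "ss_global" in blocks:
        columns["ss_global"] = np.tile(encode_ss_global(chain), (L, 1))
    if "disorder" in blocks:
        columns["disorder"] = np.stack(
            [encode_disorder_window(chain, i, spec) for i in range(L)]
        )
    if "seq_len" in blocks or "seq_pos" in blocks:
        seq_feats = np.stack([encode_sequence_features(chain, i) for i in range(L)])
        if "seq_len" in blocks:
            columns["seq_len"] = seq_feats[:, :1]
        if "seq_pos" in blocks:
            columns["seq_pos"] = seq_feats[:, 1:]
    if "physchem" in blocks:
        columns["physchem"] = np.stack(
            [encode_physchem_window(chain, i, spec, scales) for i in range(L)]
        )
    if weights is not None:
        for name in WINDOWED_BLOCKS:
            if name in columns:
                columns[name] = apply_window_weighting(
                    columns[name], spec, weights, weighting_mode
                )
    layout = [(name, columns[name].shape[1]) for name in ALL_BLOCKS if name in columns]
    values = np.concatenate([columns[name] for name, _ in layout], axis=1)
    return FeatureMatrix(values=values, layout=layout)


def expected_width(spec: WindowSpec, blocks=ALL_BLOCKS) -> int:
    """Column count of the layout: 21N + 3N + 6 + 3N + 1 + 1 + 6N = 33N + 8."""
    widths = {
        "pssm_window": 21 * spec.n,
        "ss_local": 3 * spec.n,
        "ss_global": 6,
        "disorder": 3 * spec.n,
        "seq_len": 1,
        "seq_pos": 1,
        "physchem": 6 * spec.n,
    }
    return sum(widths[b] for b in blocks)


def write_feature_tsv(path, fm: FeatureMatrix) -> None:
    """Export a feature matrix as TSV with block[offset] column names."""
    header = "\t".join(fm.column_names())
    np.savetxt(path, fm.values, delimiter="\t", header=header, comments="")
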