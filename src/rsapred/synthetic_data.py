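"""Synthetic protein chains with every upstream profile and RSA tracks of
known generative structure.

The generator emulates the *statistical shape* of the real inputs — residue
composition, PSSM self-preference, secondary-structure run lengths,
contiguous disorder segments — and produces RSA tracks from two known
processes so that downstream estimators can be validated by parameter
recovery:

``neighbor_linear``
    A spatially autocorrelated track that is the stationary law of the
    symmetric neighbour update RSA_i ← b + Σ_k w_k·RSA_{i+k} + noise, i.e. a
    Gaussian conditional autoregression with banded precision (I − W)/σ².
    By construction E[RSA_i | window neighbours] = b + Σ w_k RSA_{i±k}, so
    ordinary least squares on complete windows recovers (w, b) without bias.

``feature_linked``
    RSA is a logistic function of the residue's physicochemical values,
    local secondary-structure probabilities and chain position, plus noise —
    a learnable signal for the SVR.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import cholesky_banded, solve_banded, solveh_banded
from scipy.special import expit

from .errors import ConfigurationError
from .feature_encoding import SCALE_NAMES, PhysChemScales, load_physchem_scales
from .io_formats import (
    AA_ALPHABET,
    ChainRecord,
    DisorderProfile,
    PssmProfile,
    RsaTrack,
    Ss3Profile,
    write_disopred,
    write_fasta,
    write_predictions,
    write_psipred_ss2,
    write_pssm,
)

#: Default symmetric neighbour weights for window 9 (offsets ±1..±4, decreasing
#: outward, Σ|w| = 0.8 < 1 so the conditional autoregression is well defined).
DEFAULT_NEIGHBOR_WEIGHTS = {1: 0.22, 2: 0.12, 3: 0.05, 4: 0.01}
DEFAULT_NEIGHBOR_INTERCEPT = 0.07  # stationary mean ~= b / (1 - sum w) = 0.35

#: Default feature-linked signal coefficients (on [0,1]-normalised scales).
DEFAULT_FEATURE_COEFFS = {
    "intercept": -3.7,
    "hydrophilicity": 2.0,
    "flexibility": 0.6,
    "accessibility": 0.8,
    "polarity": 0.6,
    "exposed_surface": 1.2,
    "turns": 0.8,
    "prob_H": -0.6,
    "prob_E": -1.0,
    "position": 0.6,
}

#: Markov self-transition probabilities of the 3-state SS generator; mean run
#: length is 1/(1-p): ~6.7 for helix, 5 for strand, 4 for coil.
SS_SELF_TRANSITION = {"H": 0.85, "E": 0.80, "C": 0.75}


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic chain set."""

    n_chains: int = 30
    min_length: int = 50
    max_length: int = 80
    rng_seed: int = 0
    rsa_model: str = "feature_linked"
    neighbor_weights: dict = field(default_factory=lambda: dict(DEFAULT_NEIGHBOR_WEIGHTS))
    neighbor_intercept: float = DEFAULT_NEIGHBOR_INTERCEPT
    noise_sigma: float = 0.02
    feature_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_COEFFS))
    feature_noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length <= 10000:
            raise ConfigurationError("lengths must satisfy 1 <= min <= max <= 10000")
        if self.rsa_model not in ("neighbor_linear", "feature_linked", "none"):
            raise ConfigurationError(f"unknown rsa_model {self.rsa_model!r}")
        if self.noise_sigma < 0 or self.feature_noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")


def load_background_frequencies() -> tuple[str, np.ndarray]:
    text = resources.files("rsapred.data").joinpath("residue_frequencies.yaml").read_text()
    table = yaml.safe_load(text)
    letters = AA_ALPHABET
    freqs = np.array([float(table[a]) for a in letters])
    return letters, freqs / freqs.sum()


def _sample_sequence(rng: np.random.Generator, L: int) -> str:
    letters, freqs = load_background_frequencies()
    return "".join(rng.choice(list(letters), size=L, p=freqs))


def _sample_pssm(rng: np.random.Generator, sequence: str) -> PssmProfile:
    """Integer log-odds rows with the emitted residue's own column elevated."""
    L = len(sequence)
    scores = np.rint(rng.normal(-1.0, 2.0, size=(L, 20)))
    for i, letter in enumerate(sequence):
        col = AA_ALPHABET.index(letter) if letter in AA_ALPHABET else None
        if col is not None:
            scores[i, col] += 6
    return PssmProfile(scores)


def _sample_ss3(rng: np.random.Generator, L: int) -> Ss3Profile:
    """3-state Markov chain with realistic run lengths; probs favour the state."""
    states = []
    current = "CHE"[rng.integers(3)]
    for _ in range(L):
        states.append(current)
        if rng.uniform() >= SS_SELF_TRANSITION[current]:
            current = rng.choice([s for s in "CHE" if s != current])
    probs = np.empty((L, 3))
    for i, s in enumerate(states):
        p = rng.uniform(0.6, 0.95)
        rest = rng.uniform(0.0, 1.0)
        others = np.array([(1 - p) * rest, (1 - p) * (1 - rest)])
        row = {"C": [p, others[0], others[1]],
               "H": [others[0], p, others[1]],
               "E": [others[0], others[1], p]}[s]
        probs[i] = row
    # quantise to the .ss2 dialect's 3-decimal precision so files round-trip
    return Ss3Profile("".join(states), np.round(probs, 3))


def _sample_disorder(rng: np.random.Generator, L: int, threshold: float = 0.5) -> DisorderProfile:
    """Low background disorder with a few contiguous high-probability segments."""
    p = rng.uniform(0.01, 0.2, size=L)
    for _ in range(rng.poisson(1.5)):
        start = int(rng.integers(0, L))
        length = int(rng.integers(3, max(4, L // 5)))
        p[start : start + length] = rng.uniform(0.6, 0.95, size=p[start : start + length].shape)
    p = np.round(p, 3)  # the on-disk dialect carries 3 decimals
    return DisorderProfile(
        p_disorder=p, p_order=1.0 - p, state=(p >= threshold).astype(int),
        threshold=threshold,
    )


def _neighbor_weight_array(weights: dict) -> tuple[int, np.ndarray]:
    """Validate symmetric neighbour weights keyed by positive offset."""
    half = max(weights)
    w = np.zeros(half)
    for k in range(1, half + 1):
        w[k - 1] = float(weights.get(k, 0.0))
    total = 2 * np.sum(np.abs(w))
    if total >= 1.0:
        raise ConfigurationError(
            f"sum of |neighbour weights| is {total:.3f} >= 1: process is non-stationary"
        )
    return half, w


def generate_rsa_neighbor_linear(
    length: int,
    weights: dict,
    intercept: float,
    sigma: float,
    rng: np.random.Generator,
    obs_sigma: float = 0.0,
) -> RsaTrack:
    """Sample the stationary law of the symmetric neighbour update.

    ``weights`` maps positive offsets k to w_k (applied symmetrically to ±k).
    The track is a draw from the Gaussian field with banded precision
    (I − W)/σ², whose full conditionals are exactly
    RSA_i | rest ~ N(b + Σ_k w_k·RSA_{i±k}, σ²) — repeated application of the
    noisy neighbour update converges to this law. Optional independent
    observation noise (``obs_sigma``) is added afterwards; values are clamped
    to [0, 1] with a warning when more than 1% of them clip.
    """
    if sigma < 0:
        raise ConfigurationError("sigma must be non-negative")
    half, w = _neighbor_weight_array(weights)
    if length <= half:
        raise ConfigurationError(f"length {length} too short for offsets up to {half}")
    # banded upper storage of (I - W): ab[half + i - j, j] = A[i, j]
    ab = np.zeros((half + 1, length))
    ab[half] = 1.0
    for k in range(1, half + 1):
        ab[half - k, k:] = -w[k - 1]
    mu = solveh_banded(ab, np.full(length, intercept))
    if sigma == 0:
        x = mu  # degenerate case: the deterministic fixed point of the update
    else:
        # Q = (I - W)/sigma^2 = (U/sigma)^T (U/sigma); x = mu + sigma * U^{-1} z
        chol = cholesky_banded(ab)
        z = rng.standard_normal(length)
        x = mu + sigma * solve_banded((0, half), chol, z)
    if obs_sigma > 0:
        x = x + rng.normal(0.0, obs_sigma, size=length)
    clipped = np.sum((x < 0) | (x > 1))
    if clipped / length > 0.01:
        warnings.warn(
            f"{clipped}/{length} RSA values clamped to [0,1]; "
            "recovery near the boundary will be biased", stacklevel=2,
        )
    return RsaTrack(np.clip(x, 0.0, 1.0), unit_scale="fraction")


def generate_rsa_feature_linked(
    chain: ChainRecord,
    coeffs: dict,
    sigma: float,
    rng: np.random.Generator,
    scales: PhysChemScales,
) -> RsaTrack:
    """RSA as a logistic function of physicochemical, SS and position features."""
    L = chain.length
    if chain.ss3 is None:
        raise ConfigurationError("feature_linked RSA requires an ss3 profile")
    z = np.full(L, float(coeffs.get("intercept", 0.0)))
    for i, letter in enumerate(chain.sequence):
        vec = scales.vector(letter)
        z[i] += sum(
            float(coeffs.get(name, 0.0)) * vec[j] for j, name in enumerate(SCALE_NAMES)
        )
    z += float(coeffs.get("prob_H", 0.0)) * chain.ss3.probs[:, 1]
    z += float(coeffs.get("prob_E", 0.0)) * chain.ss3.probs[:, 2]
    i1 = np.arange(1, L + 1)
    position = 1.0 - np.abs(i1 - (L + 1) / 2.0) / (L / 2.0)
    z += float(coeffs.get("position", 0.0)) * position
    x = expit(z)
    if sigma > 0:
        x = x + rng.normal(0.0, sigma, size=L)
    return RsaTrack(np.clip(x, 0.0, 1.0), unit_scale="fraction")


def generate_chain_set(spec: SyntheticSpec, scales: PhysChemScales | None = None) -> list[ChainRecord]:
    """Generate fully populated chains (sequence, PSSM, ss3, disorder, RSA).

    Deterministic for a fixed ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if scales is None:
        scales = load_physchem_scales()
    chains = []
    for idx in range(spec.n_chains):
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        sequence = _sample_sequence(rng, L)
        chain = ChainRecord(
            chain_id=f"syn{idx:04d}",
            sequence=sequence,
            pssm=_sample_pssm(rng, sequence),
            ss3=_sample_ss3(rng, L),
            disorder=_sample_disorder(rng, L),
        )
        if spec.rsa_model == "neighbor_linear":
            chain.rsa = generate_rsa_neighbor_linear(
                L, spec.neighbor_weights, spec.neighbor_intercept, spec.noise_sigma, rng
            )
        elif spec.rsa_model == "feature_linked":
            chain.rsa = generate_rsa_feature_linked(
                chain, spec.feature_coeffs, spec.feature_noise_sigma, rng, scales
            )
        chains.append(chain)
    return chains


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_files(chains, out_dir) -> dict:
    """Write every chain in all five on-disk dialects plus a checksum manifest.

    Per chain: ``<id>.fasta``, ``<id>.pssm``, ``<id>.ss2``, ``<id>.diso`` and
    ``<id>.rsa.tsv``. Returns the manifest (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for chain in chains:
        files = {}
        base = out / chain.chain_id
        write_fasta(f"{base}.fasta", [chain])
        files["fasta"] = f"{chain.chain_id}.fasta"
        write_pssm(f"{base}.pssm", chain)
        files["pssm"] = f"{chain.chain_id}.pssm"
        write_psipred_ss2(f"{base}.ss2", chain)
        files["ss2"] = f"{chain.chain_id}.ss2"
        write_disopred(f"{base}.diso", chain)
        files["disorder"] = f"{chain.chain_id}.diso"
        if chain.rsa is not None:
            write_predictions(f"{base}.rsa.tsv", chain.chain_id, chain.sequence, chain.rsa)
            files["rsa"] = f"{chain.chain_id}.rsa.tsv"
        manifest[chain.chain_id] = {
            name: {"path": rel, "sha256": _sha256(out / rel)} for name, rel in files.items()
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
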