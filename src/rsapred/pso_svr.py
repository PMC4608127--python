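"""ε-SVR prediction engine with chain-level cross-validation and tuning.

The regressor is a Gaussian-kernel ε-SVR (scikit-learn's SVR, the standard
ε-insensitive formulation). Hyperparameters (C, γ, ε) are searched either by
inertia-weight particle swarm optimisation (PSO) or by an exhaustive grid
baseline, with cross-validated mean absolute error as the fitness. C and γ
are searched in log10 space, ε linearly.

Cross-validation is always chain-level: a chain's residues are never split
between training and test.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from sklearn.svm import SVR

from .errors import ConfigurationError
from .evaluation import mae
from .feature_encoding import ALL_BLOCKS, PhysChemScales, WindowSpec, assemble_features


@dataclass
class SvrHyperParams:
    """(C, γ, ε) for the Gaussian-kernel ε-SVR.

    Defaults follow the LIBSVM convention: C = 1, γ = 1/(D·Var(X))
    (``gamma=None`` meaning scikit-learn's "scale"), ε = 0.1.
    """

    C: float = 1.0
    gamma: Optional[float] = None
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError(f"C must be positive, got {self.C}")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError(f"gamma must be positive, got {self.gamma}")
        if self.epsilon < 0:
            raise ConfigurationError(f"epsilon must be non-negative, got {self.epsilon}")

    def as_vector(self) -> np.ndarray:
        if self.gamma is None:
            raise ConfigurationError("cannot vectorise gamma='scale'")
        return np.array([self.C, self.gamma, self.epsilon])

    @classmethod
    def from_vector(cls, vec) -> "SvrHyperParams":
        c, g, e = (float(v) for v in vec)
        return cls(C=c, gamma=g, epsilon=max(e, 0.0))


#: Search box per dimension: (low, high, log10-scale flag), order (C, γ, ε).
DEFAULT_BOUNDS = ((1e-4, 1e3, True), (1e-5, 1e1, True), (0.0, 0.5, False))


@dataclass
class PsoConfig:
    """Inertia-weight PSO settings (Clerc–Kennedy constriction-style defaults)."""

    swarm_size: int = 20
    iterations: int = 50
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    bounds: Sequence = DEFAULT_BOUNDS
    velocity_clamp: float = 0.2
    rng_seed: int = 0
    init_positions: Sequence = ()

    def __post_init__(self) -> None:
        if self.swarm_size < 1 or self.iterations < 1:
            raise ConfigurationError("swarm_size and iterations must be >= 1")
        for lo, hi, _ in self.bounds:
            if not lo < hi:
                raise ConfigurationError(f"invalid bounds ({lo}, {hi})")


def _to_internal(pos, bounds):
    return np.array(
        [np.log10(p) if log else p for p, (_, _, log) in zip(pos, bounds)]
    )


def _to_actual(pos, bounds):
    return np.array(
        [10.0 ** p if log else p for p, (_, _, log) in zip(pos, bounds)]
    )


def pso_optimize(fitness_fn: Callable, config: PsoConfig):
    """Minimise ``fitness_fn`` over the bounded box with inertia-weight PSO.

    Velocity update v ← ωv + c1·r1·(pbest − x) + c2·r2·(gbest − x); positions
    are clipped to the box and the velocity zeroed in clipped dimensions;
    velocities are clamped to ``velocity_clamp`` of each dimension's range.
    Non-finite fitness values are treated as +inf with a warning.

    Returns (best position in actual space, best fitness, per-iteration trace
    of the global best, which is non-increasing by construction).
    """
    rng = np.random.default_rng(config.rng_seed)
    bounds = config.bounds
    lo = _to_internal([b[0] for b in bounds], bounds)
    hi = _to_internal([b[1] for b in bounds], bounds)
    dim = len(bounds)
    vmax = config.velocity_clamp * (hi - lo)

    def evaluate(x_internal):
        val = fitness_fn(_to_actual(x_internal, bounds))
        if not np.isfinite(val):
            warnings.warn("non-finite fitness treated as +inf", stacklevel=2)
            return np.inf
        return float(val)

    pos = rng.uniform(lo, hi, size=(config.swarm_size, dim))
    for i, init in enumerate(config.init_positions):
        if i >= config.swarm_size:
            break
        pos[i] = np.clip(_to_internal(np.asarray(init, dtype=float), bounds), lo, hi)
    vel = np.zeros_like(pos)

    fitness = np.array([evaluate(p) for p in pos])
    pbest = pos.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(config.iterations):
        r1 = rng.uniform(size=(config.swarm_size, dim))
        r2 = rng.uniform(size=(config.swarm_size, dim))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = pos + vel
        clipped_lo = pos < lo
        clipped_hi = pos > hi
        pos = np.clip(pos, lo, hi)
        vel[clipped_lo | clipped_hi] = 0.0
        fitness = np.array([evaluate(p) for p in pos])
        improved = fitness < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace.append(gbest_fit)
    return _to_actual(gbest, bounds), gbest_fit, np.array(trace)


def grid_search(fitness_fn: Callable, grid_axes: Sequence):
    """Exhaustive minimisation over the Cartesian product of the axes.

    Ties are broken by the first point visited in row-major order.
    """
    axes = [np.asarray(a, dtype=float) for a in grid_axes]
    if any(a.size == 0 for a in axes):
        raise ConfigurationError("grid axes must be non-empty")
    best_point, best_fit = None, np.inf
    for point in product(*axes):
        val = fitness_fn(np.array(point))
        if not np.isfinite(val):
            warnings.warn("non-finite fitness treated as +inf", stacklevel=2)
            continue
        if val < best_fit:
            best_point, best_fit = np.array(point), float(val)
    return best_point, best_fit


def make_folds(chain_ids: Sequence[str], n: int, rng_seed: int) -> dict[str, int]:
    """Random chain-level partition into n folds with sizes differing by <= 1."""
    ids = list(chain_ids)
    if n < 2:
        raise ConfigurationError(f"need at least 2 folds, got {n}")
    if n > len(ids):
        raise ConfigurationError(f"{n} folds requested for {len(ids)} chains")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate chain ids")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(ids))
    return {ids[j]: i % n for i, j in enumerate(order)}


def train_svr(features, targets, params: SvrHyperParams) -> SVR:
    """Fit a Gaussian-kernel ε-SVR (standard ε-insensitive optimisation)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigurationError("training features must be a non-empty 2-D array")
    if y.shape != (X.shape[0],):
        raise ConfigurationError("targets must align with feature rows")
    model = SVR(
        kernel="rbf",
        C=params.C,
        gamma="scale" if params.gamma is None else params.gamma,
        epsilon=params.epsilon,
    )
    model.fit(X, y)
    return model


def encode_chain_set(
    chains,
    spec: WindowSpec,
    scales: PhysChemScales,
    weights=None,
    blocks=ALL_BLOCKS,
    weighting_mode: str = "max",
):
    """Feature matrix and fraction-scale RSA targets per chain id."""
    features, targets = {}, {}
    for chain in chains:
        fm = assemble_features(
            chain, spec, scales, weights=weights, blocks=blocks,
            weighting_mode=weighting_mode,
        )
        features[chain.chain_id] = fm.values
        if chain.rsa is not None:
            targets[chain.chain_id] = chain.rsa.as_fraction()
    return features, targets


def cv_predictions(
    features: dict,
    targets: dict,
    folds: dict[str, int],
    params: SvrHyperParams,
    regressor_factory: Optional[Callable] = None,
) -> dict[str, np.ndarray]:
    """Out-of-fold predictions per chain under chain-level cross-validation.

    For each fold a regressor is trained on all out-of-fold chains only, so a
    chain's own targets never influence its predictions.
    """
    missing = set(folds) - set(features)
    if missing:
        raise ConfigurationError(f"folds reference unknown chains {sorted(missing)}")
    preds: dict[str, np.ndarray] = {}
    for fold in sorted(set(folds.values())):
        train_ids = [cid for cid, f in folds.items() if f != fold]
        test_ids = [cid for cid, f in folds.items() if f == fold]
        if not train_ids or not test_ids:
            raise ConfigurationError("every fold must be non-empty with a complement")
        X_train = np.concatenate([features[c] for c in train_ids])
        y_train = np.concatenate([targets[c] for c in train_ids])
        if regressor_factory is None:
            model = train_svr(X_train, y_train, params)
        else:
            model = regressor_factory(params)
            model.fit(X_train, y_train)
        for cid in test_ids:
            preds[cid] = model.predict(features[cid])
    return preds


def cv_mae_precomputed(
    features: dict,
    targets: dict,
    folds: dict[str, int],
    params: SvrHyperParams,
    regressor_factory: Optional[Callable] = None,
) -> float:
    """Pooled (residue-weighted) CV mean absolute error on pre-encoded features.

    Errors are pooled over residues, weighting every residue equally
    regardless of chain length.
    """
    preds = cv_predictions(features, targets, folds, params, regressor_factory)
    pooled = np.concatenate([np.abs(preds[c] - targets[c]) for c in sorted(preds)])
    return float(np.mean(pooled))


def cv_fitness(
    chains,
    spec: WindowSpec,
    scales: PhysChemScales,
    weights,
    params: SvrHyperParams,
    folds: dict[str, int],
    blocks=ALL_BLOCKS,
    regressor_factory: Optional[Callable] = None,
) -> float:
    """Chain-level cross-validated MAE (fraction scale) of an ε-SVR."""
    features, targets = encode_chain_set(chains, spec, scales, weights, blocks)
    return cv_mae_precomputed(features, targets, folds, params, regressor_factory)


def tune_on_subset(
    chains,
    spec: WindowSpec,
    scales: PhysChemScales,
    subset_size: int,
    per_fold: bool = True,
    n_folds: int = 3,
    pso_config: Optional[PsoConfig] = None,
    weights=None,
    blocks=ALL_BLOCKS,
    rng_seed: int = 0,
    seed_default: bool = True,
) -> tuple[SvrHyperParams, float]:
    """Tune (C, γ, ε) by PSO on a reduced random subset of chains.

    Mirrors the reduced-set strategy used for large training corpora: the full
    set is partitioned into ``n_folds`` chain-level folds, ``subset_size``
    chains are sampled from each fold (or from the whole set when
    ``per_fold=False``), and PSO minimises the subset's chain-level CV MAE.
    When ``seed_default`` is true, the incumbent default hyperparameters join
    the initial swarm (warm start), so tuning can only match or improve them
    under the same folds. Returns (best params, best subset CV MAE).
    """
    ids = [c.chain_id for c in chains]
    folds = make_folds(ids, n_folds, rng_seed)
    rng = np.random.default_rng(rng_seed + 1)
    if per_fold:
        chosen: list[str] = []
        for fold in range(n_folds):
            members = [cid for cid, f in folds.items() if f == fold]
            if subset_size > len(members):
                raise ConfigurationError(
                    f"subset_size {subset_size} exceeds fold size {len(members)}"
                )
            chosen.extend(rng.choice(members, size=subset_size, replace=False))
    else:
        if subset_size > len(ids):
            raise ConfigurationError("subset_size exceeds chain count")
        chosen = list(rng.choice(ids, size=subset_size, replace=False))
    subset = [c for c in chains if c.chain_id in set(chosen)]
    sub_folds = {cid: folds[cid] for cid in (c.chain_id for c in subset)}

    features, targets = encode_chain_set(subset, spec, scales, weights, blocks)
    config = pso_config or PsoConfig(rng_seed=rng_seed)
    if seed_default:
        default = SvrHyperParams()
        n_feat = next(iter(features.values())).shape[1]
        var = float(np.var(np.concatenate(list(features.values()))))
        gamma_scale = 1.0 / (n_feat * var) if var > 0 else 1.0 / n_feat
        incumbent = np.array([default.C, gamma_scale, default.epsilon])
        config = PsoConfig(
            swarm_size=config.swarm_size,
            iterations=config.iterations,
            inertia=config.inertia,
            cognitive=config.cognitive,
            social=config.social,
            bounds=config.bounds,
            velocity_clamp=config.velocity_clamp,
            rng_seed=config.rng_seed,
            init_positions=tuple(config.init_positions) + (incumbent,),
        )

    def fitness(vec):
        return cv_mae_precomputed(
            features, targets, sub_folds, SvrHyperParams.from_vector(vec)
        )

    best_vec, best_fit, _ = pso_optimize(fitness, config)
    return SvrHyperParams.from_vector(best_vec), best_fit


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def scales_checksum(scales: PhysChemScales) -> str:
    blob = repr(sorted((k, sorted(v.items())) for k, v in scales.normalized.items()))
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class ModelBundle:
    """A trained predictor with everything needed to re-encode inputs safely."""

    model: SVR
    window: int
    blocks: tuple
    weighting_mode: str
    params: SvrHyperParams
    weights: object = None
    scales_digest: str = ""
    layout: list = field(default_factory=list)

    def check_compatible(self, spec: WindowSpec, scales: PhysChemScales) -> None:
        if spec.n != self.window:
            raise ConfigurationError(
                f"model trained with window {self.window}, requested {spec.n}"
            )
        if self.scales_digest and scales_checksum(scales) != self.scales_digest:
            raise ConfigurationError("physicochemical scale file differs from training")


def train_pipeline(
    chains,
    spec: WindowSpec,
    scales: PhysChemScales,
    params: SvrHyperParams,
    weights=None,
    blocks=ALL_BLOCKS,
    weighting_mode: str = "max",
) -> ModelBundle:
    """Encode all chains and fit one ε-SVR on the pooled residues."""
    features, targets = encode_chain_set(chains, spec, scales, weights, blocks, weighting_mode)
    untracked = [cid for cid in features if cid not in targets]
    if untracked:
        raise ConfigurationError(f"chains without RSA targets: {untracked}")
    X = np.concatenate(list(features.values()))
    y = np.concatenate([targets[cid] for cid in features])
    model = train_svr(X, y, params)
    fm_layout = []
    return ModelBundle(
        model=model,
        window=spec.n,
        blocks=tuple(blocks),
        weighting_mode=weighting_mode,
        params=params,
        weights=weights,
        scales_digest=scales_checksum(scales),
        layout=fm_layout,
    )


def predict_chains(bundle: ModelBundle, chains, spec: WindowSpec, scales: PhysChemScales):
    """Fraction-scale RSA predictions per chain, refusing mismatched encoders."""
    bundle.check_compatible(spec, scales)
    features, _ = encode_chain_set(
        chains, spec, scales, bundle.weights, bundle.blocks, bundle.weighting_mode
    )
    return {cid: bundle.model.predict(X) for cid, X in features.items()}


def save_model(path, bundle: ModelBundle) -> None:
    joblib.dump(bundle, path)


def load_model(path) -> ModelBundle:
    bundle = joblib.load(path)
    if not isinstance(bundle, ModelBundle):
        raise ConfigurationError(f"{path} does not contain a model bundle")
    return bundle
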