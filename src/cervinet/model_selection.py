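"""Architecture search by Monte-Carlo cross-validation.

Every feed-forward architecture with one or two hidden layers and at most
17 hidden neurons in total is scored by repeated random subsampling:
fresh 70/30 train/validation splits, z-scoring (and optionally PCA)
fitted on the training side only, a freshly initialized network trained
with Levenberg-Marquardt, and the validation MSE recorded.  The mean MSE
over repeats carries a Student-t 95% confidence interval, and the
architecture with the lowest mean wins (ties: fewer neurons, then fewer
layers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ann import NetArchitecture, TrainConfig, forward, init_model, mse, train_lm

__all__ = [
    "SearchSpace",
    "ArchitectureScore",
    "PcaTransform",
    "enumerate_architectures",
    "monte_carlo_cv",
    "select_architecture",
    "pca_transform",
    "run_search",
]


@dataclass(frozen=True)
class SearchSpace:
    max_total_neurons: int = 17
    max_layers: int = 2
    candidates: tuple[NetArchitecture, ...] = ()

    def __post_init__(self) -> None:
        for c in self.candidates:
            if not 1 <= len(c.hidden_layers) <= self.max_layers:
                raise ValueError("candidate layer count outside the search space")
            if sum(c.hidden_layers) > self.max_total_neurons:
                raise ValueError("candidate exceeds the hidden-neuron budget")


@dataclass(frozen=True)
class ArchitectureScore:
    architecture: NetArchitecture
    repeat_mses: tuple[float, ...]
    mean_mse: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_mse <= self.ci_high:
            raise ValueError("confidence interval must bracket the mean")


def enumerate_architectures(
    max_total_neurons: int = 17,
    max_layers: int = 2,
    n_inputs: int = 18,
    hidden_activation: str = "tanh",
) -> SearchSpace:
    """All single-layer widths and two-layer splits within the neuron budget.

    Ordered by total hidden neurons, then number of layers, then first-layer
    width; with the default limits (17, 2) this yields 137 candidates.
    """
    if max_total_neurons < 1 or max_layers < 1:
        raise ValueError("limits must be >= 1")
    layouts: list[tuple[int, ...]] = []
    for total in range(1, max_total_neurons + 1):
        layouts.append((total,))
        if max_layers >= 2:
            for n1 in range(1, total):
                layouts.append((n1, total - n1))
    layouts.sort(key=lambda h: (sum(h), len(h), h[0]))
    candidates = tuple(
        NetArchitecture(
            n_inputs=n_inputs,
            hidden_layers=h,
            hidden_activation=hidden_activation,  # type: ignore[arg-type]
        )
        for h in layouts
    )
    return SearchSpace(max_total_neurons, max_layers, candidates)


@dataclass
class PcaTransform:
    """Fitted principal-component rotation with a deterministic sign convention."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T

    def inverse(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.components + self.mean


def pca_transform(
    features: np.ndarray, variance_removal_fraction: float = 0.0
) -> tuple[np.ndarray, PcaTransform]:
    """Rotate features onto orthogonal principal components.

    With the removal fraction at 0 (the default) every component with
    nonzero variance is retained, so the rotation is lossless and serves
    only to decorrelate the predictors.  Components whose cumulative
    explained-variance share falls within the removal fraction (counted
    from the smallest component upwards) are dropped.  Sign convention:
    each component's largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with >= 2 samples")
    pca = PCA(n_components=min(x.shape[0] - 1, x.shape[1]), svd_solver="full")
    pca.fit(x)
    comps = pca.components_
    var = pca.explained_variance_
    keep = var > max(var.max(), 1.0) * 1e-12  # drop numerically null directions
    if variance_removal_fraction > 0:
        share = var / var.sum()
        cum_from_smallest = np.cumsum(share[::-1])[::-1]
        keep &= cum_from_smallest > variance_removal_fraction
    comps, var = comps[keep], var[keep]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    fitted = PcaTransform(mean=pca.mean_, components=comps, explained_variance=var)
    return fitted.transform(x), fitted


def _split_seed(seed: int, arch: NetArchitecture, repeat: int, stream: str) -> int:
    """Order-independent substream seed per (architecture, repeat)."""
    stream_id = {"split": 0, "init": 1}[stream]
    ss = np.random.SeedSequence(
        entropy=seed,
        spawn_key=(len(arch.hidden_layers), *arch.hidden_layers, repeat, stream_id),
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def monte_carlo_cv(
    features: np.ndarray,
    targets: np.ndarray,
    architecture: NetArchitecture,
    n_repeats: int = 10,
    train_fraction: float = 0.70,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    use_pca: bool = False,
    standardize: bool = True,
    confidence: float = 0.95,
) -> ArchitectureScore:
    """Score one architecture by repeated random 70/30 subsampling.

    ``features`` are the raw (not yet standardized) predictors; per repeat
    the z-score parameters — and the PCA rotation when ``use_pca`` — are
    fitted on the 70% training side and applied to the held-out 30%, a
    fresh random initialization is trained, and the validation MSE kept.
    The confidence interval is mean +/- t(1-(1-c)/2, n-1) * sd / sqrt(n).
    """
    x = np.asarray(features, dtype=float)
    t = np.asarray(targets, dtype=float)
    n = x.shape[0]
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError("degenerate train/validation split")
    if train_config is None:
        train_config = TrainConfig(max_epochs=100)

    repeat_mses = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(_split_seed(seed, architecture, rep, "split"))
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        x_tr, x_va = x[tr], x[va]
        if standardize:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_va = (x_va - mu) / sd
        if use_pca:
            x_tr, rot = pca_transform(x_tr)
            x_va = rot.transform(x_va)
        arch = NetArchitecture(
            n_inputs=x_tr.shape[1],
            hidden_layers=architecture.hidden_layers,
            hidden_activation=architecture.hidden_activation,
        )
        model = init_model(arch, seed=_split_seed(seed, architecture, rep, "init"))
        trained, _ = train_lm(model, x_tr, t[tr], train_config)
        repeat_mses.append(mse(forward(trained, x_va), t[va]))

    return summarize_repeats(architecture, repeat_mses, confidence)


def summarize_repeats(
    architecture: NetArchitecture,
    repeat_mses: list[float],
    confidence: float = 0.95,
) -> ArchitectureScore:
    """Mean MSE over repeats with a Student-t confidence interval."""
    m = np.asarray(repeat_mses, dtype=float)
    mean = float(m.mean())
    if m.size > 1:
        half = float(
            stats.t.ppf(1 - (1 - confidence) / 2, m.size - 1)
            * m.std(ddof=1)
            / np.sqrt(m.size)
        )
    else:
        half = 0.0
    return ArchitectureScore(
        architecture=architecture,
        repeat_mses=tuple(float(v) for v in m),
        mean_mse=mean,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def select_architecture(scores: list[ArchitectureScore]) -> NetArchitecture:
    """Lowest mean MSE; ties broken by fewer total neurons, then fewer layers."""
    if not scores:
        raise ValueError("at least one architecture score is required")
    best = min(
        scores,
        key=lambda s: (
            s.mean_mse,
            sum(s.architecture.hidden_layers),
            len(s.architecture.hidden_layers),
        ),
    )
    return best.architecture


def run_search(
    features: np.ndarray,
    targets: np.ndarray,
    space: SearchSpace,
    n_repeats: int = 10,
    train_fraction: float = 0.70,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    use_pca: bool = False,
) -> tuple[NetArchitecture, list[ArchitectureScore]]:
    """Score every candidate and return (winner, all scores)."""
    scores = [
        monte_carlo_cv(
            features,
            targets,
            arch,
            n_repeats=n_repeats,
            train_fraction=train_fraction,
            seed=seed,
            train_config=train_config,
            use_pca=use_pca,
        )
        for arch in space.candidates
    ]
    return select_architecture(scores), scores
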