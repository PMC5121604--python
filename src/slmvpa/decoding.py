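"""Per-sphere identity decoding under four classification schemes.

Schemes
-------
face, voice
    within-modality: repeated random 80/20 splits of that modality's beta
    samples; train a linear one-vs-one SVM on the four identities, score
    on the held-out 20%.
face_to_voice, voice_to_face
    cross-modality: per repeat, train on a random 80% of the training
    modality's samples and test on a random 20% of the *other* modality's
    samples, so the total test count matches the within-modality case.
    Above-chance transfer implies an identity code shared across
    modalities.

The empirical chance level c' is estimated per sphere by shuffling the
*training* labels before fitting and testing on intact labels; with four
identities the theoretical chance is 0.25 but c' guards against label or
data structure biasing the classifier.

Randomness: every sphere draws its splits from a private generator seeded
by (master seed, scheme, stream, centre voxel index), so maps are
reproducible and independent of centre iteration order or parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._svm import fit_predict_gram, gram_matrix
from .searchlight import SearchlightMap
from .synth import BetaImageSet, IDENTITIES

__all__ = [
    "Scheme",
    "SCHEMES",
    "SplitPlan",
    "CentreMap",
    "evaluate_sphere",
    "run_searchlight",
    "empirical_chance_map",
]

_DECODED_MODALITIES = ("face", "voice")


@dataclass(frozen=True)
class Scheme:
    name: str
    train_modality: str
    test_modality: str

    def __post_init__(self) -> None:
        if self.train_modality not in _DECODED_MODALITIES or \
           self.test_modality not in _DECODED_MODALITIES:
            raise ValueError("schemes decode face and voice samples only")

    @property
    def is_cross(self) -> bool:
        return self.train_modality != self.test_modality


SCHEMES: dict[str, Scheme] = {
    "face": Scheme("face", "face", "face"),
    "voice": Scheme("voice", "voice", "voice"),
    "face_to_voice": Scheme("face_to_voice", "face", "voice"),
    "voice_to_face": Scheme("voice_to_face", "voice", "face"),
}
_SCHEME_CODE = {name: k for k, name in enumerate(SCHEMES)}
# substream tags so accuracy and chance estimation never share draws
_STREAM_ACCURACY, _STREAM_CHANCE = 0, 1


def get_scheme(scheme: "Scheme | str") -> Scheme:
    if isinstance(scheme, Scheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {list(SCHEMES)}") from None


@dataclass(frozen=True)
class SplitPlan:
    """Repeated random split plan: 80% train / 20% test, 100 repeats.

    Splits are identity-stratified by default (80% of each identity's
    samples train, the rest test): with unstratified draws the training
    class counts anti-correlate with the test composition, which biases
    both the accuracy and the shuffled-label chance level visibly below
    1/4 at these pool sizes. ``stratify=False`` restores plain random
    sampling with bounded redraws when a draw misses an identity.
    """

    train_fraction: float = 0.8
    n_repeats: int = 100
    seed: int = 0
    stratify: bool = True
    #: redraws allowed when an unstratified draw misses an identity
    max_redraws: int = 100
    #: chance estimation redraws the split per shuffle (if False, one split
    #: is drawn per sphere and only the labels are reshuffled)
    redraw_split_per_shuffle: bool = True
    C: float = 1.0
    #: per-feature standardization estimated on each training split
    #: (off by default: betas enter the classifier unscaled)
    standardize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CentreMap:
    """A per-sphere-centre statistic (accuracy or chance) on one grid."""

    shape: tuple[int, int, int]
    centres: np.ndarray        # flat voxel indices
    values: np.ndarray         # statistic per centre
    n_test_total: np.ndarray   # held-out predictions summed over repeats
    n_repeats: int = 1         # repeats the totals were summed over
    #: size of the sample pool test sets are drawn from (the number of
    #: independent observations behind the mean, used by calibrated inference)
    n_pool: int = 0

    def volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.shape, fill, dtype=float)
        vol.flat[self.centres] = self.values
        return vol

    def __len__(self) -> int:
        return len(self.centres)


def _centre_rng(seed: int, scheme_name: str, stream: int, centre: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _SCHEME_CODE[scheme_name], stream, int(centre)))
    )


def _draw_train(rng, pool: np.ndarray, identities: np.ndarray, n_train: int,
                max_redraws: int) -> tuple[np.ndarray, np.ndarray]:
    """Unstratified random train subset containing every identity; the rest
    of the pool is returned as the held-out candidates. A draw missing one
    of the identities in training is redrawn (bounded), then errors."""
    n_classes = len(np.unique(identities[pool]))
    for _ in range(max_redraws + 1):
        perm = rng.permutation(pool)
        train = perm[:n_train]
        if len(np.unique(identities[train])) == n_classes:
            return train, perm[n_train:]
    raise RuntimeError(
        f"could not draw a training set containing all identities in {max_redraws} redraws"
    )


def _stratified_split(
    rng, pool: np.ndarray, identities: np.ndarray, train_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-identity 80/20 split of a pool: round(f * n_k) of each identity's
    samples train (at least 1, at most n_k - 1), the rest test."""
    train_parts, test_parts = [], []
    for k in np.unique(identities[pool]):
        idx = rng.permutation(pool[identities[pool] == k])
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train_parts.append(idx[:n_tr])
        test_parts.append(idx[n_tr:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def _draw_split(
    rng,
    train_pool: np.ndarray,
    test_pool: np.ndarray | None,
    identities: np.ndarray,
    plan: SplitPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """One train/test draw. Within-modality (``test_pool=None``): disjoint
    80/20 of the pool. Cross-modality: train = 80% of the training
    modality's pool, test = 20% of the other modality's pool."""
    if plan.stratify:
        train, held = _stratified_split(rng, train_pool, identities, plan.train_fraction)
        if test_pool is None:
            return train, held
        _, test = _stratified_split(rng, test_pool, identities, plan.train_fraction)
        return train, test
    n_pool = len(train_pool)
    n_train = int(round(plan.train_fraction * n_pool))
    n_train = min(max(n_train, 1), n_pool - 1 if test_pool is None else n_pool)
    train, rest = _draw_train(rng, train_pool, identities, n_train, plan.max_redraws)
    if test_pool is None:
        return train, rest
    n_test = max(1, int(round((1.0 - plan.train_fraction) * len(test_pool))))
    return train, rng.permutation(test_pool)[:n_test]


def _predict_split(
    X: np.ndarray,
    gram: np.ndarray | None,
    train: np.ndarray,
    test: np.ndarray,
    y_train: np.ndarray,
    plan: SplitPlan,
) -> np.ndarray:
    """One train/test run; standardization (if on) is fit on the training
    rows only, so no test information leaks into the scaler."""
    if not plan.standardize:
        return fit_predict_gram(gram, train, test, y_train, C=plan.C)
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    sd[sd == 0] = 1.0
    from ._svm import fit_predict

    return fit_predict((X[train] - mu) / sd, y_train, (X[test] - mu) / sd, C=plan.C)


def _evaluate_pool(
    X: np.ndarray,
    identities: np.ndarray,
    train_pool: np.ndarray,
    test_pool: np.ndarray | None,
    plan: SplitPlan,
    rng: np.random.Generator,
    n_runs: int,
    shuffle_train: bool,
) -> tuple[float, int]:
    """Shared driver for accuracy and chance estimation on one sphere.

    ``test_pool=None`` means within-modality: each repeat splits
    ``train_pool`` into disjoint 80/20 subsets. Otherwise (cross scheme)
    the test samples are drawn from the disjoint ``test_pool``.
    Returns (mean per-repeat accuracy, total held-out predictions).
    """
    gram = None if plan.standardize else gram_matrix(X)
    accs = np.empty(n_runs)
    n_total = 0
    for r in range(n_runs):
        train, test = _draw_split(rng, train_pool, test_pool, identities, plan)
        y_train = identities[train]
        if shuffle_train:
            y_train = rng.permutation(y_train)
        pred = _predict_split(X, gram, train, test, y_train, plan)
        accs[r] = float(np.mean(pred == identities[test]))
        n_total += len(test)
    return float(accs.mean()), n_total


def evaluate_sphere(
    X: np.ndarray,
    identities: np.ndarray,
    modalities: np.ndarray | None = None,
    scheme: "Scheme | str | None" = None,
    plan: SplitPlan = SplitPlan(),
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Mean cross-validated identity-decoding accuracy of one voxel set.

    ``X`` is samples x feature voxels. If ``scheme`` is given, rows are
    pooled by ``modalities`` per the scheme; otherwise all rows form one
    within-modality pool. Returns (mean accuracy, total test predictions).
    """
    X = np.asarray(X, dtype=np.float64)
    identities = np.asarray(identities)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be samples x features with >= 1 feature")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((plan.seed,)))

    if scheme is None:
        train_pool, test_pool = np.arange(len(X)), None
    else:
        scheme = get_scheme(scheme)
        if modalities is None:
            raise ValueError("modalities required when a scheme is given")
        modalities = np.asarray(modalities)
        train_pool = np.flatnonzero(modalities == scheme.train_modality)
        test_pool = (None if not scheme.is_cross
                     else np.flatnonzero(modalities == scheme.test_modality))

    counts = np.bincount(identities[train_pool] - min(IDENTITIES),
                         minlength=len(IDENTITIES))
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per identity in the training pool")
    return _evaluate_pool(
        X, identities, train_pool, test_pool, plan, rng,
        n_runs=plan.n_repeats, shuffle_train=False,
    )


def _searchlight_driver(
    betas: BetaImageSet,
    sl: SearchlightMap,
    scheme: Scheme,
    plan: SplitPlan,
    n_runs: int,
    shuffle_train: bool,
    stream: int,
) -> CentreMap:
    if len(sl) == 0:
        raise ValueError("empty searchlight map")
    if sl.shape != betas.grid.shape:
        raise ValueError("searchlight and beta grids differ")

    train_rows = betas.modality_rows(scheme.train_modality)
    if scheme.is_cross:
        test_rows = betas.modality_rows(scheme.test_modality)
        pooled = np.concatenate([train_rows, test_rows])
    else:
        pooled = train_rows
    data = betas.data[pooled]
    identities = betas.labels["identity"].to_numpy()[pooled]

    n_tr = len(train_rows)
    train_pool = np.arange(n_tr)
    test_pool = np.arange(n_tr, len(pooled)) if scheme.is_cross else None

    values = np.empty(len(sl))
    n_totals = np.empty(len(sl), dtype=np.int64)
    for k, centre in enumerate(sl.centres):
        rng = _centre_rng(plan.seed, scheme.name, stream, centre)
        values[k], n_totals[k] = _evaluate_pool(
            data[:, sl.features[k]], identities, train_pool, test_pool, plan, rng,
            n_runs=n_runs, shuffle_train=shuffle_train,
        )
    n_pool = len(test_pool) if test_pool is not None else len(train_pool)
    return CentreMap(shape=sl.shape, centres=sl.centres.copy(),
                     values=values, n_test_total=n_totals, n_repeats=n_runs,
                     n_pool=n_pool)


def run_searchlight(
    betas: BetaImageSet,
    sl: SearchlightMap,
    scheme: "Scheme | str",
    plan: SplitPlan = SplitPlan(),
) -> CentreMap:
    """Accuracy map: mean cross-validated accuracy at every sphere centre."""
    scheme = get_scheme(scheme)
    return _searchlight_driver(
        betas, sl, scheme, plan, n_runs=plan.n_repeats,
        shuffle_train=False, stream=_STREAM_ACCURACY,
    )


def empirical_chance_map(
    betas: BetaImageSet,
    sl: SearchlightMap,
    scheme: "Scheme | str",
    n_shuffles: int = 100,
    plan: SplitPlan = SplitPlan(),
) -> CentreMap:
    """Empirical chance map c': mean accuracy with shuffled training labels.

    Training labels are permuted before fitting; the classifier is tested
    on intact test labels. By default each shuffle also redraws the 80/20
    split (``plan.redraw_split_per_shuffle``).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    scheme = get_scheme(scheme)
    if plan.redraw_split_per_shuffle:
        return _searchlight_driver(
            betas, sl, scheme, plan, n_runs=n_shuffles,
            shuffle_train=True, stream=_STREAM_CHANCE,
        )
    # fixed-split variant: one split per sphere, labels reshuffled per run
    fixed_plan = SplitPlan(
        train_fraction=plan.train_fraction, n_repeats=1, seed=plan.seed,
        max_redraws=plan.max_redraws, C=plan.C,
    )
    train_rows = betas.modality_rows(scheme.train_modality)
    if scheme.is_cross:
        test_rows = betas.modality_rows(scheme.test_modality)
        pooled = np.concatenate([train_rows, test_rows])
    else:
        pooled = train_rows
    data = betas.data[pooled]
    identities = betas.labels["identity"].to_numpy()[pooled]
    n_tr = len(train_rows)
    train_pool = np.arange(n_tr)
    test_pool = np.arange(n_tr, len(pooled)) if scheme.is_cross else None

    values = np.empty(len(sl))
    n_totals = np.empty(len(sl), dtype=np.int64)
    for k, centre in enumerate(sl.centres):
        X = data[:, sl.features[k]]
        gram = None if plan.standardize else gram_matrix(X)
        rng = _centre_rng(plan.seed, scheme.name, _STREAM_CHANCE, centre)
        train, test = _draw_split(rng, train_pool, test_pool, identities, plan)
        correct = total = 0
        for _ in range(n_shuffles):
            pred = _predict_split(X, gram, train, test,
                                  rng.permutation(identities[train]), plan)
            correct += int(np.sum(pred == identities[test]))
            total += len(test)
        values[k] = correct / total
        n_totals[k] = total
    n_pool = len(test_pool) if test_pool is not None else len(train_pool)
    return CentreMap(shape=sl.shape, centres=sl.centres.copy(),
                     values=values, n_test_total=n_totals, n_repeats=n_shuffles,
                     n_pool=n_pool)
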