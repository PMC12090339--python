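"""Bootstrapped ensemble surrogate over one-hot encoded variants.

The fitness landscape over all 20**P amino-acid combinations is modelled by
an ensemble of k feed-forward neural-network regressors.  Each member is
trained on a random 90% subsample of the training data (drawn without
replacement, seeded); the spread of member predictions at a query point acts
as a sample-based Bayesian posterior, so a uniformly drawn member is a
posterior draw — which is exactly what Thompson sampling needs.

`BootstrapEnsembleRegressor` follows the scikit-learn estimator contract
(get_params/set_params, fit/predict, fitted attributes with a trailing
underscore) and therefore composes with sklearn pipelines and model
selection.  Any base regressor with fit/predict semantics can be plugged in;
the default is a two-hidden-layer MLP (32 units each, ReLU, MSE loss).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .sequence_space import RegionSpec, Variant, VariantOneHotEncoder

#: Default number of ensemble members.
DEFAULT_ENSEMBLE_SIZE = 5
#: Default fraction of the training data each member sees.
DEFAULT_BOOTSTRAP_FRACTION = 0.9
#: Minimum training-set size for a meaningful ensemble fit.
MIN_TRAINING_SIZE = 5


def default_member() -> MLPRegressor:
    """The default ensemble member: a small feed-forward network.

    Two hidden layers of 32 ReLU units, squared-error loss, L-BFGS solver
    (full-batch quasi-Newton — fast and reliable on training sets of tens
    of variants) with mild L2 weight decay (alpha=2e-3): enough to keep
    predictions well-behaved on the vast unmeasured part of sequence space
    while leaving the members free to disagree far from the data, which is
    where the ensemble's uncertainty signal comes from.  Inputs are binary
    one-hot vectors and targets are on the WT-normalized fitness scale, so
    no feature or target scaling is applied.
    """
    return MLPRegressor(hidden_layer_sizes=(32, 32), activation="relu",
                        solver="lbfgs", alpha=2e-3, max_iter=2000)


class BootstrapEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Ensemble of k regressors, each fit on a seeded 90% subsample.

    Parameters
    ----------
    n_members : int, default 5
        Ensemble size k.
    bootstrap_fraction : float, default 0.9
        Fraction of the training set each member sees; member i trains on
        ``floor(bootstrap_fraction * n)`` rows drawn without replacement.
    base_estimator : sklearn regressor or None
        Prototype cloned per member; None means :func:`default_member`.
    random_state : int or None
        Seeds both the subsampling and each member's weight initialization;
        the whole fit/predict path is reproducible from (data, random_state).

    Attributes
    ----------
    members_ : list of fitted regressors
    member_indices_ : list of ndarray, the training rows each member saw
    n_features_in_ : int
    """

    def __init__(self, n_members: int = DEFAULT_ENSEMBLE_SIZE,
                 bootstrap_fraction: float = DEFAULT_BOOTSTRAP_FRACTION,
                 base_estimator=None, random_state: int | None = None):
        self.n_members = n_members
        self.bootstrap_fraction = bootstrap_fraction
        self.base_estimator = base_estimator
        self.random_state = random_state

    def fit(self, X, y) -> "BootstrapEnsembleRegressor":
        X, y = check_X_y(X, y)
        n = X.shape[0]
        if n < MIN_TRAINING_SIZE:
            raise ValueError(
                f"need at least {MIN_TRAINING_SIZE} training records, got {n}; "
                "score a larger initial library first")
        if self.n_members < 2:
            raise ValueError("ensemble needs at least 2 members")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        m = int(np.floor(self.bootstrap_fraction * n))
        if m < 2:
            raise ValueError("subsample too small; raise bootstrap_fraction")
        rng = np.random.default_rng(self.random_state)
        proto = self.base_estimator if self.base_estimator is not None \
            else default_member()
        self.members_ = []
        self.member_indices_ = []
        for i in range(self.n_members):
            idx = rng.choice(n, size=m, replace=False)
            member = clone(proto)
            if "random_state" in member.get_params():
                member.set_params(
                    random_state=int(rng.integers(0, 2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                member.fit(X[idx], y[idx])
            self.members_.append(member)
            self.member_indices_.append(np.sort(idx))
        self.n_features_in_ = X.shape[1]
        return self

    def member_predictions(self, X) -> np.ndarray:
        """(k, n_samples) matrix of per-member predictions."""
        check_is_fitted(self, "members_")
        X = check_array(X)
        return np.vstack([m.predict(X) for m in self.members_])

    def predict(self, X, return_std: bool = False):
        """Posterior mean (and optionally SD) over the k member predictions."""
        preds = self.member_predictions(X)
        mean = preds.mean(axis=0)
        if return_std:
            return mean, preds.std(axis=0, ddof=0)
        return mean

    def draw_member(self, rng: np.random.Generator | int):
        """A uniformly random fitted member — one posterior sample.

        The returned regressor's ``predict`` is deterministic; only the
        choice of member consumes randomness.
        """
        check_is_fitted(self, "members_")
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        return self.members_[int(rng.integers(len(self.members_)))]


@dataclass
class TrainingSet:
    """Measured (variant, fitness) records for one region.

    Always contains the wild type with fitness exactly 1 (it is the
    normalizer), holds no duplicate variants, and keeps inactive
    (fitness 0) records — a mostly-dead region's zeros are informative.
    """

    region: RegionSpec
    variants: list[Variant]
    fitness: np.ndarray

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if len(self.variants) != self.fitness.size:
            raise ValueError("variants and fitness must align")
        idents = [v.identities for v in self.variants]
        if len(set(idents)) != len(idents):
            raise ValueError("duplicate variants in training set")
        if self.region.wildtype not in idents:
            raise ValueError("training set must contain the wild type")
        wt_f = self.fitness[idents.index(self.region.wildtype)]
        if not np.isclose(wt_f, 1.0):
            raise ValueError(f"wild-type fitness must be 1, got {wt_f}")
        if not np.all(np.isfinite(self.fitness)) or np.any(self.fitness < 0):
            raise ValueError("fitness values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.variants)


def fit_ensemble(data: TrainingSet,
                 n_members: int = DEFAULT_ENSEMBLE_SIZE,
                 bootstrap_fraction: float = DEFAULT_BOOTSTRAP_FRACTION,
                 seed: int | None = 0,
                 base_estimator=None) -> BootstrapEnsembleRegressor:
    """Encode a training set and fit the bootstrapped ensemble on it."""
    enc = VariantOneHotEncoder(data.region).fit()
    X = enc.transform(data.variants)
    model = BootstrapEnsembleRegressor(
        n_members=n_members, bootstrap_fraction=bootstrap_fraction,
        base_estimator=base_estimator, random_state=seed)
    return model.fit(X, data.fitness)


def predict_posterior(ensemble: BootstrapEnsembleRegressor,
                      variants: list[Variant],
                      region: RegionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD of fitness for each variant."""
    enc = VariantOneHotEncoder(region).fit()
    X = enc.transform(variants)
    return ensemble.predict(X, return_std=True)


def save_ensemble(ensemble: BootstrapEnsembleRegressor, path) -> None:
    """Serialize a fitted ensemble plus its config to a run directory."""
    import pickle
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "ensemble.pkl", "wb") as fh:
        pickle.dump(ensemble, fh)
    meta = {"n_members": ensemble.n_members,
            "bootstrap_fraction": ensemble.bootstrap_fraction,
            "random_state": ensemble.random_state,
            "n_features_in": int(ensemble.n_features_in_),
            "member_training_sizes":
                [int(i.size) for i in ensemble.member_indices_]}
    (path / "ensemble.json").write_text(json.dumps(meta, indent=2))


def load_ensemble(path) -> BootstrapEnsembleRegressor:
    import pickle
    from pathlib import Path
    with open(Path(path) / "ensemble.pkl", "rb") as fh:
        return pickle.load(fh)
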