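"""Scikit-learn style estimators for single-trial P300 detection.

:class:`WideDeepP300Classifier` is the full wide-and-deep detector; the
``use_wide`` / ``use_deep`` switches give the two single-branch ablations.
:class:`SklearnAdapter` wraps any ordinary scikit-learn classifier so it can
run in the same evaluation harnesses (it flattens epochs and ignores
participant attributes).

X may be ``(n, 30, 90)`` epochs or already-flattened ``(n, 2700)``; values
are microvolts at the 100 Hz working rate. Participant attributes arrive as
``profiles`` (a mapping ``subject_id -> profile`` or an iterable of
profiles) plus per-epoch ``subject_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import CrossSpec, SparseFeatureSpec
from .ftrl import FtrlConfig, fit_model
from .network import deep_forward_batch, initialize_model, sigmoid

__all__ = ["WideDeepP300Classifier", "SklearnAdapter", "AnonymousProfile"]


@dataclass(frozen=True)
class AnonymousProfile:
    """Stand-in profile when no participant attributes are supplied."""

    subject_id: str = ""
    sex: str = "M"
    age_group: str = ""


def _as_profile_map(profiles) -> dict:
    if profiles is None:
        return {}
    if isinstance(profiles, dict):
        return dict(profiles)
    return {p.subject_id: p for p in profiles}


class WideDeepP300Classifier(ClassifierMixin, BaseEstimator):
    """Wide-and-deep single-trial P300 detector trained with FTRL-Proximal.

    Parameters
    ----------
    use_wide, use_deep : bool
        Enable the logistic-regression (memorizing) branch and/or the CNN
        (generalizing) branch. Both by default.
    use_sparse : bool
        When False, participant attributes are ignored entirely (no one-hot
        block, no crosses, no embedding row) — the participant-blind
        configuration, e.g. a plain CNN when combined with use_wide=False.
    alpha, beta, l1, l2 : float
        FTRL-Proximal hyperparameters (per-coordinate learning rate scale and
        offset, L1 and L2 strengths).
    n_passes, batch_size : int
        Mini-batch training schedule.
    cross : {"pairwise", "none"} or CrossSpec
        Which cross-product features the wide branch sees.
    deep_optimizer : {"ftrl", "adaptive"}
        Optimizer for the deep branch; "ftrl" (default) uses FTRL for every
        parameter, "adaptive" switches the deep branch to Adagrad.
    leaky_slope : float
        Negative slope of the LeakyReLU activations.
    random_state : int
        Seeds weight initialization and batch shuffling.

    Attributes
    ----------
    model_ : CombinedModel
        The fitted parameters of both branches.
    loss_curve_ : list of float
        Mean training logistic loss per pass.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        use_wide: bool = True,
        use_deep: bool = True,
        use_sparse: bool = True,
        alpha: float = 0.05,
        beta: float = 1.0,
        l1: float = 1e-5,
        l2: float = 1e-4,
        n_passes: int = 3,
        batch_size: int = 64,
        cross="pairwise",
        deep_optimizer: str = "ftrl",
        leaky_slope: float = 0.01,
        random_state: int = 0,
    ):
        self.use_wide = use_wide
        self.use_deep = use_deep
        self.use_sparse = use_sparse
        self.alpha = alpha
        self.beta = beta
        self.l1 = l1
        self.l2 = l2
        self.n_passes = n_passes
        self.batch_size = batch_size
        self.cross = cross
        self.deep_optimizer = deep_optimizer
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] % 90 != 0:
                raise ValueError(f"cannot reshape {X.shape} into (n, channels, 90)")
            X = X.reshape(len(X), -1, 90)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, channels, samples), got shape {X.shape}")
        return X

    def _cross_spec(self, feature_spec: SparseFeatureSpec) -> CrossSpec:
        if isinstance(self.cross, CrossSpec):
            return self.cross
        if self.cross == "pairwise":
            return CrossSpec.pairwise(feature_spec)
        if self.cross == "none":
            return CrossSpec.none(feature_spec)
        raise ValueError(f"cross must be 'pairwise', 'none' or a CrossSpec, got {self.cross!r}")

    def _resolve(self, subject_ids, n, extra_profiles=None):
        """Per-epoch ids and a profile map covering them."""
        ids = list(subject_ids) if subject_ids is not None else [""] * n
        if len(ids) == 1 and n > 1:
            ids = ids * n
        if len(ids) != n:
            raise ValueError(f"{len(ids)} subject ids for {n} epochs")
        profs = dict(getattr(self, "profile_map_", {}))
        profs.update(_as_profile_map(extra_profiles))
        for sid in ids:
            if sid not in profs:
                profs[sid] = AnonymousProfile(subject_id=str(sid))
        return ids, profs

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, subject_ids=None, profiles=None):
        """Fit on epochs ``X`` with binary labels ``y``.

        ``profiles`` supplies the participant attributes used by the sparse
        features and the embedding; subjects absent from it are treated as
        anonymous. Without any profiles the sparse blocks are empty and the
        model reduces to dense-EEG wide + CNN branches.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")

        self.profile_map_ = _as_profile_map(profiles) if self.use_sparse else {}
        ids, profs = self._resolve(subject_ids, len(X))
        if self.profile_map_:
            feature_spec = SparseFeatureSpec.from_profiles(
                [self.profile_map_[s] for s in self.profile_map_]
            )
        else:
            feature_spec = SparseFeatureSpec.empty()
        self.feature_spec_ = feature_spec

        model = initialize_model(
            feature_spec,
            cross_spec=self._cross_spec(feature_spec),
            seed=self.random_state,
            n_channels=X.shape[1],
            n_samples=X.shape[2],
            leaky_slope=self.leaky_slope,
            use_wide=self.use_wide,
            use_deep=self.use_deep,
        )
        cfg = FtrlConfig(alpha=self.alpha, beta=self.beta, lambda1=self.l1, lambda2=self.l2)
        self.model_, self.loss_curve_ = fit_model(
            model,
            X,
            y,
            ids,
            profs,
            cfg=cfg,
            n_passes=self.n_passes,
            batch_size=self.batch_size,
            seed=self.random_state,
            deep_optimizer=self.deep_optimizer,
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def decision_function(self, X, subject_ids=None, profiles=None) -> np.ndarray:
        """Combined logit (wide + deep + shared bias) per epoch."""
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        ids, profs = self._resolve(subject_ids, len(X), profiles)
        model = self.model_
        enc = {}
        T = model.feature_spec.total_length
        k = model.cross_spec.n_features
        d2 = np.zeros((len(X), T))
        dphi = np.zeros((len(X), k))
        for i, sid in enumerate(ids):
            if sid not in enc:
                enc[sid] = model.encode_profile(profs[sid])
            d2[i], dphi[i] = enc[sid]
        logits = np.full(len(X), model.b)
        if model.wide is not None:
            xw = np.concatenate([X.reshape(len(X), -1), d2, dphi], axis=1)
            logits = logits + xw @ model.wide.w
        if model.deep is not None:
            embed_rows = d2 @ model.deep.embedding
            _, dl, _ = deep_forward_batch(X, embed_rows, model.deep)
            logits = logits + dl
        return logits

    def predict_proba(self, X, subject_ids=None, profiles=None) -> np.ndarray:
        p = sigmoid(self.decision_function(X, subject_ids, profiles))
        return np.column_stack([1.0 - p, p])

    def predict(self, X, subject_ids=None, profiles=None) -> np.ndarray:
        p = self.predict_proba(X, subject_ids, profiles)[:, 1]
        return (p >= 0.5).astype(int)


class SklearnAdapter(ClassifierMixin, BaseEstimator):
    """Run a plain sklearn classifier under the harness contract.

    Flattens epochs to ``(n, channels*samples)`` and ignores subject ids and
    profiles — exactly how a subject-agnostic baseline sees the data.
    """

    def __init__(self, base_estimator=None):
        self.base_estimator = base_estimator

    def fit(self, X, y, subject_ids=None, profiles=None):
        from sklearn.base import clone
        from sklearn.linear_model import LogisticRegression

        base = self.base_estimator if self.base_estimator is not None else LogisticRegression(max_iter=2000)
        self.estimator_ = clone(base)
        X = np.asarray(X, dtype=np.float64)
        self.estimator_.fit(X.reshape(len(X), -1), np.asarray(y))
        self.classes_ = self.estimator_.classes_
        return self

    def predict_proba(self, X, subject_ids=None, profiles=None):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=np.float64)
        return self.estimator_.predict_proba(X.reshape(len(X), -1))

    def predict(self, X, subject_ids=None, profiles=None):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=np.float64)
        return self.estimator_.predict(X.reshape(len(X), -1))
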