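"""scikit-learn-style estimators over the Poisson phylogenetic GLMM.

:class:`PoissonPhyloGLMM` fits one speciation model;
:class:`SpeciationModelSelector` fits all three and applies the DIC
4-unit rule.  Both follow sklearn conventions (``get_params`` /
``set_params``, fitted attributes with a trailing underscore, input
validation in ``fit``), so they compose with pipelines and
cross-validation utilities.  ``X`` is the per-tip time elapsed (Myr) as
a column vector; the phylogenetic covariance is passed to ``fit`` as
``vcv`` (or derived from a dated ``tree``) because it is per-sample
metadata rather than a feature.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import glmm as _glmm
from . import pathstats as _pathstats
from . import selection as _selection
from .glmm import MCMCSettings, ModelSpec, PriorSpec

__all__ = ["PoissonPhyloGLMM", "SpeciationModelSelector"]


def _validate_Xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] != 1:
        raise ValueError(
            "X must be (n_samples, 1): the per-tip time elapsed in Myr"
        )
    if np.any(~np.isfinite(X)) or np.any(X < 0):
        raise ValueError("time elapsed must be finite and >= 0")
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("y must be one count per row of X")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integer counts")
    return X, y


def _resolve_vcv(n, vcv=None, tree=None):
    if vcv is None and tree is None:
        raise ValueError("pass the phylogenetic covariance via vcv= or tree=")
    if vcv is None:
        vcv = _pathstats.phylo_vcv(tree).matrix
    if hasattr(vcv, "matrix"):
        vcv = vcv.matrix
    vcv = np.asarray(vcv, dtype=float)
    if vcv.shape != (n, n):
        raise ValueError(f"vcv must be ({n}, {n}) to match X")
    return vcv


class PoissonPhyloGLMM(RegressorMixin, BaseEstimator):
    """Bayesian log-link Poisson GLMM with a phylogenetic random effect.

    Parameters
    ----------
    form : {"null", "asymptote", "downturn"}
        Fixed-effect shape in time elapsed t: linear, sqrt(t), or
        t + t^2.
    intercept_mode : {"estimated", "fixed_zero", "fixed_one"}
        Whether the latent-scale intercept is a free coefficient or a
        fixed offset.
    priors : PriorSpec, optional
    n_iter, thin, burn_in : int
        MCMC schedule; the defaults retain 450 samples.
    random_state : int, optional

    Attributes
    ----------
    fit_ : ModelFit
        Full chains and diagnostics.
    coef_ : ndarray
        Posterior-mean fixed-effect coefficients.
    dic_, pd_, mean_ess_ : float
    """

    def __init__(
        self,
        form: str = "null",
        intercept_mode: str = "estimated",
        priors: Optional[PriorSpec] = None,
        n_iter: int = 500_000,
        thin: int = 1_000,
        burn_in: int = 50_000,
        random_state: Optional[int] = None,
    ):
        self.form = form
        self.intercept_mode = intercept_mode
        self.priors = priors
        self.n_iter = n_iter
        self.thin = thin
        self.burn_in = burn_in
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(form=self.form, intercept_mode=self.intercept_mode)

    def fit(self, X, y, vcv=None, tree=None):
        """Fit to per-tip times ``X`` (n, 1) and node counts ``y`` (n,)."""
        X, y = _validate_Xy(X, y)
        A = _resolve_vcv(X.shape[0], vcv=vcv, tree=tree)
        spec = self._spec()
        design, offset = _glmm.build_design(X[:, 0], spec)
        settings = MCMCSettings(
            n_iter=self.n_iter, thin=self.thin, burn_in=self.burn_in,
            seed=self.random_state,
        )
        self.fit_ = _glmm.fit_mcmc(
            y, design, offset, A,
            priors=self.priors or PriorSpec(),
            settings=settings, spec=spec,
        )
        self.coef_ = self.fit_.beta_mean
        self.coef_names_ = self.fit_.coef_names
        self.dic_ = self.fit_.dic
        self.pd_ = self.fit_.pd_
        self.ess_ = dict(self.fit_.ess)
        self.mean_ess_ = self.fit_.mean_ess
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Expected node count exp(x'beta + offset) at new times (fixed
        effects only, phylogenetic effect marginalised at 0)."""
        if not hasattr(self, "fit_"):
            raise AttributeError("this estimator is not fitted yet; call fit first")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design, offset = _glmm.build_design(X[:, 0], self._spec())
        return np.exp(design @ self.coef_ + offset)

    def credible_interval(self, level: float = 0.95):
        if not hasattr(self, "fit_"):
            raise AttributeError("this estimator is not fitted yet; call fit first")
        return self.fit_.credible_interval(level)


class SpeciationModelSelector(BaseEstimator):
    """Fit all three speciation models and classify by the DIC rule.

    Attributes (after ``fit``): ``fits_`` (form -> ModelFit), ``dics_``,
    ``best_model_``, ``category_``.
    """

    def __init__(
        self,
        intercept_mode: str = "estimated",
        threshold: float = 4.0,
        priors: Optional[PriorSpec] = None,
        n_iter: int = 500_000,
        thin: int = 1_000,
        burn_in: int = 50_000,
        random_state: Optional[int] = None,
    ):
        self.intercept_mode = intercept_mode
        self.threshold = threshold
        self.priors = priors
        self.n_iter = n_iter
        self.thin = thin
        self.burn_in = burn_in
        self.random_state = random_state

    def fit(self, X, y, vcv=None, tree=None):
        X, y = _validate_Xy(X, y)
        A = _resolve_vcv(X.shape[0], vcv=vcv, tree=tree)
        self.fits_ = {}
        self.dics_ = {}
        for form in _glmm.MODEL_FORMS:
            seed = (
                _glmm.derive_seed(self.random_state, form, self.intercept_mode)
                if self.random_state is not None
                else None
            )
            est = PoissonPhyloGLMM(
                form=form,
                intercept_mode=self.intercept_mode,
                priors=self.priors,
                n_iter=self.n_iter,
                thin=self.thin,
                burn_in=self.burn_in,
                random_state=seed,
            ).fit(X, y, vcv=A)
            self.fits_[form] = est.fit_
            self.dics_[form] = est.dic_
        self.best_model_ = _selection.best_model(self.dics_)
        self.category_ = _selection.classify(self.dics_, threshold=self.threshold)
        self.n_features_in_ = 1
        return self
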