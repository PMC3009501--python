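"""Relaxed variable kernel density estimation and the two-class classifier.

Each training instance s_i carries its own Gaussian kernel whose
bandwidth scales with R(s_i), the Euclidean distance from s_i to its
ks-th nearest same-class neighbour:

    sigma_i = c(m, ks) * beta * R(s_i),
    c(m, ks) = sqrt(pi) / (ks * Gamma(m/2 + 1))**(1/m),

so sparse regions receive wide kernels and dense regions narrow ones.
Each kernel is normalized to unit integral over m-space,

    k_i(v) = (sqrt(pi) * sigma_i)^(-m) * exp(-||v - s_i||^2 / sigma_i^2),

and the density estimate at a query v averages the kernels of the kt
training instances nearest to v (kt = "all" gives the full estimator):

    f(v) = (1/n) * sum_{i in kt-NN(v)} k_i(v).

Classification builds one estimator per class and predicts the class with
the larger prior-weighted density, the prior being the class fraction
|S_j| / sum |S_j|. Exact likelihood ties go to the non-interacting class
(the conservative call in an interaction screen). In high dimension the
kernel normalizer underflows double precision, so all evaluation is done
in the log domain.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln, logsumexp

#: Floor for bandwidths when duplicate instances force R(s_i) = 0.
SIGMA_FLOOR = 1e-12

LABEL_INTERACTING = 1
LABEL_NON_INTERACTING = 0


@dataclasses.dataclass
class RvkdeParams:
    """beta > 0 scales every bandwidth; ks sets the neighbour count that
    defines R(s_i); kt truncates the density sum to the kt instances
    nearest the query ("all" disables truncation)."""

    beta: float = 1.0
    ks: int = 5
    kt: Union[int, str] = "all"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.ks < 1:
            raise ValueError(f"ks must be >= 1, got {self.ks}")
        if self.kt != "all" and (not isinstance(self.kt, int) or self.kt < 1):
            raise ValueError(f"kt must be a positive integer or 'all', got {self.kt}")


def dimension_constant(m: int, ks: int) -> float:
    """c(m, ks) linking the neighbour radius to the kernel bandwidth.

    Derived from the volume of the m-ball of radius R(s_i) that holds the
    ks neighbours (hence the Gamma function); any positive constant gives
    a valid estimator, this default keeps sigma on the scale of the local
    inter-point spacing.
    """
    return np.sqrt(np.pi) * np.exp(-(np.log(ks) + gammaln(m / 2.0 + 1.0)) / m)


@dataclasses.dataclass
class ClassDensityModel:
    """One class's instances with their per-instance adaptive bandwidths."""

    instances: np.ndarray  # (n, m)
    radii: np.ndarray  # (n,) distance to ks-th nearest same-class neighbour
    sigmas: np.ndarray  # (n,) kernel bandwidths
    params: RvkdeParams

    @property
    def n(self) -> int:
        return self.instances.shape[0]

    @property
    def m(self) -> int:
        return self.instances.shape[1]


def fit_density(
    instances: np.ndarray,
    params: RvkdeParams,
    constant: float | None = None,
) -> ClassDensityModel:
    """Compute R(s_i) and sigma_i for every instance.

    ``constant`` overrides c(m, ks) for users who want a different
    radius-to-bandwidth link. Requires n > ks (each instance needs ks
    neighbours besides itself). Duplicate instances can force R(s_i) = 0;
    those bandwidths are floored at a tiny epsilon with a warning.
    """
    X = np.atleast_2d(np.asarray(instances, dtype=float))
    n, m = X.shape
    if n <= params.ks:
        raise ValueError(f"need n > ks, got n={n}, ks={params.ks}")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    # ks-th nearest neighbour distance (1-based among the other instances)
    radii = np.partition(D, params.ks - 1, axis=1)[:, params.ks - 1]
    c = dimension_constant(m, params.ks) if constant is None else constant
    sigmas = c * params.beta * radii
    if np.any(sigmas < SIGMA_FLOOR):
        warnings.warn(
            "duplicate instances produced zero neighbour radii; "
            "bandwidths floored at epsilon",
            RuntimeWarning,
            stacklevel=2,
        )
        sigmas = np.maximum(sigmas, SIGMA_FLOOR)
    return ClassDensityModel(instances=X, radii=radii, sigmas=sigmas, params=params)


def _log_kernels(model: ClassDensityModel, V: np.ndarray) -> np.ndarray:
    """(n_query, n_instance) matrix of log kernel values."""
    d2 = cdist(V, model.instances, "sqeuclidean")
    log_norm = -model.m * np.log(np.sqrt(np.pi) * model.sigmas)  # (n,)
    return log_norm[None, :] - d2 / model.sigmas[None, :] ** 2


def log_density(
    model: ClassDensityModel,
    v: np.ndarray,
    kt: Union[int, str, None] = None,
) -> np.ndarray:
    """log f(v) for one query or a batch of queries.

    Only the kt instances nearest each query contribute; the sum is still
    divided by the full n, so kt = "all" reproduces the complete estimator.
    """
    V = np.atleast_2d(np.asarray(v, dtype=float))
    if V.shape[1] != model.m:
        raise ValueError(f"query dimension {V.shape[1]} != model dimension {model.m}")
    if kt is None:
        kt = model.params.kt
    logk = _log_kernels(model, V)
    if kt != "all" and kt < model.n:
        d = cdist(V, model.instances)
        keep = np.argpartition(d, kt - 1, axis=1)[:, :kt]
        rows = np.arange(V.shape[0])[:, None]
        logk = logk[rows, keep]
    out = logsumexp(logk, axis=1) - np.log(model.n)
    return out if np.asarray(v).ndim > 1 else out[0]


def density(
    model: ClassDensityModel,
    v: np.ndarray,
    kt: Union[int, str, None] = None,
) -> np.ndarray:
    """f(v); thin exponential wrapper over :func:`log_density`."""
    return np.exp(log_density(model, v, kt))


class RvkdeClassifier:
    """Two-class maximum-likelihood classifier over per-class estimators.

    Likelihood_j(v) = (|S_j| / sum |S_j|) * f_j(v); the predicted label is
    the argmax, with exact ties resolved to non-interacting. Features are
    z-scored with training statistics by default (count features on very
    different scales make raw Euclidean distance fragile); disable with
    ``standardize=False``.
    """

    def __init__(self, params: RvkdeParams, standardize: bool = True):
        self.params = params
        self.standardize = standardize
        self._models: dict[int, ClassDensityModel] = {}
        self._log_priors: dict[int, float] = {}
        self._mu: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    @property
    def is_fitted(self) -> bool:
        return bool(self._models)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RvkdeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if set(classes) != {LABEL_NON_INTERACTING, LABEL_INTERACTING}:
            raise ValueError("training data must contain both classes (labels 0/1)")
        if self.standardize:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._scale = np.where(sd > 0, sd, 1.0)
        else:
            self._mu = np.zeros(X.shape[1])
            self._scale = np.ones(X.shape[1])
        Z = (X - self._mu) / self._scale
        total = len(y)
        for cls in (LABEL_NON_INTERACTING, LABEL_INTERACTING):
            Zc = Z[y == cls]
            self._models[cls] = fit_density(Zc, self.params)
            self._log_priors[cls] = np.log(Zc.shape[0] / total)
        return self

    def _check_fitted(self) -> None:
        if not self.is_fitted:
            raise RuntimeError("classifier has not been fitted")

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        """(n_query, 2) log prior-weighted class densities, column j = class j."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self._mu) / self._scale
        out = np.empty((Z.shape[0], 2))
        for cls in (LABEL_NON_INTERACTING, LABEL_INTERACTING):
            out[:, cls] = self._log_priors[cls] + log_density(self._models[cls], Z)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels: interacting iff its likelihood strictly exceeds the other."""
        ll = self.log_likelihoods(X)
        return (ll[:, LABEL_INTERACTING] > ll[:, LABEL_NON_INTERACTING]).astype(int)

    def classify(self, v: np.ndarray) -> tuple[int, dict[int, float]]:
        """Label and per-class log-likelihoods for a single query."""
        ll = self.log_likelihoods(np.atleast_2d(v))[0]
        label = int(ll[LABEL_INTERACTING] > ll[LABEL_NON_INTERACTING])
        return label, {
            LABEL_NON_INTERACTING: float(ll[LABEL_NON_INTERACTING]),
            LABEL_INTERACTING: float(ll[LABEL_INTERACTING]),
        }
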