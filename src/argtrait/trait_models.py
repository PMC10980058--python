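"""Effect-size distribution models.

A :class:`TraitModel` specifies the distribution from which per-site raw
effect sizes are drawn: five univariate families (``normal``, ``t``,
``fixed``, ``exponential``, ``gamma``) plus the multivariate normal for
pleiotropic traits, where each causal site receives a correlated vector of
effect sizes, one per trait.

Exponential and gamma effects are non-negative by default; passing
``negative_allowed=True`` flips the sign of each draw independently with
probability one half, giving a symmetric heavy-one-sided architecture.

The ``t`` family is location–scale: draws are ``mean + sqrt(var) * T(df)``
so that ``mean``/``var`` keep the same meaning across families (``var`` is
the squared scale, not the variance of the t itself).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TraitModel",
    "NormalModel",
    "TModel",
    "FixedModel",
    "ExponentialModel",
    "GammaModel",
    "MultivariateNormalModel",
    "trait_model",
    "draw_effects",
    "trait_model_from_dict",
]

_PSD_TOL = 1e-8


def _as_rng(rng_or_seed):
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


class TraitModel:
    """Base class for effect-size distributions.

    Subclasses implement :meth:`sample`, returning an
    ``(n_sites, num_traits)`` array of raw effect sizes.
    """

    family: str
    num_traits: int = 1

    def sample(self, n_sites, rng):
        raise NotImplementedError

    def __repr__(self):
        params = ", ".join(
            f"{k}={v!r}" for k, v in self.__dict__.items() if not k.startswith("_")
        )
        return f"{type(self).__name__}({params})"


class NormalModel(TraitModel):
    family = "normal"

    def __init__(self, mean=0.0, var=1.0):
        if var <= 0:
            raise ValueError(f"var must be positive, got {var}")
        self.mean = float(mean)
        self.var = float(var)

    def sample(self, n_sites, rng):
        rng = _as_rng(rng)
        return rng.normal(self.mean, np.sqrt(self.var), size=(n_sites, 1))


class TModel(TraitModel):
    family = "t"

    def __init__(self, mean=0.0, var=1.0, df=None):
        if var <= 0:
            raise ValueError(f"var must be positive, got {var}")
        if df is None or df <= 0:
            raise ValueError(f"df must be positive, got {df}")
        self.mean = float(mean)
        self.var = float(var)
        self.df = float(df)

    def sample(self, n_sites, rng):
        rng = _as_rng(rng)
        t = rng.standard_t(self.df, size=(n_sites, 1))
        return self.mean + np.sqrt(self.var) * t


class FixedModel(TraitModel):
    """Degenerate distribution: every draw equals ``value`` exactly."""

    family = "fixed"

    def __init__(self, value=None):
        if value is None:
            raise ValueError("fixed model requires a value")
        self.value = float(value)

    def sample(self, n_sites, rng):
        return np.full((n_sites, 1), self.value)


class _SignedPositiveModel(TraitModel):
    def __init__(self, negative_allowed=False):
        self.negative_allowed = bool(negative_allowed)

    def _positive_sample(self, n_sites, rng):
        raise NotImplementedError

    def sample(self, n_sites, rng):
        rng = _as_rng(rng)
        draws = self._positive_sample(n_sites, rng)
        if self.negative_allowed:
            signs = np.where(rng.random(size=draws.shape) < 0.5, -1.0, 1.0)
            draws = draws * signs
        return draws


class ExponentialModel(_SignedPositiveModel):
    family = "exponential"

    def __init__(self, scale=None, negative_allowed=False):
        if scale is None or scale <= 0:
            raise ValueError(f"scale must be positive, got {scale}")
        super().__init__(negative_allowed)
        self.scale = float(scale)

    def _positive_sample(self, n_sites, rng):
        return rng.exponential(self.scale, size=(n_sites, 1))


class GammaModel(_SignedPositiveModel):
    family = "gamma"

    def __init__(self, shape=None, scale=None, negative_allowed=False):
        if shape is None or shape <= 0:
            raise ValueError(f"shape must be positive, got {shape}")
        if scale is None or scale <= 0:
            raise ValueError(f"scale must be positive, got {scale}")
        super().__init__(negative_allowed)
        self.shape = float(shape)
        self.scale = float(scale)

    def _positive_sample(self, n_sites, rng):
        return rng.gamma(self.shape, self.scale, size=(n_sites, 1))


class MultivariateNormalModel(TraitModel):
    """Pleiotropic model: one k-vector of effects per causal site.

    The covariance matrix must be symmetric positive semi-definite
    (smallest eigenvalue ≥ −1e−8 after symmetry check).
    """

    family = "multivariate_normal"

    def __init__(self, mean=None, cov=None):
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if mean.ndim != 1:
            raise ValueError("mean must be a 1-d vector")
        k = mean.shape[0]
        if cov.shape != (k, k):
            raise ValueError(f"cov must be {k}x{k}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=_PSD_TOL):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -_PSD_TOL:
            raise ValueError("cov must be positive semi-definite")
        self.mean = mean
        self.cov = cov
        self.num_traits = k

    def sample(self, n_sites, rng):
        rng = _as_rng(rng)
        return rng.multivariate_normal(
            self.mean, self.cov, size=n_sites, method="svd"
        )


_FAMILIES = {
    m.family: m
    for m in (
        NormalModel,
        TModel,
        FixedModel,
        ExponentialModel,
        GammaModel,
        MultivariateNormalModel,
    )
}


def trait_model(family, **parameters):
    """Build a validated :class:`TraitModel`.

    >>> model = trait_model("normal", mean=0, var=1)
    >>> model.num_traits
    1
    """
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown model family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
    return cls(**parameters)


def trait_model_from_dict(spec):
    """Build a model from a plain mapping, e.g. parsed from a config file.

    The mapping must contain a ``family`` key; all other keys are passed as
    distribution parameters.
    """
    spec = dict(spec)
    try:
        family = spec.pop("family")
    except KeyError:
        raise ValueError("model specification needs a 'family' key") from None
    return trait_model(family, **spec)


def draw_effects(model, n_sites, rng_or_seed=None):
    """Draw raw effect sizes: an ``(n_sites, model.num_traits)`` array.

    Draws are independent across sites; for the multivariate normal each
    site receives one vector across traits.  Reproducible given the same
    seed or generator state.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    out = model.sample(int(n_sites), _as_rng(rng_or_seed))
    out = np.asarray(out, dtype=float)
    assert out.shape == (n_sites, model.num_traits)
    return out
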