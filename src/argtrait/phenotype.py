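"""Environmental noise and phenotype assembly.

The phenotype of individual ``j`` for a trait is ``Y_j = G_j + E_j`` where
``G_j`` is the additive genetic value and the environmental noise is drawn
as ``E_j ~ Normal(0, V_G (1 - h2) / h2)``.  ``V_G`` is the sample variance
(denominator n−1) of the genetic values across the individuals receiving
phenotypes and ``h2`` is the narrow-sense heritability supplied by the
user, so that in expectation a fraction ``h2`` of the phenotypic variance
is genetic.

``h2 = 1`` yields a purely genetic trait (noise identically zero);
``h2 = 0`` is rejected rather than read as infinite noise.  Noise for each
trait of a pleiotropic model comes from an independent stream split off
the master seed, so adding a trait never perturbs another trait's noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effect_sim import sim_trait
from .genetic_value import genetic_values

__all__ = ["sim_env", "sim_phenotype", "PhenotypeResult", "PHENOTYPE_COLUMNS"]

PHENOTYPE_COLUMNS = [
    "individual_id",
    "trait_id",
    "genetic_value",
    "environmental_noise",
    "phenotype",
]

#: Default narrow-sense heritability, a typical value for complex traits.
DEFAULT_H2 = 0.3


@dataclass
class PhenotypeResult:
    """Return value of :func:`sim_phenotype`: the two result tables."""

    effects: pd.DataFrame
    phenotypes: pd.DataFrame


def _split_rng(rng_or_seed, n):
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed.spawn(n)
    ss = np.random.SeedSequence(rng_or_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def sim_env(gvalues, h2=DEFAULT_H2, random_seed=None):
    """Add heritability-calibrated environmental noise to genetic values.

    Parameters
    ----------
    gvalues : pandas.DataFrame
        Columns ``individual_id, trait_id, genetic_value`` (the output of
        :func:`argtrait.genetic_values`).
    h2 : float or sequence of float
        Narrow-sense heritability in (0, 1], scalar or one value per trait.
    random_seed : int or numpy.random.Generator, optional

    Returns
    -------
    pandas.DataFrame
        Columns ``individual_id, trait_id, genetic_value,
        environmental_noise, phenotype`` with ``phenotype = genetic_value +
        environmental_noise`` exactly, row by row.
    """
    trait_ids = sorted(gvalues["trait_id"].unique())
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (len(trait_ids),))
    if np.any((h2 <= 0) | (h2 > 1)):
        raise ValueError(f"h2 must lie in (0, 1], got {h2}")

    streams = _split_rng(random_seed, len(trait_ids))
    frames = []
    for t, h, rng in zip(trait_ids, h2, streams):
        sub = gvalues[gvalues["trait_id"] == t].copy()
        g = sub["genetic_value"].to_numpy()
        if h == 1:
            env = np.zeros(len(sub))
        else:
            v_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
            if not v_g > 0:
                raise ValueError(
                    f"trait {t}: V_G = 0 with h2 = {h} < 1; environmental "
                    "variance V_G*(1-h2)/h2 is undefined without genetic variance"
                )
            env = rng.normal(0.0, np.sqrt(v_g * (1.0 - h) / h), size=len(sub))
        sub["environmental_noise"] = env
        sub["phenotype"] = g + env
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["individual_id", "trait_id"], ignore_index=True)[
        PHENOTYPE_COLUMNS
    ]


def sim_phenotype(
    ts,
    model,
    *,
    num_causal=None,
    causal_sites=None,
    alpha=0.0,
    h2=DEFAULT_H2,
    random_seed=None,
):
    """One-call pipeline: effect sizes -> genetic values -> phenotypes.

    Composes :func:`argtrait.sim_trait`, :func:`argtrait.genetic_values`
    and :func:`argtrait.sim_env`; with defaults, a single causal site is
    chosen at random and no frequency scaling is applied.  Fully
    reproducible given ``random_seed``.

    Returns a :class:`PhenotypeResult` holding the effect and phenotype
    tables.
    """
    trait_rng, env_rng = _split_rng(random_seed, 2)
    effects = sim_trait(
        ts,
        model,
        num_causal=num_causal,
        causal_sites=causal_sites,
        alpha=alpha,
        random_seed=trait_rng,
    )
    gvalues = genetic_values(ts, effects)
    phenotypes = sim_env(gvalues, h2=h2, random_seed=env_rng)
    return PhenotypeResult(effects=effects, phenotypes=phenotypes)
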