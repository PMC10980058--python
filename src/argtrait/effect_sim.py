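"""Causal-site selection, causal-allele assignment and effect-size scaling.

This is the ``sim_trait`` stage: pick causal sites (randomly, or as given
by the user), pick the causal allele at each, draw raw effect sizes from a
:class:`~argtrait.trait_models.TraitModel`, and optionally apply the
frequency-dependent alpha scaling

    beta_scaled = beta_raw * (2 p (1 - p))^(alpha / 2)

where ``p`` is the causal-allele frequency among haploid sample nodes.
Negative alpha gives rare alleles larger effects; ``alpha = 0`` (the
default) leaves effects untouched.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from . import arg_core
from .trait_models import draw_effects

__all__ = [
    "select_causal_sites",
    "choose_causal_allele",
    "scale_effect",
    "sim_trait",
    "EFFECT_COLUMNS",
]

EFFECT_COLUMNS = [
    "site_id",
    "position",
    "causal_allele",
    "trait_id",
    "beta_raw",
    "allele_freq",
    "beta_scaled",
]


def _eligible_sites(ts):
    # Sites carrying at least one mutation; mutation-free sites can never
    # generate genetic variance and are excluded from random selection.
    counts = np.bincount(ts.tables.mutations.site, minlength=ts.num_sites)
    return np.flatnonzero(counts > 0)


def select_causal_sites(ts, num_causal=None, rng=None):
    """Sample causal site ids uniformly without replacement.

    ``num_causal`` defaults to 1.  Only sites with at least one mutation
    are eligible.  Returned ids are in position order.
    """
    if num_causal is None:
        num_causal = 1
    if num_causal < 1:
        raise ValueError(f"num_causal must be >= 1, got {num_causal}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eligible = _eligible_sites(ts)
    if num_causal > eligible.size:
        raise ValueError(
            f"num_causal={num_causal} exceeds the {eligible.size} sites "
            "carrying at least one mutation"
        )
    chosen = rng.choice(eligible, size=num_causal, replace=False)
    # tskit site ids are position-sorted, so sorting ids sorts positions
    return sorted(int(s) for s in chosen)


def _derived_candidates(ts, site_id):
    site = ts.site(site_id)
    seen = []
    for mut in site.mutations:
        if mut.derived_state != site.ancestral_state and mut.derived_state not in seen:
            seen.append(mut.derived_state)
    return site, seen


def choose_causal_allele(ts, site_id, rng=None):
    """Pick the causal allele uniformly among distinct derived states.

    The ancestral state is never causal; silent mutations (derived equal to
    ancestral, e.g. pure back mutations) are not candidates.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    site, candidates = _derived_candidates(ts, site_id)
    if not candidates:
        raise ValueError(
            f"site {site_id} has no derived allele differing from its "
            f"ancestral state {site.ancestral_state!r}"
        )
    return candidates[int(rng.integers(len(candidates)))]


def scale_effect(beta_raw, p, alpha):
    """Apply frequency-dependent scaling ``beta * (2 p (1-p))^(alpha/2)``.

    With ``alpha = 0`` the raw effect is returned unchanged (exactly, for
    any ``p``).  For nonzero alpha the causal-allele frequency must lie
    strictly inside (0, 1).
    """
    if alpha == 0:
        return beta_raw
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            f"frequency-dependent scaling (alpha={alpha}) requires 0 < p < 1"
        )
    out = np.asarray(beta_raw, dtype=float) * (2.0 * p * (1.0 - p)) ** (alpha / 2.0)
    return out if out.ndim else float(out)


def _load_causal_table(causal_sites):
    if isinstance(causal_sites, (str, pathlib.Path)):
        return pd.read_csv(causal_sites, dtype={"causal_allele": str})
    if isinstance(causal_sites, pd.DataFrame):
        return causal_sites.copy()
    return pd.DataFrame(causal_sites)


def _resolve_explicit(ts, causal_sites, num_traits):
    """Validate a user causal-site table.

    Sites are given by ``site_id`` or exact ``position``; optional columns
    ``causal_allele`` and ``beta_raw`` (with ``trait_id`` when the model
    has several traits) override random choices.  Returns
    ``(site_ids, alleles, betas)`` with unspecified entries ``None``.
    """
    df = _load_causal_table(causal_sites)
    if "site_id" in df.columns:
        site_ids = df["site_id"].astype(int).tolist()
        for s in site_ids:
            if not 0 <= s < ts.num_sites:
                raise ValueError(f"causal site {s} does not exist")
    elif "position" in df.columns:
        positions = {ts.site(s).position: s for s in range(ts.num_sites)}
        site_ids = []
        for pos in df["position"]:
            if float(pos) not in positions:
                raise ValueError(f"no site at position {pos}")
            site_ids.append(positions[float(pos)])
    else:
        raise ValueError("causal-site table needs a 'site_id' or 'position' column")
    alleles = {}
    if "causal_allele" in df.columns:
        for s, a in zip(site_ids, df["causal_allele"]):
            if pd.isna(a):
                continue
            site, candidates = _derived_candidates(ts, s)
            if a not in candidates:
                raise ValueError(
                    f"allele {a!r} is not a segregating derived state at site {s}"
                )
            alleles[s] = a

    betas = {}
    if "beta_raw" in df.columns:
        if num_traits > 1 and "trait_id" not in df.columns:
            raise ValueError(
                "user effect sizes for a multi-trait model need a 'trait_id' column"
            )
        trait_ids = (
            df["trait_id"].astype(int)
            if "trait_id" in df.columns
            else pd.Series(0, index=df.index)
        )
        for s, t, b in zip(site_ids, trait_ids, df["beta_raw"]):
            if pd.isna(b):
                continue
            if not 0 <= t < num_traits:
                raise ValueError(f"trait_id {t} out of range for {num_traits} traits")
            betas[(s, int(t))] = float(b)

    unique_ids = sorted(set(site_ids))
    return unique_ids, alleles, betas


def sim_trait(ts, model, *, num_causal=None, causal_sites=None, alpha=0.0, random_seed=None):
    """Simulate effect sizes for an ARG.

    Parameters
    ----------
    ts : tskit.TreeSequence
        The ARG (see :func:`argtrait.load_arg`).
    model : TraitModel
        Distribution of raw effect sizes.
    num_causal : int, optional
        Number of causal sites to choose uniformly at random (default 1).
        Mutually exclusive with ``causal_sites``.
    causal_sites : DataFrame, path or records, optional
        Explicit causal sites (``site_id`` or ``position``; optional
        ``causal_allele``, ``beta_raw`` and, for multi-trait models,
        ``trait_id``).
    alpha : float
        Strength of frequency dependence; 0 disables scaling.
    random_seed : int or numpy.random.Generator, optional

    Returns
    -------
    pandas.DataFrame
        One row per (causal site x trait), ordered by (position,
        trait_id), with columns ``site_id, position, causal_allele,
        trait_id, beta_raw, allele_freq, beta_scaled``.
    """
    if num_causal is not None and causal_sites is not None:
        raise ValueError("num_causal and causal_sites are mutually exclusive")
    rng = (
        random_seed
        if isinstance(random_seed, np.random.Generator)
        else np.random.default_rng(random_seed)
    )
    k = model.num_traits

    user_alleles, user_betas = {}, {}
    if causal_sites is not None:
        site_ids, user_alleles, user_betas = _resolve_explicit(ts, causal_sites, k)
    else:
        site_ids = select_causal_sites(ts, num_causal, rng)

    alleles = [
        user_alleles.get(s, None) or choose_causal_allele(ts, s, rng)
        for s in site_ids
    ]
    betas = draw_effects(model, len(site_ids), rng)
    for (s, t), b in user_betas.items():
        betas[site_ids.index(s), t] = b

    rows = []
    for i, (s, allele) in enumerate(zip(site_ids, alleles)):
        p = arg_core.allele_frequency(ts, s, allele)
        position = ts.site(s).position
        for t in range(k):
            raw = float(betas[i, t])
            rows.append(
                (s, position, allele, t, raw, p, float(scale_effect(raw, p, alpha)))
            )
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)
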