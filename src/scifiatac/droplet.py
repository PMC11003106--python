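"""Droplet occupancy reconstruction and analytic barcode-collision rates.

A droplet holding k pre-indexed nuclei loses identity information only when
two of them drew the same Tn5 well — a birthday problem over the 96 wells.
From the retained (bead, well) combinations this module reconstructs the
occupancy distribution, evaluates the same-well collision probability per
occupancy (exactly, for uniform or non-uniform well loading), aggregates it
into a dataset-level expected collision fraction, and corrects an observed
cross-genotype collision rate for the invisible same-genotype collisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CollisionEstimate:
    per_k_prob: dict[int, float]  # P(>=2 of k nuclei share a well)
    per_k_fraction: dict[int, float]  # expected fraction of the k colliding
    dataset_rate: float  # nucleus-weighted expected collision fraction
    mean_occupancy: float
    occupancy: dict[int, int] = field(default_factory=dict)


def droplet_occupancy(combos: pd.DataFrame) -> tuple[pd.Series, float, pd.DataFrame]:
    """Occupancy from retained (bead, well) combinations.

    Returns (histogram indexed by k, mean occupancy, per-bead table with
    column ``k``). Occupancy is the number of distinct retained wells of a
    bead barcode — a lower bound on the true nucleus count, since nuclei
    colliding in the same well are indistinguishable.
    """
    if combos.empty:
        return pd.Series(dtype=np.int64), float("nan"), pd.DataFrame(
            columns=["bead", "k"]
        )
    per_bead = (
        combos.groupby("bead", observed=True)["well"]
        .nunique()
        .rename("k")
        .reset_index()
    )
    hist = per_bead["k"].value_counts().sort_index()
    return hist, float(per_bead["k"].mean()), per_bead


def _elementary_symmetric(p: np.ndarray, k: int) -> float:
    """e_k over well probabilities by the O(W*k) DP recurrence."""
    e = np.zeros(k + 1)
    e[0] = 1.0
    for x in p:
        e[1 : k + 1] = e[1 : k + 1] + x * e[0:k]
    return float(e[k])


def same_well_collision_prob(
    k: int,
    n_wells: int = 96,
    well_probs: np.ndarray | None = None,
    n_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """P(at least two of k independently well-assigned nuclei share a well).

    Uniform wells: 1 - prod_{i<k} (W - i)/W. Non-uniform: 1 - k! e_k(p),
    with the elementary symmetric polynomial computed exactly for k <= 10
    and by seeded Monte Carlo beyond.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k <= 1:
        return 0.0
    if well_probs is None:
        if k > n_wells:
            return 1.0
        i = np.arange(k)
        return float(1.0 - np.prod((n_wells - i) / n_wells))
    p = np.asarray(well_probs, dtype=float)
    if (p < 0).any():
        raise ValueError("well_probs must be non-negative")
    s = p.sum()
    if abs(s - 1.0) > 1e-9:
        warnings.warn("well_probs not normalised; normalising", stacklevel=2)
        p = p / s
    nz = p[p > 0]
    if k > len(nz):
        return 1.0
    if k <= 10:
        from math import factorial

        return float(1.0 - factorial(k) * _elementary_symmetric(nz, k))
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(p), size=(n_draws, k), p=p)
    distinct = np.array([len(np.unique(row)) for row in draws])
    return float((distinct < k).mean())


def expected_colliding_fraction(
    k: int, n_wells: int = 96, well_probs: np.ndarray | None = None
) -> float:
    """Expected fraction of k nuclei that share their well with another.

    By linearity of expectation this is exact for every k:
    1 - sum_w p_w (1 - p_w)^(k-1), reducing to 1 - (1 - 1/W)^(k-1) for
    uniform wells.
    """
    if k <= 1:
        return 0.0
    if well_probs is None:
        return float(1.0 - (1.0 - 1.0 / n_wells) ** (k - 1))
    p = np.asarray(well_probs, dtype=float)
    s = p.sum()
    if abs(s - 1.0) > 1e-9:
        warnings.warn("well_probs not normalised; normalising", stacklevel=2)
        p = p / s
    return float(1.0 - np.sum(p * (1.0 - p) ** (k - 1)))


def dataset_collision_rate(
    occupancy: pd.Series | dict,
    n_wells: int = 96,
    well_probs: np.ndarray | None = None,
) -> CollisionEstimate:
    """Nucleus-level expected collision fraction over an occupancy mixture.

    occupancy maps k -> droplet count (or probability); the dataset rate is
    sum_k P(k) k q(k) / sum_k P(k) k with q(k) the expected colliding
    fraction at occupancy k. Pass a single-key mapping (e.g. {4: 1.0}) for
    the fixed-occupancy variant.
    """
    occ = pd.Series(occupancy, dtype=float).sort_index()
    if occ.empty or occ.sum() <= 0:
        raise ValueError("occupancy distribution is empty")
    if (occ < 0).any():
        raise ValueError("occupancy weights must be non-negative")
    w = occ / occ.sum()
    ks = occ.index.to_numpy()
    q = {int(k): expected_colliding_fraction(int(k), n_wells, well_probs) for k in ks}
    prob = {
        int(k): same_well_collision_prob(int(k), n_wells, well_probs) for k in ks
    }
    num = sum(w[k] * k * q[int(k)] for k in ks)
    den = sum(w[k] * k for k in ks)
    mean_k = float(den)
    return CollisionEstimate(
        per_k_prob=prob,
        per_k_fraction=q,
        dataset_rate=float(num / den),
        mean_occupancy=mean_k,
        occupancy={int(k): int(v) for k, v in occ.items()},
    )


def total_collision_from_observed(observed_rate: float, genotype_fractions) -> float:
    """Correct an observed cross-genotype collision rate for same-genotype
    collisions.

    Only mixtures of different genotypes are observable; with pool fractions
    f_g, a random collision is cross-genotype with probability
    1 - sum f_g^2, so total = observed / (1 - sum f_g^2). For two equal
    genotypes this doubles the observed rate.
    """
    f = np.asarray(genotype_fractions, dtype=float)
    if len(f) < 2:
        raise ValueError("need >= 2 genotype fractions")
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("genotype fractions must sum to 1")
    if not 0.0 <= observed_rate <= 1.0:
        raise ValueError("observed_rate must lie in [0, 1]")
    denom = 1.0 - float(np.sum(f**2))
    if denom <= 0:
        raise ValueError("degenerate genotype fractions")
    return observed_rate / denom


def well_probs_from_counts(combos: pd.DataFrame, n_wells: int = 96) -> np.ndarray:
    """Empirical well-loading distribution from retained nucleus counts."""
    counts = combos["well"].value_counts().reindex(
        np.arange(1, n_wells + 1), fill_value=0
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("no retained combos")
    return (counts / total).to_numpy()


def collision_report(
    combos: pd.DataFrame,
    n_wells: int = 96,
    uniform_wells: bool = False,
) -> dict:
    """End-to-end JSON-ready report from a retained-combo table."""
    hist, mean_k, _ = droplet_occupancy(combos)
    probs = None if uniform_wells else well_probs_from_counts(combos, n_wells)
    est = dataset_collision_rate(hist, n_wells, probs)
    return {
        "mean_occupancy": mean_k,
        "occupancy_histogram": {int(k): int(v) for k, v in hist.items()},
        "per_k_collision_prob": est.per_k_prob,
        "per_k_colliding_fraction": est.per_k_fraction,
        "dataset_collision_rate": est.dataset_rate,
    }
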