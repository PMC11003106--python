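"""Genotype assignment, barcode-collision detection and contamination.

Each candidate nucleus accumulates allele counts at homozygous biallelic
SNPs that distinguish the pooled genotypes. Counts are modelled per
informative read: a singlet of genotype g yields a matching allele with
probability 1 - eps (eps the conservative per-read sequencing error rate,
default 0.05), while a barcode collision — two nuclei of different genotypes
sharing both the droplet and the Tn5 well — yields an equal mixture. With
flat priors the Bayes posterior is the normalised likelihood; the winning
hypothesis is the call, requiring at least ``min_reads`` informative reads
(default 50). The contamination of a called singlet is the fraction of its
informative reads that carry another genotype's allele — an estimate of
index-hopping cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

COLLISION = "collision"
UNASSIGNED = "unassigned"
OTHER = "other"


@dataclass
class GenotypeModelParams:
    epsilon: float = 0.05
    min_reads: int = 50
    priors: np.ndarray | None = None  # over [genotypes..., collision]; flat if None
    mixture_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.priors is not None:
            p = np.asarray(self.priors, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("priors must be a distribution")
            self.priors = p


def count_alleles(
    reads: pd.DataFrame,
    snps: pd.DataFrame,
    genotype_labels,
    barcode_col: str = "barcode",
) -> pd.DataFrame:
    """Per-cell informative-read counts for each genotype.

    ``reads`` carries one row per read with ``snp_id`` (row index into
    ``snps``; -1 for reads overlapping no SNP) and ``snp_allele`` (0 = ref,
    1 = alt, the observed allele at the read's first overlapped SNP).
    A read contributes one count to the genotype whose allele it carries;
    reads matching no genotype, or whose allele is shared by several pooled
    genotypes (uninformative at that SNP), are ignored.

    Returns a DataFrame indexed by barcode with one column per genotype plus
    ``n`` (their sum).
    """
    labels = list(genotype_labels)
    snps = snps.reset_index(drop=True)
    for g in labels:
        if g not in snps.columns:
            raise ValueError(f"SNP table lacks allele column for {g!r}")
    inf = reads[reads["snp_id"] >= 0]
    sid = inf["snp_id"].to_numpy()
    obs_alt = inf["snp_allele"].to_numpy() == 1
    obs_base = np.where(
        obs_alt, snps["alt"].to_numpy()[sid], snps["ref"].to_numpy()[sid]
    )
    match = np.stack(
        [snps[g].to_numpy()[sid] == obs_base for g in labels], axis=1
    )
    unique = match.sum(axis=1) == 1
    geno_idx = match.argmax(axis=1)
    tab = (
        pd.DataFrame(
            {
                "barcode": inf[barcode_col].to_numpy()[unique],
                "genotype": np.asarray(labels, dtype=object)[geno_idx[unique]],
            }
        )
        .groupby(["barcode", "genotype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=labels, fill_value=0)
    )
    tab.columns.name = None
    tab["n"] = tab[labels].sum(axis=1)
    return tab


def _hypothesis_probs(labels, epsilon: float, mixture_weight: float):
    """Per-read allele probabilities under each hypothesis.

    Rows: one singlet hypothesis per genotype, then the collision
    hypotheses (every unordered genotype pair, equal mixture). Columns:
    probability that an informative read carries each genotype's allele.
    """
    k = len(labels)
    hyps, names = [], []
    for i, g in enumerate(labels):
        p = np.full(k, epsilon / (k - 1) if k > 1 else 0.0)
        p[i] = 1.0 - epsilon
        hyps.append(p)
        names.append(g)
    w = mixture_weight
    for i, j in combinations(range(k), 2):
        if k == 2:
            p = np.array([w, 1.0 - w])
        else:
            p = np.full(k, epsilon / (k - 2))
            p[i] = w * (1.0 - epsilon)
            p[j] = (1.0 - w) * (1.0 - epsilon)
        hyps.append(p)
        names.append(COLLISION)
    return np.asarray(hyps), names


def call_genotypes(
    counts: pd.DataFrame,
    params: GenotypeModelParams | None = None,
    genotype_labels=None,
) -> pd.DataFrame:
    """Posterior genotype/collision calls for a table of allele counts.

    ``counts`` is the output of :func:`count_alleles` (index barcode, one
    column per genotype, column ``n``). Likelihoods are per-read products
    evaluated in log space; with k > 2 genotypes the collision hypothesis is
    the best equal-mixture pair. The posterior over {each genotype,
    collision} is returned together with the argmax call, which is
    ``unassigned`` when n < min_reads or when the maximum is tied.
    """
    params = params or GenotypeModelParams()
    labels = list(genotype_labels) if genotype_labels is not None else [
        c for c in counts.columns if c != "n"
    ]
    if len(labels) < 2:
        raise ValueError("need at least two genotypes")
    k = len(labels)
    X = counts[labels].to_numpy(dtype=np.int64)
    n = X.sum(axis=1)

    probs, hyp_names = _hypothesis_probs(labels, params.epsilon, params.mixture_weight)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    logp[np.isneginf(logp)] = -745.0  # exp underflows to 0 exactly
    loglik = X @ logp.T  # (cells, hypotheses)

    # collapse the pair hypotheses into one collision column via their max
    is_coll = np.array([h == COLLISION for h in hyp_names])
    ll = np.concatenate(
        [loglik[:, ~is_coll], loglik[:, is_coll].max(axis=1, keepdims=True)],
        axis=1,
    )
    hyp_out = labels + [COLLISION]
    priors = (
        np.full(k + 1, 1.0 / (k + 1)) if params.priors is None else params.priors
    )
    if len(priors) != k + 1:
        raise ValueError("priors must cover each genotype plus collision")
    with np.errstate(divide="ignore"):
        ll = ll + np.log(priors)
    m = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - m)
    post /= post.sum(axis=1, keepdims=True)

    best = post.argmax(axis=1)
    best_p = post.max(axis=1)
    tied = (np.isclose(post, best_p[:, None], rtol=0, atol=1e-12).sum(axis=1)) > 1
    call = np.asarray(hyp_out, dtype=object)[best]
    call[tied] = UNASSIGNED
    call[n < params.min_reads] = UNASSIGNED

    out = pd.DataFrame(index=counts.index)
    out["call"] = call
    out["n"] = n
    for i, h in enumerate(hyp_out):
        out[f"p_{h}"] = post[:, i]
    out["posterior_max"] = best_p
    out.loc[out["call"] == UNASSIGNED, "posterior_max"] = np.nan
    out["contamination"] = contamination_rate(counts, out["call"], labels)
    return out


def genotype_posterior(
    counts_row: pd.Series | dict,
    params: GenotypeModelParams | None = None,
    genotype_labels=None,
) -> pd.Series:
    """Single-cell convenience wrapper around :func:`call_genotypes`."""
    df = pd.DataFrame([dict(counts_row)])
    labels = genotype_labels or [c for c in df.columns if c != "n"]
    df["n"] = df[list(labels)].sum(axis=1)
    return call_genotypes(df, params, labels).iloc[0]


def contamination_rate(
    counts: pd.DataFrame, calls: pd.Series | np.ndarray, genotype_labels
) -> np.ndarray:
    """Fraction of informative reads not matching the called genotype.

    Defined for singlet calls only; collision/unassigned cells get NaN.
    """
    labels = list(genotype_labels)
    X = counts[labels].to_numpy(dtype=float)
    n = X.sum(axis=1)
    calls = np.asarray(calls, dtype=object)
    out = np.full(len(counts), np.nan)
    for i, g in enumerate(labels):
        m = (calls == g) & (n > 0)
        out[m] = (n[m] - X[m, i]) / n[m]
    return out


def assign_expected_genotype(
    counts: pd.DataFrame,
    barcode_wells: pd.Series | dict,
    well_samples: dict[int, str],
    params: GenotypeModelParams | None = None,
    genotype_labels=None,
) -> pd.DataFrame:
    """Multiplexed-mode calls against the genotype expected from the Tn5 well.

    Each cell's expected genotype comes from its well's sample label; reads
    not carrying the expected allele are pooled as "another genotype" and
    the binomial machinery tests expected-singlet (match prob 1 - eps)
    against other-singlet (eps) and equal-mixture collision. For a cell
    called as its expected genotype the mismatch fraction is the
    index-hopping contamination estimate.
    """
    params = params or GenotypeModelParams()
    labels = list(genotype_labels) if genotype_labels is not None else [
        c for c in counts.columns if c != "n"
    ]
    wells = pd.Series(barcode_wells)
    missing = set(wells.unique()) - set(well_samples)
    if missing:
        raise ValueError(f"wells without sample label: {sorted(missing)}")
    expected = wells.map(well_samples)
    expected = expected.reindex(counts.index)
    if expected.isna().any():
        raise ValueError("barcodes without a well assignment")

    X = counts[labels].to_numpy(dtype=np.int64)
    n = X.sum(axis=1)
    exp_idx = np.array([labels.index(g) for g in expected])
    n_match = X[np.arange(len(X)), exp_idx]

    eps, w = params.epsilon, params.mixture_weight
    p_match = np.array([1.0 - eps, eps, w])  # expected, other, collision
    hyp = np.array([0, 1, 2])
    ll = (
        n_match[:, None] * np.log(p_match)[None, :]
        + (n - n_match)[:, None] * np.log(1.0 - p_match)[None, :]
    )
    m = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - m)
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    tied = (np.isclose(post, post.max(axis=1)[:, None], rtol=0, atol=1e-12).sum(axis=1)) > 1

    call = np.empty(len(X), dtype=object)
    call[best == 0] = expected.to_numpy()[best == 0]
    call[best == 1] = OTHER
    call[best == 2] = COLLISION
    call[tied | (n < params.min_reads)] = UNASSIGNED

    contam = np.full(len(X), np.nan)
    ok = (call == expected.to_numpy()) & (n > 0)
    contam[ok] = (n[ok] - n_match[ok]) / n[ok]
    return pd.DataFrame(
        {
            "expected_genotype": expected.to_numpy(),
            "call": call,
            "n": n,
            "n_match": n_match,
            "p_expected": post[:, 0],
            "p_other": post[:, 1],
            "p_collision": post[:, 2],
            "contamination": contam,
        },
        index=counts.index,
    )
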