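"""Binomial/Bayes genotype calls, collision detection, contamination."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scifiatac import genotype
from scifiatac.genotype import (
    COLLISION,
    OTHER,
    UNASSIGNED,
    GenotypeModelParams,
    assign_expected_genotype,
    call_genotypes,
    contamination_rate,
    count_alleles,
    genotype_posterior,
)
from scifiatac.synthetic import SimulationDesign, simulate_experiment


def _counts(**kw):
    df = pd.DataFrame([kw])
    df["n"] = df.sum(axis=1)
    return df


def test_pure_singlet_called_confidently():
    out = genotype_posterior({"A": 100, "B": 0})
    assert out["call"] == "A"
    assert out["p_A"] > 0.999


def test_even_mixture_called_collision():
    out = genotype_posterior({"A": 50, "B": 50})
    assert out["call"] == COLLISION
    assert out["p_collision"] > 0.999


def test_low_coverage_unassigned():
    assert genotype_posterior({"A": 49, "B": 0})["call"] == UNASSIGNED
    assert genotype_posterior({"A": 0, "B": 0})["call"] == UNASSIGNED


def test_posteriors_sum_to_one():
    out = call_genotypes(_counts(A=80, B=20))
    assert out[["p_A", "p_B", "p_collision"]].iloc[0].sum() == pytest.approx(1.0)


def test_calls_invariant_under_label_permutation():
    df = pd.DataFrame({"A": [90, 40, 55], "B": [10, 60, 45]})
    df["n"] = df.sum(axis=1)
    swapped = df.rename(columns={"A": "B", "B": "A"})
    a = call_genotypes(df, genotype_labels=["A", "B"])
    b = call_genotypes(swapped, genotype_labels=["A", "B"])
    remap = {"A": "B", "B": "A", COLLISION: COLLISION, UNASSIGNED: UNASSIGNED}
    assert [remap[c] for c in a["call"]] == list(b["call"])


def test_likelihood_matches_per_read_brute_force():
    """Log-likelihoods equal the sum of per-read log-probabilities, n <= 20."""
    eps, labels = 0.05, ["A", "B", "C"]
    params = GenotypeModelParams(epsilon=eps, min_reads=1)
    for nA, nB, nC in [(20, 0, 0), (9, 8, 3), (5, 5, 5), (0, 2, 18)]:
        df = pd.DataFrame({"A": [nA], "B": [nB], "C": [nC]})
        df["n"] = nA + nB + nC
        out = call_genotypes(df, params, labels)
        # brute force: singlet-A prob per read
        reads = ["A"] * nA + ["B"] * nB + ["C"] * nC
        def singlet_ll(g):
            return sum(
                np.log(1 - eps if r == g else eps / 2) for r in reads
            )
        def pair_ll(g, h):
            return sum(
                np.log((1 - eps) / 2 if r in (g, h) else eps) for r in reads
            )
        lls = [singlet_ll(g) for g in labels]
        lls.append(max(pair_ll(g, h) for g, h in itertools.combinations(labels, 2)))
        post = np.exp(lls - np.max(lls))
        post /= post.sum()
        expected = [f"p_{g}" for g in labels] + ["p_collision"]
        np.testing.assert_allclose(
            out[expected].iloc[0].to_numpy(), post, atol=1e-9
        )


def test_contamination_arithmetic():
    counts = _counts(A=97, B=3)
    assert contamination_rate(counts, np.array(["A"]), ["A", "B"])[0] == pytest.approx(
        0.03
    )
    assert np.isnan(
        contamination_rate(counts, np.array([COLLISION]), ["A", "B"])[0]
    )


def test_count_alleles_matches_brute_force(small_exp, small_fragments_with_barcode):
    ref = small_exp.reference
    f = small_fragments_with_barcode.head(30_000)
    counts = count_alleles(f, ref.snps, ref.genotype_labels)
    # brute force per-read lookup
    snps = ref.snps.reset_index(drop=True)
    tally: dict[tuple, int] = {}
    for r in f.itertuples():
        if r.snp_id < 0:
            continue
        obs = snps.at[r.snp_id, "alt"] if r.snp_allele == 1 else snps.at[r.snp_id, "ref"]
        matches = [g for g in ref.genotype_labels if snps.at[r.snp_id, g] == obs]
        if len(matches) == 1:
            tally[(r.barcode, matches[0])] = tally.get((r.barcode, matches[0]), 0) + 1
    for (bc, g), v in tally.items():
        assert counts.at[bc, g] == v
    assert counts[list(ref.genotype_labels)].to_numpy().sum() == sum(tally.values())


def test_reads_without_snp_ignored(small_ref):
    reads = pd.DataFrame(
        {"barcode": ["c"] * 3, "snp_id": [-1, -1, -1], "snp_allele": [-1, -1, -1]}
    )
    counts = count_alleles(reads, small_ref.snps, small_ref.genotype_labels)
    assert counts.empty or counts["n"].sum() == 0


def test_noiseless_singlets_have_zero_contamination(small_ref):
    design = SimulationDesign(
        n_nuclei=150, hopping_rate=0.0, seq_error=0.0, seed=17
    )
    exp = simulate_experiment(small_ref, design, with_reads=False)
    f = exp.fragments
    f = f.assign(barcode=f["nucleus"])  # exact per-nucleus cells
    counts = count_alleles(f, small_ref.snps, small_ref.genotype_labels)
    calls = call_genotypes(counts)
    singlets = calls[calls["call"].isin(small_ref.genotype_labels)]
    assert len(singlets) > 100
    assert (singlets["contamination"] == 0.0).all()
    truth = exp.truth.nuclei.set_index("nucleus")["genotype"]
    assert (truth.loc[singlets.index] == singlets["call"]).all()


def test_singlet_and_doublet_calibration():
    """>= 99% correct on model-matched singlets, >= 95% on 50/50 doublets."""
    rng = np.random.default_rng(5)
    n = rng.integers(50, 301, size=2000)
    singlet = pd.DataFrame({"A": rng.binomial(n, 0.95)})
    singlet["B"] = n - singlet["A"]
    singlet["n"] = n
    calls = call_genotypes(singlet)
    assert (calls["call"] == "A").mean() >= 0.99
    doublet = pd.DataFrame({"A": rng.binomial(n, 0.5)})
    doublet["B"] = n - doublet["A"]
    doublet["n"] = n
    calls = call_genotypes(doublet)
    assert (calls["call"] == COLLISION).mean() >= 0.95


def test_expected_genotype_multiplexed_path():
    counts = pd.DataFrame(
        {"G1": [98, 50, 10], "G2": [2, 50, 90]},
        index=["cell1", "cell2", "cell3"],
    )
    counts["n"] = counts[["G1", "G2"]].sum(axis=1)
    wells = pd.Series({"cell1": 1, "cell2": 1, "cell3": 2})
    well_samples = {1: "G1", 2: "G2"}
    out = assign_expected_genotype(counts, wells, well_samples)
    assert out.loc["cell1", "call"] == "G1"
    assert out.loc["cell1", "contamination"] == pytest.approx(0.02)
    assert out.loc["cell2", "call"] == COLLISION  # 50/50 expected vs other
    assert out.loc["cell3", "call"] == "G2"
    assert out.loc["cell3", "contamination"] == pytest.approx(0.10)


def test_expected_genotype_requires_labelled_wells():
    counts = pd.DataFrame({"G1": [10], "G2": [0]}, index=["c"])
    counts["n"] = 10
    with pytest.raises(ValueError):
        assign_expected_genotype(counts, pd.Series({"c": 5}), {1: "G1"})


def test_multiplexed_simulation_assigns_every_candidate(small_ref):
    """An 8-sample plate map gives every nucleus exactly one expected label."""
    well_sample_map = {w: f"S{(w - 1) % 8 + 1}" for w in range(1, 97)}
    labels = tuple(sorted(set(well_sample_map.values())))
    from scifiatac.synthetic import make_reference

    ref8 = make_reference(
        seed=23,
        chrom_lengths={"chr1": 1_200_000},
        organelle_lengths={},
        n_genes=60,
        n_acrs=240,
        genotype_labels=labels,
    )
    design = SimulationDesign(
        n_nuclei=120, well_sample_map=well_sample_map, seed=31, hopping_rate=0.0
    )
    exp = simulate_experiment(ref8, design, with_reads=False)
    truth = exp.truth.nuclei
    assert (
        truth["genotype"] == truth["well"].map(well_sample_map)
    ).all()


def test_params_validation():
    with pytest.raises(ValueError):
        GenotypeModelParams(epsilon=0.6)
    with pytest.raises(ValueError):
        GenotypeModelParams(min_reads=0)
    with pytest.raises(ValueError):
        GenotypeModelParams(priors=[0.5, 0.2])
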