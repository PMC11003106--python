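"""Synthetic pre-indexed droplet scATAC-seq experiments with ground truth.

Emulates the data-generating process of a combinatorial fluidic indexing
ATAC experiment: nuclei are pre-indexed with one of 96 two-sided Tn5 well
barcodes, then overloaded into droplets so that occupied droplets carry a
zero-truncated-Poisson number of nuclei. Each nucleus emits Tn5 fragments
whose density is elevated inside accessible chromatin regions (ACRs) and
near transcription start sites; a configurable fraction of fragments lands
on organelle scaffolds. Reads can acquire a wrong bead barcode (index
hopping) and SNP-overlapping reads can report the wrong allele (sequencing
error). A complete truth table is kept so every downstream stage —
demultiplexing, QC, genotype/collision calling, occupancy modelling — can be
scored against the simulation.

Sequences outside barcodes and SNP positions are placeholder bases; quality
scores are constant. Neither matters to any consumer in this package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import (
    DEFAULT_A_BARCODES,
    DEFAULT_B_BARCODES,
    MOSAIC_END,
    WellMap,
    build_well_map,
)

_BASES = np.array(list("ACGT"))

DEFAULT_CHROM_LENGTHS = {"chr1": 6_000_000, "chr2": 4_000_000}
DEFAULT_ORGANELLE_LENGTHS = {"scaf_organelle1": 200_000}


@dataclass
class SyntheticReference:
    """A small genome with genes, ACRs and a homozygous biallelic SNP panel.

    Organelle scaffolds carry no genes, ACRs or SNPs; they exist only to
    receive the organelle-derived fragment background that the QC filter
    screens out.
    """

    chromosomes: dict[str, int]
    organelles: dict[str, int]
    genes: pd.DataFrame  # chrom, start, end, strand (0-based half-open)
    acrs: pd.DataFrame  # chrom, start, end
    snps: pd.DataFrame  # chrom, pos, ref, alt, one allele column per genotype
    genotype_labels: tuple[str, ...]

    @property
    def all_scaffolds(self) -> dict[str, int]:
        return {**self.chromosomes, **self.organelles}

    @property
    def tss(self) -> pd.DataFrame:
        """Transcription start sites: gene start on +, end-1 on - strand."""
        if self.genes.empty:
            return pd.DataFrame(columns=["chrom", "pos"])
        pos = np.where(
            self.genes["strand"].to_numpy() == "+",
            self.genes["start"].to_numpy(),
            self.genes["end"].to_numpy() - 1,
        )
        return pd.DataFrame({"chrom": self.genes["chrom"].to_numpy(), "pos": pos})

    def validate(self) -> None:
        for df, what in ((self.genes, "gene"), (self.acrs, "ACR")):
            for chrom, grp in df.groupby("chrom", observed=True):
                if chrom not in self.chromosomes:
                    raise ValueError(f"{what} on unknown chromosome {chrom}")
                L = self.chromosomes[chrom]
                if (grp["start"] < 0).any() or (grp["end"] > L).any():
                    raise ValueError(f"{what} outside chromosome {chrom}")
        for chrom in self.snps["chrom"].unique():
            if chrom not in self.chromosomes:
                raise ValueError(f"SNP on unknown chromosome {chrom}")
        if len(self.genotype_labels) >= 2 and len(self.snps):
            cols = self.snps[list(self.genotype_labels)].to_numpy()
            if (cols[:, :1] == cols).all(axis=1).any():
                raise ValueError("SNP identical across all genotypes")


def make_reference(
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    organelle_lengths: dict[str, int] | None = None,
    n_genes: int = 300,
    n_acrs: int = 1200,
    genotype_labels=("B73", "Mo17"),
    snp_rate: float = 0.0007,
    gene_length: tuple[int, int] = (1000, 3000),
    acr_width: int = 500,
    acr_tss_fraction: float = 0.7,
) -> SyntheticReference:
    """Build a deterministic synthetic reference.

    SNP counts per chromosome are Binomial(length, snp_rate); 0.0007/bp
    matches the ~0.70/kb density of a maize inbred panel. Genes are
    non-overlapping; a fraction of ACRs is centred near gene TSSs so that
    fragment enrichment in ACRs also produces TSS enrichment, as in real
    chromatin.
    """
    if snp_rate < 0:
        raise ValueError("snp_rate must be >= 0")
    if not genotype_labels:
        raise ValueError("need at least one genotype label")
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    organelle_lengths = dict(organelle_lengths or DEFAULT_ORGANELLE_LENGTHS)
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    total = lens.sum()

    # genes: apportion per chromosome by length, then drop them without
    # overlap by splitting the leftover space into random gaps
    gene_rows = []
    per_chrom = np.floor(n_genes * lens / total).astype(int)
    per_chrom[: n_genes - per_chrom.sum()] += 1
    for c, L, ng in zip(chroms, lens, per_chrom):
        if ng == 0:
            continue
        glens = rng.integers(gene_length[0], gene_length[1] + 1, size=ng)
        slack = L - glens.sum()
        if slack < 0:
            raise ValueError(f"chromosome {c} too short for {ng} genes")
        cuts = np.sort(rng.integers(0, slack + 1, size=ng))
        starts = cuts + np.concatenate(([0], np.cumsum(glens[:-1])))
        strands = rng.choice(["+", "-"], size=ng)
        for s, gl, st in zip(starts, glens, strands):
            gene_rows.append((c, int(s), int(s + gl), st))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand"])

    # ACRs: a fraction sits at gene TSSs, the rest is uniform background
    acr_rows = []
    if n_acrs > 0:
        n_tss_acr = int(round(acr_tss_fraction * n_acrs)) if len(genes) else 0
        if n_tss_acr:
            gi = rng.integers(0, len(genes), size=n_tss_acr)
            tss = np.where(
                genes["strand"].to_numpy()[gi] == "+",
                genes["start"].to_numpy()[gi],
                genes["end"].to_numpy()[gi] - 1,
            )
            centers = tss + rng.integers(-200, 201, size=n_tss_acr)
            for c, ctr in zip(genes["chrom"].to_numpy()[gi], centers):
                L = chrom_lengths[c]
                s = int(np.clip(ctr - acr_width // 2, 0, max(L - acr_width, 0)))
                acr_rows.append((c, s, s + acr_width))
        for _ in range(n_acrs - n_tss_acr):
            ci = rng.choice(len(chroms), p=lens / total)
            L = lens[ci]
            if L <= acr_width:
                raise ValueError(f"chromosome {chroms[ci]} too short for ACRs")
            s = int(rng.integers(0, L - acr_width))
            acr_rows.append((chroms[ci], s, s + acr_width))
    acrs = pd.DataFrame(acr_rows, columns=["chrom", "start", "end"])

    # SNPs: Binomial(L, rate) per chromosome, unique positions, each SNP
    # homozygous-distinct: exactly one genotype carries the alt allele
    snp_rows = []
    for c, L in zip(chroms, lens):
        n_snp = rng.binomial(L, snp_rate)
        pos = np.sort(rng.choice(L, size=n_snp, replace=False))
        refs = rng.integers(0, 4, size=n_snp)
        alts = (refs + rng.integers(1, 4, size=n_snp)) % 4
        alt_carrier = rng.integers(0, len(genotype_labels), size=n_snp)
        for p, r, a, g in zip(pos, refs, alts, alt_carrier):
            alleles = [_BASES[r]] * len(genotype_labels)
            alleles[g] = _BASES[a]
            snp_rows.append((c, int(p), _BASES[r], _BASES[a], *alleles))
    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref", "alt", *genotype_labels]
    )
    ref = SyntheticReference(
        chromosomes=chrom_lengths,
        organelles=organelle_lengths,
        genes=genes,
        acrs=acrs,
        snps=snps,
        genotype_labels=tuple(genotype_labels),
    )
    ref.validate()
    return ref


@dataclass
class SimulationDesign:
    """Parameters of one simulated experiment.

    Defaults mirror an overloaded two-genotype run: mean two nuclei per
    occupied droplet, uniform well loading across the 96-well plate, ~1000
    fragments per nucleus (≈2000 Tn5 insertion sites), 2% index hopping and
    a 5% per-informative-read allele error.
    """

    n_nuclei: int = 5000
    lambda_droplet: float = 2.0
    well_weights: np.ndarray | None = None  # length n_wells, sums to 1
    n_wells: int = 96
    well_sample_map: dict[int, str] | None = None  # multiplexed mode
    fragments_per_nucleus: float = 1000.0
    fragment_dispersion: float = 8.0  # gamma shape; larger = tighter
    hopping_rate: float = 0.02
    seq_error: float = 0.05
    barcode_error_rate: float = 0.001  # per-base error on barcode sequences
    organelle_fraction: float = 0.05
    acr_enrichment: float = 5.0
    frag_size_means: tuple[float, float] = (80.0, 200.0)  # NFR, mononucleosome
    frag_size_sds: tuple[float, float] = (25.0, 35.0)
    nfr_weight: float = 0.6
    duplication_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_droplet <= 0:
            raise ValueError("lambda_droplet must be > 0")
        if not 0.0 <= self.hopping_rate < 1.0:
            raise ValueError("hopping_rate must lie in [0, 1)")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")


@dataclass
class SimTruth:
    """Ground truth: one row per nucleus, plus truth columns on fragments."""

    nuclei: pd.DataFrame  # nucleus, droplet, bead_barcode, well, genotype, n_fragments
    bead_barcodes: np.ndarray  # droplet index -> 16-mer


@dataclass
class SimulatedExperiment:
    fragments: pd.DataFrame
    reads: pd.DataFrame | None
    truth: SimTruth
    reference: SyntheticReference
    design: SimulationDesign
    well_map: WellMap

    def fragment_bed(self) -> pd.DataFrame:
        """BED6+ fragment table with the combined '<bead>-<well>' barcode
        as observed (i.e. after any index hopping)."""
        f = self.fragments
        beads = self.truth.bead_barcodes[f["droplet_obs"].to_numpy()]
        barcode = pd.Series(beads) + "-" + f["well"].astype(str).to_numpy()
        return pd.DataFrame(
            {
                "chrom": f["chrom"].to_numpy(),
                "start": f["start"].to_numpy(),
                "end": f["end"].to_numpy(),
                "barcode": barcode.to_numpy(),
                "count": 1,
                "strand": "+",
            }
        )


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via rejection of zeros."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 16) -> np.ndarray:
    while True:
        mat = rng.integers(0, 4, size=(n, length))
        seqs = np.array(["".join(s) for s in _BASES[mat]], dtype=object)
        if len(np.unique(seqs)) == n:
            return seqs


def _inject_errors(
    rng: np.random.Generator, seqs: np.ndarray, rate: float
) -> np.ndarray:
    """Per-base substitution errors on an array of equal-length sequences."""
    if rate <= 0 or len(seqs) == 0:
        return seqs.copy()
    L = len(seqs[0])
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    codes = np.searchsorted(np.sort([b"A", b"C", b"G", b"T"]), mat)
    err = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=mat.shape)
    codes = np.where(err, (codes + shift) % 4, codes)
    flat = _BASES[codes.ravel()]
    return np.array(
        ["".join(row) for row in flat.reshape(len(seqs), L)], dtype=object
    )


def simulate_experiment(
    ref: SyntheticReference,
    design: SimulationDesign,
    with_reads: bool = True,
) -> SimulatedExperiment:
    """Run one experiment: droplet loading, fragment emission, hopping and
    allele errors, with a complete per-fragment truth table.

    ``with_reads=False`` skips materialising the per-read barcode-sequence
    table (all fragment-level consumers are unaffected); use it for large
    designs where only fragment records are needed.
    """
    rng = np.random.default_rng(design.seed)
    n_wells = design.n_wells
    well_p = (
        np.full(n_wells, 1.0 / n_wells)
        if design.well_weights is None
        else np.asarray(design.well_weights, dtype=float)
    )
    if len(well_p) != n_wells or abs(well_p.sum() - 1.0) > 1e-9 or (well_p < 0).any():
        raise ValueError("well_weights must be a distribution over n_wells")

    # -- droplet loading: zero-truncated Poisson occupancy ------------------
    n_drop_guess = max(1, int(design.n_nuclei / design.lambda_droplet))
    occ = _sample_ztp(rng, design.lambda_droplet, n_drop_guess)
    while occ.sum() < design.n_nuclei:
        occ = np.concatenate(
            [occ, _sample_ztp(rng, design.lambda_droplet, n_drop_guess // 4 + 1)]
        )
    cum = np.cumsum(occ)
    n_droplets = int(np.searchsorted(cum, design.n_nuclei) + 1)
    occ = occ[:n_droplets]
    occ[-1] -= int(cum[n_droplets - 1] - design.n_nuclei)
    nucleus_droplet = np.repeat(np.arange(n_droplets, dtype=np.int32), occ)
    bead_barcodes = _random_barcodes(rng, n_droplets)

    # -- nucleus attributes --------------------------------------------------
    n = design.n_nuclei
    wells = rng.choice(n_wells, size=n, p=well_p) + 1
    labels = ref.genotype_labels
    if design.well_sample_map is not None:
        missing = set(np.unique(wells)) - set(design.well_sample_map)
        if missing:
            raise ValueError(f"wells without sample label: {sorted(missing)}")
        genotype = np.array(
            [design.well_sample_map[w] for w in wells], dtype=object
        )
    else:
        genotype = np.asarray(labels, dtype=object)[
            rng.integers(0, len(labels), size=n)
        ]
    lam = rng.gamma(
        design.fragment_dispersion,
        design.fragments_per_nucleus / design.fragment_dispersion,
        size=n,
    )
    n_frags = rng.poisson(lam)

    nuclei = pd.DataFrame(
        {
            "nucleus": np.arange(n),
            "droplet": nucleus_droplet,
            "bead_barcode": bead_barcodes[nucleus_droplet],
            "well": wells,
            "genotype": genotype,
            "n_fragments": n_frags,
        }
    )

    # -- fragment emission (int32 arrays: datasets reach ~2e7 fragments) ----
    frag_nucleus = np.repeat(np.arange(n, dtype=np.int32), n_frags)
    F = len(frag_nucleus)
    chrom_names = list(ref.chromosomes) + list(ref.organelles)
    chrom_lens = np.array(
        [ref.all_scaffolds[c] for c in chrom_names], dtype=np.int64
    )
    n_nuc_chrom = len(ref.chromosomes)
    nuc_lens = chrom_lens[:n_nuc_chrom]
    nuc_total = nuc_lens.sum()

    has_org = len(ref.organelles) > 0 and design.organelle_fraction > 0
    is_org = (
        rng.random(F) < design.organelle_fraction
        if has_org
        else np.zeros(F, dtype=bool)
    )

    chrom_idx = np.empty(F, dtype=np.int16)
    center = np.empty(F, dtype=np.int32)

    # nuclear fragments: ACR-enriched placement
    nuc_mask = ~is_org
    n_nuc = int(nuc_mask.sum())
    acr = ref.acrs
    acr_total = int((acr["end"] - acr["start"]).sum()) if len(acr) else 0
    f_acr = acr_total / nuc_total
    E = design.acr_enrichment
    p_in_acr = E * f_acr / (1.0 - f_acr + E * f_acr) if acr_total else 0.0
    in_acr = rng.random(n_nuc) < p_in_acr
    # uniform background over nuclear chromosomes
    bg = ~in_acr
    ci = rng.choice(n_nuc_chrom, size=int(bg.sum()), p=nuc_lens / nuc_total)
    tmp_chrom = np.empty(n_nuc, dtype=np.int16)
    tmp_center = np.empty(n_nuc, dtype=np.int32)
    tmp_chrom[bg] = ci
    tmp_center[bg] = (rng.random(int(bg.sum())) * nuc_lens[ci]).astype(np.int32)
    del ci, bg
    if in_acr.any():
        widths = (acr["end"] - acr["start"]).to_numpy()
        ai = rng.choice(len(acr), size=int(in_acr.sum()), p=widths / widths.sum())
        chrom_code = {c: i for i, c in enumerate(chrom_names)}
        acr_chrom = acr["chrom"].map(chrom_code).to_numpy()
        tmp_chrom[in_acr] = acr_chrom[ai]
        tmp_center[in_acr] = acr["start"].to_numpy()[ai] + (
            rng.random(int(in_acr.sum())) * widths[ai]
        ).astype(np.int32)
        del ai
    chrom_idx[nuc_mask] = tmp_chrom
    center[nuc_mask] = tmp_center
    del tmp_chrom, tmp_center, in_acr

    if is_org.any():
        org_lens = chrom_lens[n_nuc_chrom:]
        oi = rng.choice(
            len(org_lens), size=int(is_org.sum()), p=org_lens / org_lens.sum()
        )
        chrom_idx[is_org] = (n_nuc_chrom + oi).astype(np.int16)
        center[is_org] = (rng.random(int(is_org.sum())) * org_lens[oi]).astype(
            np.int32
        )
    del is_org, nuc_mask

    # fragment sizes: nucleosome-free + mononucleosome mixture
    comp = rng.random(F) < design.nfr_weight
    size = np.where(
        comp,
        rng.normal(design.frag_size_means[0], design.frag_size_sds[0], size=F),
        rng.normal(design.frag_size_means[1], design.frag_size_sds[1], size=F),
    ).astype(np.int32)
    del comp
    np.clip(size, 25, None, out=size)
    start = center - size // 2
    L_of = chrom_lens[chrom_idx].astype(np.int32)
    np.clip(start, 0, np.maximum(L_of - size, 0), out=start)
    end = np.minimum(start + size, L_of)
    del size, L_of, center

    # -- index hopping: reassign the bead barcode of single fragments.
    # The destination droplet is that of a uniformly chosen other fragment,
    # i.e. hopping probability onto a bead barcode is proportional to its
    # read abundance (free-index concentration scales with library share).
    # This makes the hopped-in read fraction of every cell equal to the
    # hopping rate in expectation, independent of droplet occupancy.
    hopped = (
        rng.random(F) < design.hopping_rate
        if n_droplets > 1
        else np.zeros(F, dtype=bool)
    )
    droplet_true = nucleus_droplet[frag_nucleus]
    droplet_obs = droplet_true.copy()
    if hopped.any():
        nh = int(hopped.sum())
        src = droplet_true[hopped]
        dest = droplet_true[rng.integers(0, F, size=nh)]
        for _ in range(1000):  # reject same-droplet destinations
            same = dest == src
            if not same.any():
                break
            dest[same] = droplet_true[rng.integers(0, F, size=int(same.sum()))]
        else:
            same = dest == src
            alt = rng.integers(0, n_droplets - 1, size=int(same.sum()))
            alt += (alt >= src[same]).astype(alt.dtype)
            dest[same] = alt
        droplet_obs[hopped] = dest

    # -- SNP alleles ---------------------------------------------------------
    snp_allele = np.full(F, -1, dtype=np.int8)  # -1 none, 0 ref, 1 alt
    snp_id = np.full(F, -1, dtype=np.int32)
    allele_err = np.zeros(F, dtype=bool)
    if len(ref.snps):
        snps = ref.snps.reset_index(drop=True)
        chrom_code = {c: i for i, c in enumerate(chrom_names)}
        snp_chrom = snps["chrom"].map(chrom_code).to_numpy()
        snp_pos = snps["pos"].to_numpy()
        # first SNP overlapped by each fragment, chromosome by chromosome
        for c_i in np.unique(snp_chrom):
            s_mask = snp_chrom == c_i
            s_pos = np.sort(snp_pos[s_mask])
            s_orig = np.flatnonzero(s_mask)[np.argsort(snp_pos[s_mask])]
            f_mask = chrom_idx == c_i
            lo = np.searchsorted(s_pos, start[f_mask], side="left")
            hi = np.searchsorted(s_pos, end[f_mask], side="left")
            hit = hi > lo
            ids = np.full(int(f_mask.sum()), -1, dtype=np.int32)
            ids[hit] = s_orig[lo[hit]].astype(np.int32)
            snp_id[f_mask] = ids
            del lo, hi, hit, ids, f_mask
        has = snp_id >= 0
        if has.any():
            is_alt_geno = {
                g: (snps[g] == snps["alt"]).to_numpy() for g in labels
            }
            frag_geno = genotype[frag_nucleus[has]]
            true_alt = np.zeros(int(has.sum()), dtype=bool)
            for g in labels:
                gm = frag_geno == g
                true_alt[gm] = is_alt_geno[g][snp_id[has][gm]]
            flip = rng.random(int(has.sum())) < design.seq_error
            obs_alt = true_alt ^ flip
            snp_allele[has] = obs_alt.astype(np.int8)
            allele_err[has] = flip

    fragments = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(
                chrom_idx, categories=chrom_names
            ),
            "start": start,
            "end": end,
            "nucleus": frag_nucleus,
            "droplet": droplet_true,
            "droplet_obs": droplet_obs,
            "well": wells[frag_nucleus].astype(np.int16),
            "hopped": hopped,
            "snp_id": snp_id,
            "snp_allele": snp_allele,
            "allele_err": allele_err,
        }
    )

    if design.duplication_rate > 0 and F:
        dup = rng.random(F) < design.duplication_rate
        fragments = pd.concat(
            [fragments, fragments[dup]], ignore_index=True
        )

    truth = SimTruth(nuclei=nuclei, bead_barcodes=bead_barcodes)
    well_map = build_well_map(
        DEFAULT_A_BARCODES,
        DEFAULT_B_BARCODES,
        well_samples=design.well_sample_map,
    )

    reads = None
    if with_reads:
        reads = _emit_reads(rng, fragments, truth, design, well_map)

    return SimulatedExperiment(
        fragments=fragments,
        reads=reads,
        truth=truth,
        reference=ref,
        design=design,
        well_map=well_map,
    )


def _emit_reads(
    rng: np.random.Generator,
    fragments: pd.DataFrame,
    truth: SimTruth,
    design: SimulationDesign,
    well_map: WellMap,
) -> pd.DataFrame:
    """One read pair per fragment, with per-base barcode sequencing errors."""
    F = len(fragments)
    well_to_pair = {w: pair for pair, w in well_map.wells.items()}
    wells = fragments["well"].to_numpy()
    a_true = np.array([well_to_pair[w][0] for w in wells], dtype=object)
    b_true = np.array([well_to_pair[w][1] for w in wells], dtype=object)
    bead_true = truth.bead_barcodes[fragments["droplet_obs"].to_numpy()]
    rate = design.barcode_error_rate
    reads = pd.DataFrame(
        {
            "read_id": [f"frag{i}" for i in range(F)],
            "bead_obs": _inject_errors(rng, bead_true, rate),
            "a_obs": _inject_errors(rng, a_true, rate),
            "b_obs": _inject_errors(rng, b_true, rate),
            "bead_true": bead_true,
            "well_true": wells,
            "nucleus": fragments["nucleus"].to_numpy(),
            "hopped": fragments["hopped"].to_numpy(),
        }
    )
    return reads


# ---------------------------------------------------------------------------
# fixture I/O (plain-text; round-trips through the readers below)
# ---------------------------------------------------------------------------

def write_fixtures(
    exp: SimulatedExperiment, directory: str | os.PathLike
) -> dict[str, str]:
    """Write the experiment and its reference as plain-text fixtures.

    Produces: chroms.tsv, genes.tsv, acrs.bed, snps.tsv, fragments.bed,
    truth_nuclei.tsv, and (if reads were emitted) reads_R1.fastq /
    reads_R2.fastq with the bead barcode carried in the read name and the
    inline Tn5 barcode + mosaic end at each insert start.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    ref = exp.reference
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(directory, name)
        return paths[name]

    chroms = pd.DataFrame(
        [(c, l, 0) for c, l in ref.chromosomes.items()]
        + [(c, l, 1) for c, l in ref.organelles.items()],
        columns=["chrom", "length", "is_organelle"],
    )
    chroms.to_csv(_p("chroms.tsv"), sep="\t", index=False)
    ref.genes.to_csv(_p("genes.tsv"), sep="\t", index=False)
    ref.acrs.to_csv(_p("acrs.bed"), sep="\t", index=False, header=False)
    ref.snps.to_csv(_p("snps.tsv"), sep="\t", index=False)
    exp.fragment_bed().to_csv(
        _p("fragments.bed"), sep="\t", index=False, header=False
    )
    exp.truth.nuclei.to_csv(_p("truth_nuclei.tsv"), sep="\t", index=False)

    if exp.reads is not None:
        filler = "A" * 20
        r1 = open(_p("reads_R1.fastq"), "w")
        r2 = open(_p("reads_R2.fastq"), "w")
        with r1, r2:
            for row in exp.reads.itertuples(index=False):
                name = f"{row.read_id}_{row.bead_obs}"
                s1 = row.a_obs + MOSAIC_END + filler
                s2 = row.b_obs + MOSAIC_END + filler
                r1.write(f"@{name}\n{s1}\n+\n{'I' * len(s1)}\n")
                r2.write(f"@{name}\n{s2}\n+\n{'I' * len(s2)}\n")
    return paths


def read_fragments_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6+ fragment file (chrom, start, end, barcode, count, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "barcode", "count", "strand"],
        dtype={"chrom": str, "barcode": str},
    )
    return df


def read_fastq_pairs(r1_path, r2_path) -> pd.DataFrame:
    """Parse paired FASTQ into the read-table convention used by demux."""
    def _parse(path):
        names, seqs = [], []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                names.append(header.strip()[1:])
                seqs.append(seq)
        return names, seqs

    n1, s1 = _parse(r1_path)
    n2, s2 = _parse(r2_path)
    if n1 != n2:
        raise ValueError("R1/R2 read names disagree")
    rid, bead = zip(*(n.rsplit("_", 1) for n in n1)) if n1 else ((), ())
    bclen = len(DEFAULT_A_BARCODES[0])
    return pd.DataFrame(
        {
            "read_id": list(rid),
            "bead_obs": list(bead),
            "a_obs": [s[:bclen] for s in s1],
            "b_obs": [s[:bclen] for s in s2],
            "r1_seq": s1,
            "r2_seq": s2,
        }
    )
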