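"""Call high-quality nuclei from Tn5 insertion sites.

Converts fragments to single-base insertion sites (+4/-5), deduplicates
per cell, computes the four QC metrics, and applies the pass thresholds:
>= 1000 unique sites, >= 20% near TSSs, >= 20% in ACRs, <= 30% organelle.
"""

from scifiatac.insertions import (
    QCThresholds,
    call_nuclei,
    compute_qc,
    dedupe_insertions,
    insertions_from_fragments,
)
from scifiatac.synthetic import SimulationDesign, make_reference, simulate_experiment

ref = make_reference(
    seed=1,
    chrom_lengths={"chr1": 1_500_000, "chr2": 1_000_000},
    organelle_lengths={"scaf_org": 150_000},
    n_genes=80,
    n_acrs=300,
)
design = SimulationDesign(n_nuclei=300, seed=4)
exp = simulate_experiment(ref, design, with_reads=False)

frags = exp.fragment_bed()
sites = dedupe_insertions(insertions_from_fragments(frags))
print(f"{len(frags)} fragments -> {len(sites)} unique insertion sites")

qc = compute_qc(sites, ref.tss, ref.acrs, list(ref.organelles))
called, summary = call_nuclei(qc, QCThresholds())
deep = qc[qc["n_unique_sites"] >= 1000]
print(f"{summary['n_barcodes']} barcodes observed "
      f"(most are trace hopped background), {summary['n_pass']} pass QC")
print(f"deep cells: median sites {deep['n_unique_sites'].median():.0f}, "
      f"mean TSS fraction {deep['frac_tss'].mean():.3f}, "
      f"mean FRiP {deep['frip'].mean():.3f}, "
      f"mean organelle fraction {deep['frac_organelle'].mean():.3f}")
print("A passing nucleus is a genuine cell: sites concentrate near TSSs and "
      "inside ACRs instead of scattering uniformly.")
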