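import numpy as np
import pandas as pd
import pytest

from scifiatac import demux
from scifiatac.synthetic import (
    SimulationDesign,
    make_reference,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_ref():
    """Compact reference whose ACR/TSS density mirrors the default genome."""
    return make_reference(
        seed=11,
        chrom_lengths={"chr1": 1_500_000, "chr2": 1_000_000},
        organelle_lengths={"scaf_org": 150_000},
        n_genes=80,
        n_acrs=300,
    )


@pytest.fixture(scope="session")
def small_exp(small_ref):
    """300-nucleus experiment with reads, default noise processes."""
    design = SimulationDesign(n_nuclei=300, seed=7)
    return simulate_experiment(small_ref, design, with_reads=True)


@pytest.fixture(scope="session")
def small_schema(small_exp):
    return demux.BarcodeSchema(bead_whitelist=tuple(small_exp.truth.bead_barcodes))


@pytest.fixture(scope="session")
def small_fragments_with_barcode(small_exp):
    """Fragment table with the observed combined '<bead>-<well>' barcode."""
    f = small_exp.fragments
    beads = pd.Series(
        small_exp.truth.bead_barcodes[f["droplet_obs"].to_numpy()], index=f.index
    )
    return f.assign(barcode=beads.str.cat(f["well"].astype(str), sep="-"))
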