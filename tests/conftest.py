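import pytest

from isopipe.io_formats import GeneModel
from isopipe.syndata import SimConfig, generate_isotigs, generate_reference_panel


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=42, n_genes=12)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return generate_reference_panel(small_cfg)


@pytest.fixture(scope="session")
def small_isotigs(small_panel, small_cfg):
    return generate_isotigs(small_panel, small_cfg)


@pytest.fixture
def toy_model():
    """Single-exon transcript: 30 bp 5' UTR, 120 bp CDS (ATG..TAA), 30 bp 3' UTR."""
    import numpy as np

    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    utr5 = "".join(bases[rng.integers(0, 4, 30)])
    utr3 = "".join(bases[rng.integers(0, 4, 30)])
    body = "".join(sense[i] for i in rng.integers(0, len(sense), 38))
    seq = utr5 + "ATG" + body + "TAA" + utr3
    return GeneModel(
        "t_toy", "g_toy", "mouse", "chr_toy", [(100, 100 + len(seq))],
        (30, 150), seq, "OG_toy",
    )
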