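import numpy as np
import pytest

import pbscreen as pb


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale two-group screen used by several integration tests."""
    return pb.SimConfig(
        seed=11, n_chroms=2, chrom_length=80_000, n_genes=8,
        n_insertions_per_sample=40, pcr_dup_mean=1.0,
        seq_error_rate=0.0, contaminant_frac=0.0,
        groups=[("tumour", 3), ("metastatic", 3)],
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return pb.run_screen(small_config)


@pytest.fixture()
def toy_genome():
    """A tiny hand-made genome with TTAA motifs at known positions."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGG"))  # no T runs, so no accidental TTAA
    seq = "".join(rng.choice(bases, size=400))
    # plant TTAA at fixed spots
    seq = seq[:100] + "TTAA" + seq[104:200] + "TTAA" + seq[204:]
    return pb.ReferenceGenome({"chrT": seq})
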