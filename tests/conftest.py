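import numpy as np
import pytest

import multiclip as mc


@pytest.fixture(scope="session")
def sim_bundle():
    """One small synthetic dataset shared by read-only tests."""
    tx, truth = mc.simulate_transcriptome(n_genes=80, seed=11)
    pileups, clusters = mc.simulate_parclip(tx, truth, seed=11)
    sites = mc.normalize_tc_per_million(mc.filter_sites(pileups[0], pileups[1], tx))
    return {
        "transcriptome": tx,
        "truth": truth,
        "pileups": pileups,
        "clusters": clusters,
        "sites": sites,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_cluster_table(rng, n, n_transcripts=5, length=2000):
    """Random cluster intervals for oracle comparisons."""
    import pandas as pd

    starts = rng.integers(0, length - 60, size=n)
    widths = rng.integers(10, 60, size=n)
    ends = starts + widths
    peaks = starts + rng.integers(0, widths)
    return pd.DataFrame(
        {
            "transcript_id": [f"T{int(i)}" for i in rng.integers(0, n_transcripts, n)],
            "start": starts,
            "end": ends,
            "tc_sum": rng.integers(0, 12, size=n),
            "max_tc_pos": peaks,
        }
    )
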