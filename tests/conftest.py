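import numpy as np
import pandas as pd
import pytest

from barseq_noise import synthetic_data as sd
from barseq_noise.index_design import build_scheme


@pytest.fixture
def two_lineage_pool():
    return [
        sd.LineageSpec("A" * 26, "reference", 0.0, 0.0, 0.5),
        sd.LineageSpec("C" * 26, "mutant", 0.0, 1.0, 0.5),
    ]


@pytest.fixture
def small_pool():
    return sd.make_pool(
        n_lineages=40, n_reference=10, n_ira1=5, n_gpb2=5, seed=11
    )


@pytest.fixture
def unique8():
    return build_scheme("unique_dual", 8)


def make_readset(scheme, samples=None, reads_per_sample=1000, barcodes=("AAAA", "CCCC", "GGGG"),
                 seed=0):
    """Uniform-frequency read set over the given samples of a scheme."""
    samples = list(scheme.samples) if samples is None else samples
    rng = np.random.default_rng(seed)
    frames = []
    for sid in samples:
        f, n, r, s = scheme.samples[sid]
        bcs = rng.choice(list(barcodes), size=reads_per_sample)
        umis = sd._random_umis(reads_per_sample, 8, rng)
        frames.append(pd.DataFrame({
            "f_idx": f, "n_idx": n, "r_idx": r, "s_idx": s,
            "barcode_id": bcs, "umi": umis,
            "origin_sample": sid, "event": "none", "partner_sample": None,
            "breakpoint_region": None, "hidden": False,
        }))
    df = pd.concat(frames, ignore_index=True)
    return sd.ReadSet(df, scheme=scheme, assignment=dict(scheme.samples))
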