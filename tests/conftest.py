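import numpy as np
import pandas as pd
import pytest

from targetmr.sumstats import (HarmonizedInstrumentSet, Instrument,
                               SumstatsTable)


def make_hset(bx, sx, by, sy, eaf=None):
    """Build a HarmonizedInstrumentSet from plain vectors."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    sx = np.broadcast_to(sx, bx.shape)
    sy = np.broadcast_to(sy, bx.shape)
    eaf = np.broadcast_to(eaf if eaf is not None else 0.3, bx.shape)
    instruments = [
        Instrument(f"rs{i + 1}", float(bx[i]), float(sx[i]), float(by[i]),
                   float(sy[i]), float(eaf[i]))
        for i in range(len(bx))
    ]
    return HarmonizedInstrumentSet("exposure", "outcome", instruments)


@pytest.fixture
def two_instrument_set():
    """The hand-computed worked example: ratios 2.0 and 1.5 with outcome
    weights 1 and 4 give IVW beta 1.6 and Cochran's Q 0.2."""
    return make_hset([0.1, 0.2], [0.01, 0.01], [0.2, 0.3], [0.1, 0.1])


def make_table(trait_id="trait", trait_type="quantitative", **columns):
    """SumstatsTable from keyword column overrides on a 3-SNP template."""
    base = {
        "snp": ["rs1", "rs2", "rs3"],
        "chr": ["1", "1", "2"],
        "pos": [1000, 2000, 3000],
        "a1": ["A", "A", "A"],
        "a2": ["G", "G", "G"],
        "eaf": [0.3, 0.3, 0.3],
        "beta": [0.1, 0.1, 0.1],
        "se": [0.02, 0.02, 0.02],
        "p": [np.nan, np.nan, np.nan],
        "n": [10000, 10000, 10000],
    }
    base.update(columns)
    df = pd.DataFrame(base)
    from scipy import stats
    missing = df["p"].isna()
    df.loc[missing, "p"] = 2 * stats.norm.sf(
        np.abs(df.loc[missing, "beta"] / df.loc[missing, "se"]))
    return SumstatsTable(trait_id, trait_type, df)
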