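import numpy as np
import pandas as pd
import pytest

from bsaqtl.io import TABLE_COLUMNS


def make_table(rows):
    """Allele-count table from (chrom, pos, ref_h, alt_h, ref_l, alt_l) tuples
    with informative opposite-homozygous parents and clean defaults."""
    recs = []
    for chrom, pos, rh, ah, rl, al in rows:
        recs.append(
            {
                "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
                "ref_h": rh, "alt_h": ah, "ref_l": rl, "alt_l": al,
                "parent_h_gt": 2, "parent_l_gt": 0,
                "ph_ref": 0, "ph_alt": 30, "pl_ref": 30, "pl_alt": 0,
                "qual": 60.0, "variant_type": "SNP",
            }
        )
    return pd.DataFrame(recs, columns=TABLE_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
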