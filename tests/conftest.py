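import logging

import numpy as np
import pandas as pd
import pytest

from gxeblup.types import GenotypePanel

logging.getLogger("gxeblup").setLevel(logging.ERROR)


def make_panel(dosage, chrom=None, pos=None, populations=None, ids=None):
    """Tiny genotype panel from a raw dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = (np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos))
    ids = [f"i{k}" for k in range(n)] if ids is None else list(ids)
    pops = ["pop"] * n if populations is None else list(populations)
    loci = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "B"})
    indiv = pd.DataFrame({"id": ids, "population": pops})
    return GenotypePanel(dosage, loci, indiv)


@pytest.fixture
def hwe_panel():
    """500 unrelated individuals, 1000 loci in Hardy-Weinberg proportions."""
    rng = np.random.default_rng(42)
    m = 1000
    p = rng.uniform(0.1, 0.9, size=m)
    dosage = rng.binomial(2, p, size=(500, m)).astype(float)
    return make_panel(dosage)
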