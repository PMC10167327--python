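import numpy as np
import pytest

from spxlab import synthetic
from spxlab.io import ShiftRecord, ShiftTable


@pytest.fixture
def quiet_spec():
    """A SimSpec with all noise switched off (exact forward models)."""
    return synthetic.SimSpec(
        seed=11,
        mst_noise_frac=0.0,
        dsf_noise_frac=0.0,
        relax_noise_frac=0.0,
        rdc_noise_hz=0.0,
    )


@pytest.fixture
def default_spec():
    return synthetic.SimSpec(seed=11)


def make_table(values, isotope_scheme="protonated", aa="A", **extra):
    """ShiftTable from {residue: (dH, dN)} or {residue: dict of fields}."""
    records = []
    for idx in sorted(values):
        v = values[idx]
        if isinstance(v, dict):
            records.append(ShiftRecord(residue_index=idx, aa=v.pop("aa", aa), **v))
        else:
            dh, dn = v
            records.append(
                ShiftRecord(residue_index=idx, aa=aa, dH=dh, dN=dn, **extra)
            )
    return ShiftTable(tuple(records), isotope_scheme=isotope_scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
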