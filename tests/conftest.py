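import numpy as np
import pandas as pd
import pytest

from pmfsa.preprocessing import BDL, MEASURED, MISSING, SpeciatedDataset


def make_dataset(conc, flags=None, mdl=None, species=None, mass_column="PM2.5",
                 start="2020-04-22"):
    """Build a SpeciatedDataset from plain lists for hand-crafted cases."""
    conc = np.asarray(conc, dtype=float)
    n, m = conc.shape
    if species is None:
        species = ["PM2.5"] + [f"S{j}" for j in range(1, m)]
    if flags is None:
        flags = np.full((n, m), MEASURED, dtype=object)
        flags[~np.isfinite(conc)] = MISSING
    else:
        flags = np.asarray(flags, dtype=object)
    if mdl is None:
        mdl = np.full(m, 0.01)
    return SpeciatedDataset(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        dates=pd.date_range(start, periods=n, freq="D"),
        species_names=list(species),
        conc=conc,
        mdl=np.asarray(mdl, dtype=float),
        flags=flags,
        mass_column=mass_column,
    )


@pytest.fixture
def toy_dataset():
    """4 samples x 4 species (mass first), one BDL and one missing cell."""
    conc = [
        [10.0, 5.0, 3.0, 2.0],
        [12.0, 6.0, 4.0, 2.0],
        [8.0, 4.0, np.nan, 1.0],
        [9.0, 5.0, 2.0, np.nan],
    ]
    flags = np.full((4, 4), MEASURED, dtype=object)
    flags[2, 2] = BDL
    flags[3, 3] = MISSING
    return make_dataset(conc, flags=flags, mdl=[0.5, 0.1, 0.12, 0.05])
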