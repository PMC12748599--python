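import numpy as np
import pytest

from borealdist.spectral import AnnualSpectra
from borealdist.validation import load_vilts_matrix


@pytest.fixture(scope="session")
def table_matrix():
    """The packaged photo-interpreted 6-class validation count matrix."""
    return load_vilts_matrix()


def spectra_from_nbr(nbr_values, start_year=2000, total=0.4, missing=None):
    """Build an AnnualSpectra whose NBR series equals `nbr_values` exactly.

    NIR and SWIR2 are derived holding NIR+SWIR2 = total; other bands are
    constants.
    """
    nbr = np.asarray(nbr_values, dtype=float)
    n = nbr.size
    refl = np.tile([0.02, 0.04, 0.03, 0.0, 0.15, 0.0], (n, 1))
    refl[:, 3] = total * (1 + nbr) / 2
    refl[:, 5] = total * (1 - nbr) / 2
    years = np.arange(start_year, start_year + n)
    return AnnualSpectra(years, refl, missing)


@pytest.fixture
def nbr_spectra():
    return spectra_from_nbr
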