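"""ctcspectro: charge-transfer complex spectrophotometry and microwell assay
validation.

Analysis chain for colored 1:1 charge-transfer complexes of an electron-donor
drug with pi-acceptors, observed by UV-vis: band detection, Benesi-Hildebrand
association constants, Tauc band gaps, Job's-method stoichiometry, derived
electronic constants, donor-site ranking from partial charges, ICH-style
calibration/validation statistics for 96-well plate assays, and Analytical
Eco-Scale greenness scoring.  A synthetic-data module generates every input
from known ground truth.
"""

from importlib import resources

from . import characterization, greenness, spectra, synth, validation
from .config import RunConfig

__version__ = "0.1.0"

__all__ = [
    "characterization",
    "greenness",
    "spectra",
    "synth",
    "validation",
    "RunConfig",
    "data_path",
]


def data_path(name: str):
    """Path-like handle to a bundled data fixture (charge table, Eco-Scale
    ledger, scenario parameter files)."""
    return resources.files(__name__).joinpath("data", name)
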