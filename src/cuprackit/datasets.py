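"""Bundled reference datasets.

Two small delimited tables ship with the package so the full pipeline can
be exercised without external files:

* ``solvent_screen.csv`` — the seven-composition methanol/ethanol/water
  simplex screen (triplicate absorbance signals of Trolox per composition).
* ``trolox_calibration.csv`` — the six-level (0-50 uM) triplicate Trolox
  calibration recorded at the optimised methanol/water composition.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mixture import MixtureDesignTable
from .plate import read_calibration, read_design


def _data_path(name: str):
    return resources.files("cuprackit").joinpath("data", name)


def load_solvent_screen_frame() -> pd.DataFrame:
    """The reference solvent-screen design table as a dataframe."""
    with resources.as_file(_data_path("solvent_screen.csv")) as p:
        return read_design(p)


def load_solvent_screen() -> MixtureDesignTable:
    """The reference solvent-screen design as a :class:`MixtureDesignTable`."""
    return MixtureDesignTable.from_dataframe(load_solvent_screen_frame())


def load_trolox_calibration() -> pd.DataFrame:
    """The reference Trolox calibration table (conc_uM, replicate, absorbance)."""
    with resources.as_file(_data_path("trolox_calibration.csv")) as p:
        return read_calibration(p)
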