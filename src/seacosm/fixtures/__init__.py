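"""Packaged reference tables.

Small CSV transcriptions of the published seasonal summary tables used to
seed the synthetic experiments and to check the range-summary arithmetic:

``table1``
    Physicochemical and biological parameters of the initial seawater
    samples per season (temperature, nutrients, chlorophyll, prokaryotic
    abundance, leucine-based production, ...).
``table2``
    In situ contribution of each bacterioplankton group to total
    DAPI-stained cells, as percentages per season (plus a multi-year
    average column), with standard deviations where published.
``table3``
    Minimal and maximal specific growth rates (day^-1) per group for eight
    experiments at the same observatory, the overall Range row, and the
    printed max-min spreads for that row.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fixture"]

_FIXTURES = ("table1", "table2", "table3")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a typed DataFrame."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    with resources.files(__package__).joinpath(f"{name}.csv").open("r") as fh:
        df = pd.read_csv(fh)
    if name == "table1":
        df = df.set_index("variable")
    return df
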