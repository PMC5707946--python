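"""Packaged study data: Three Gorges Reservoir Area wastewater emissions.

Annual emissions of the four main water-pollutant streams in the Three
Gorges Reservoir Area, 2008-2014, from the area's environmental and
ecological monitoring bulletins:

- ``W1`` — industrial wastewater (10^8 tons). The raw industrial record
  (``W1_raw``) is distorted by reporting shocks, so the modelled series is
  its grey strengthening-buffer transform, stored at the 2-decimal
  precision in which it is published; ``W1`` loads as ``buffered=True``.
- ``W2`` — domestic wastewater (10^8 tons).
- ``W3`` — oily wastewater from ships (10^4 tons).
- ``W4`` — domestic wastewater from ships (10^4 tons).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sequences import AnnualSeries, validate

__all__ = ["three_gorges_frame", "three_gorges_series"]

_UNITS = {
    "W1_raw": "10^8 tons",
    "W1": "10^8 tons",
    "W2": "10^8 tons",
    "W3": "10^4 tons",
    "W4": "10^4 tons",
}


def three_gorges_frame() -> pd.DataFrame:
    """The packaged table as a DataFrame (year + five value columns)."""
    ref = resources.files("greycast.data") / "three_gorges_wastewater.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def three_gorges_series() -> dict[str, AnnualSeries]:
    """The packaged table as validated :class:`AnnualSeries`, keyed by label.

    Keys: ``W1_raw`` (unbuffered industrial record), ``W1`` (buffered,
    modelled), ``W2``, ``W3``, ``W4``.
    """
    df = three_gorges_frame()
    start = int(df["year"].iloc[0])
    out = {}
    for col, units in _UNITS.items():
        out[col] = validate(
            AnnualSeries(
                label=col,
                start_year=start,
                values=df[col].to_numpy(dtype=float),
                units=units,
                buffered=(col == "W1"),
            )
        )
    return out
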