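"""Shared state-space constants for the aging-chain model.

The population aged 20+ is split into six age bands and three health
states: NDM (no diabetes), DM (diabetes, not on dialysis) and DMDi
(on dialysis due to diabetic nephropathy).  Dialysis stocks exist only
from age 40 upward; younger dialysis patients are outside the model.
"""

from __future__ import annotations

BANDS: tuple[str, ...] = ("2029", "3039", "4049", "5059", "6069", "over70")
DIALYSIS_BANDS: tuple[str, ...] = BANDS[2:]
STATES: tuple[str, ...] = ("NDM", "DM", "DMDi")
SEXES: tuple[str, ...] = ("male", "female")

N_BANDS = len(BANDS)
N_DIALYSIS_BANDS = len(DIALYSIS_BANDS)

#: ordered (state, band) pairs defining the flat 16-element state vector
STOCKS: tuple[tuple[str, str], ...] = (
    tuple(("NDM", b) for b in BANDS)
    + tuple(("DM", b) for b in BANDS)
    + tuple(("DMDi", b) for b in DIALYSIS_BANDS)
)
N_STOCKS = len(STOCKS)  # 16

STOCK_INDEX: dict[tuple[str, str], int] = {sb: i for i, sb in enumerate(STOCKS)}

NDM_SLICE = slice(0, N_BANDS)
DM_SLICE = slice(N_BANDS, 2 * N_BANDS)
DMDI_SLICE = slice(2 * N_BANDS, N_STOCKS)

#: width of each closed age band, years (over70 is open-ended / terminal)
BAND_WIDTH = 10.0

#: default prevalence of diabetes among 20-year-old entrants (0.2%)
DEFAULT_ENTRY_DM_PREVALENCE = 0.002

#: assumed all-cause mortality hazard ratio, DM vs non-DM (1:2)
DEFAULT_HAZARD_RATIO = 2.0

CALIBRATION_START = 2000
CALIBRATION_END = 2015
DEFAULT_HORIZON = 2035
DEFAULT_DT = 1.0 / 16.0


def stock_name(state: str, band: str) -> str:
    """Model variable name in the conventional notation, e.g. ``DMDi4049``."""
    return f"{state}{band}"
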