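"""Quantitative readouts for co-immunoprecipitation and FRET assays.

The immunoprecipitation ratio normalizes band intensities by the protein
amounts loaded:

    IPR = (IIP / IIC) * (AIC / AIP) * 100%

and a candidate is a positive interaction when both reciprocal assays
strictly exceed 3%.  FRET efficiency after acceptor photobleaching is
FE = (D_post - D_pre) / D_post (clamped to 0 when the donor did not
recover), and the positivity threshold is the maximum of mean + standard
error over the background/negative-control candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

IPR_THRESHOLD = 3.0  # percent, strict


@dataclass(frozen=True)
class IPMeasurement:
    """Band intensities and loaded amounts for one IP lane pair.

    ``iip``/``iic``: band intensities of the immunoprecipitated protein
    and the input loading control; ``aip``/``aic``: protein amounts (ug)
    used for immunoprecipitation and input control.
    """

    iip: float
    iic: float
    aip: float
    aic: float

    def __post_init__(self) -> None:
        for name in ("iip", "iic", "aip", "aic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FRETMeasurement:
    """Donor intensities before/after photobleaching for one region."""

    d_pre: float
    d_post: float

    def __post_init__(self) -> None:
        if self.d_pre < 0 or self.d_post < 0:
            raise ValueError("intensities must be nonnegative")


def ipr(m: IPMeasurement) -> float:
    """Immunoprecipitation ratio in percent."""
    return (m.iip / m.iic) * (m.aic / m.aip) * 100.0


def call_ip_positive(ipr_forward: float, ipr_reciprocal: float,
                     threshold: float = IPR_THRESHOLD) -> bool:
    """Positive interaction iff both reciprocal IPRs strictly exceed the
    threshold (default 3%)."""
    return ipr_forward > threshold and ipr_reciprocal > threshold


def fret_efficiency(d_pre: float, d_post: float) -> float:
    """FRET efficiency (D_post - D_pre)/D_post, 0 when D_post <= D_pre."""
    if d_post <= 0:
        raise ValueError("D_post must be positive")
    if d_pre < 0:
        raise ValueError("D_pre must be nonnegative")
    if d_post <= d_pre:
        return 0.0
    return (d_post - d_pre) / d_post


def fret_cut(candidates: Sequence[tuple[float, float]]) -> float:
    """Positivity threshold max_i (MFE_i + SE_i) over background signals.

    ``candidates`` are (mean FRET efficiency, standard error) pairs for
    the background/negative-control measurements.  An efficiency must
    strictly exceed the cut to call a positive interaction.
    """
    if not candidates:
        raise ValueError("need at least one background candidate")
    return max(mfe + se for mfe, se in candidates)
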