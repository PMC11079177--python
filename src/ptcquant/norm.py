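"""Normalization conventions for functional readouts.

Three conventions recur when characterizing channel variants:

* percent-of-WT — express a readout relative to the wild-type construct;
* mRNA normalization — divide a protein-level readout by the construct's
  relative transcript level, so expression differences do not masquerade as
  folding or trafficking effects;
* fractional plasma-membrane (PM) activity — short-circuit current divided
  by PM density, a proxy for channel open probability: a variant with
  proportionally reduced current and surface expression has WT-like
  fractional activity (trafficking defect), while reduced fractional
  activity indicates a gating defect.

All operations accept scalars or numpy/pandas vectors and apply per
replicate; summary statistics are computed downstream of normalization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "percent_of_wt",
    "mrna_normalize",
    "fractional_pm_activity",
    "relative_fractional_activity",
]

#: Divisors at or below this magnitude raise instead of producing inflated ratios.
DIVISOR_EPS = 1e-12


def _check_divisor(value, name: str) -> None:
    if np.any(np.asarray(value, dtype=float) <= DIVISOR_EPS):
        raise ValueError(f"{name} must be positive (got {value!r})")


def percent_of_wt(value, wt_value):
    """Express ``value`` as a percentage of the wild-type reference."""
    _check_divisor(wt_value, "wt_value")
    return 100.0 * np.asarray(value, dtype=float) / np.asarray(wt_value, dtype=float)


def mrna_normalize(value, mrna_level):
    """Divide a readout by the construct's relative mRNA level."""
    _check_divisor(mrna_level, "mrna_level")
    return np.asarray(value, dtype=float) / np.asarray(mrna_level, dtype=float)


def fractional_pm_activity(isc, pm_density):
    """Short-circuit current per unit plasma-membrane density.

    Invariant to common rescaling of both inputs, so it isolates per-channel
    activity from expression level.
    """
    _check_divisor(pm_density, "pm_density")
    return np.asarray(isc, dtype=float) / np.asarray(pm_density, dtype=float)


def relative_fractional_activity(isc, pm_density, wt_isc, wt_pm_density):
    """Fractional PM activity expressed relative to the wild type's ratio.

    1.0 means WT-like open probability regardless of expression level.
    """
    wt_ratio = fractional_pm_activity(wt_isc, wt_pm_density)
    _check_divisor(wt_ratio, "wild-type fractional activity")
    return fractional_pm_activity(isc, pm_density) / wt_ratio
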