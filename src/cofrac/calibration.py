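"""SEC column calibration from MW standards.

A size-exclusion column is calibrated by running standards of known MW and
fitting log10(MW) linearly against elution volume; fraction mean MWs are
then read off the fit. The slope is negative by construction — bigger
molecules travel a shorter path through the porous matrix and elute first.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .models import Calibration


def calibrate_column(standards: Sequence[tuple[float, float]]) -> Calibration:
    """Least-squares fit of log10(MW/kDa) on elution volume (mL).

    Parameters
    ----------
    standards : sequence of (elution_volume_mL, mw_kda)
        At least three standards with distinct elution volumes.

    Returns
    -------
    Calibration
        With ``valid_range`` spanning the standards' volumes; predictions
        outside it are flagged as extrapolations.
    """
    if len(standards) < 3:
        raise InsufficientDataError(
            f"column calibration needs >= 3 standards, got {len(standards)}"
        )
    volumes = np.asarray([v for v, _ in standards], dtype=float)
    mws = np.asarray([m for _, m in standards], dtype=float)
    if len(np.unique(volumes)) < 3:
        raise InsufficientDataError(
            "column calibration needs >= 3 distinct elution volumes"
        )
    if np.any(mws <= 0):
        raise ValidationError("standard MWs must be positive")

    order = np.argsort(volumes)
    if np.any(np.diff(mws[order]) > 0):
        warnings.warn(
            "standards are not monotone (some MW increases with elution "
            "volume); check for mis-entered standards",
            stacklevel=2,
        )

    fit = stats.linregress(volumes, np.log10(mws))
    if fit.slope >= 0:
        raise ValidationError(
            f"fitted calibration slope is non-negative ({fit.slope:.4g}); "
            "MW must decrease with elution volume on an SEC column"
        )
    return Calibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        valid_range=(float(volumes.min()), float(volumes.max())),
        stderr=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
    )
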