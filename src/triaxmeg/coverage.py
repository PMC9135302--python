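"""Array-coverage analysis: Frobenius-norm sensitivity maps.

For each candidate source j (and tangential orientation), the total
signal an array captures is summarised by the root-sum-of-squares of its
lead-field entries across the selected channels,

    f_j = sqrt( sum_i b_ij^2 ),

the Frobenius norm of the measured field vector — a proxy for the
array's sensitivity to that source.  Maps are normalised by their
maximum (per axis selection and orientation) to expose spatial
inhomogeneity: radial-only arrays close to a small head develop blind
spots directly beneath sensors, which tangential channels fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .forward import LeadField

__all__ = ["SensitivityMap", "sensitivity_map", "uniformity_metrics"]

_ORIENTATION_INDEX = {"theta": 0, "phi": 1}


@dataclass
class SensitivityMap:
    """Per-source Frobenius-norm sensitivity for one axis selection and
    one source orientation."""

    f: np.ndarray  # tesla per A·m, >= 0
    f_normalized: np.ndarray  # f / max(f), in (0, 1]
    axis_selection: str
    orientation: str
    source_positions: np.ndarray


def sensitivity_map(
    L: LeadField, axis_selection: str = "triaxial", orientation: str = "theta"
) -> SensitivityMap:
    """Frobenius-norm sensitivity over the sources of ``L``.

    ``axis_selection`` picks the channel rows (``r``, ``r+theta``,
    ``r+phi``, ``triaxial``); ``orientation`` the source orientation
    (``theta`` or ``phi``).
    """
    if orientation not in _ORIENTATION_INDEX:
        raise ConfigurationError(
            f"orientation must be 'theta' or 'phi', got {orientation!r}"
        )
    sub = L.select_axes(axis_selection)
    o = _ORIENTATION_INDEX[orientation]
    f = np.sqrt(np.sum(sub.matrix[:, :, o] ** 2, axis=0))
    fmax = f.max()
    if fmax <= 0:
        raise ConfigurationError("lead field is identically zero")
    return SensitivityMap(
        f=f,
        f_normalized=f / fmax,
        axis_selection=axis_selection,
        orientation=orientation,
        source_positions=L.source_positions,
    )


def uniformity_metrics(smap: SensitivityMap):
    """(min, 5th percentile, median) of the normalised sensitivity —
    scalar summaries of coverage uniformity (1 everywhere = perfectly
    uniform)."""
    f = smap.f_normalized
    if f.size == 0:
        raise ConfigurationError("empty sensitivity map")
    return float(f.min()), float(np.percentile(f, 5)), float(np.median(f))
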