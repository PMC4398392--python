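"""Two-way split-beam directivity model shared by the simulator and detector.

The quadratic two-way beam-pattern model standard in split-beam processing:

    G2(a, b) = -6.0206 * [x^2 + y^2 - 0.18 * x^2 * y^2]   (dB, <= 0)

with x = a/d, y = b/d, where a, b are the minor/major-axis off-axis angles
and d is half the (full, two-sided) half-power beamwidth. At one half-power
point on a single axis (a = d, b = 0) the two-way loss is 6.02 dB by
construction. Beam compensation is -G2: the dB added back to an
uncompensated echo.
"""

from __future__ import annotations

import numpy as np

DEFAULT_BEAMWIDTH_DEG = 6.5


def two_way_gain_db(theta_minor_deg, theta_major_deg, beamwidth_deg=DEFAULT_BEAMWIDTH_DEG):
    """Two-way beam-pattern gain in dB (0 on axis, negative off axis)."""
    d = beamwidth_deg / 2.0
    x = np.square(np.asarray(theta_minor_deg, dtype=float) / d)
    y = np.square(np.asarray(theta_major_deg, dtype=float) / d)
    out = -6.0206 * (x + y - 0.18 * x * y)
    return float(out) if out.ndim == 0 else out


def beam_compensation(theta_minor_deg, theta_major_deg, beamwidth_deg=DEFAULT_BEAMWIDTH_DEG):
    """Compensation (dB >= 0) for a target at the given off-axis angles.

    Zero on axis, symmetric under angle sign flips. Angles at or beyond the
    full beamwidth are outside the model's validity; ValueError is raised
    (the detector treats this as a rejected target).
    """
    tm = np.asarray(theta_minor_deg, dtype=float)
    ta = np.asarray(theta_major_deg, dtype=float)
    if np.any(np.abs(tm) >= beamwidth_deg) or np.any(np.abs(ta) >= beamwidth_deg):
        raise ValueError("off-axis angle beyond beam model validity")
    out = -two_way_gain_db(tm, ta, beamwidth_deg)
    return float(out) if np.ndim(out) == 0 else out


def max_offaxis_angle_deg(max_comp_db, beamwidth_deg=DEFAULT_BEAMWIDTH_DEG):
    """Single-axis off-axis angle at which compensation reaches ``max_comp_db``."""
    d = beamwidth_deg / 2.0
    return d * float(np.sqrt(max_comp_db / 6.0206))
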