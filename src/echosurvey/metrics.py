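"""Survey-quality diagnostics.

* Degree of coverage: total transect length / sqrt(surveyed area), the
  standard effort index for lake acoustic surveys (values above ~3 give
  good precision).
* Sawada's Nv: expected number of fish per reverberation volume,
  Nv = (c*tau/2) * psi * R^2 * rho. Below ~0.1 (conservatively 0.01)
  single-echo detection is considered unbiased by overlapping targets.
* Per-survey target depth summaries (mean and normal 95% CI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .beam import max_offaxis_angle_deg


@dataclass
class SurveyMeta:
    survey_id: object
    date: Optional[str] = None
    transect_lengths_km: Optional[Sequence[float]] = None
    total_length_km: Optional[float] = None
    year: Optional[int] = None

    def __post_init__(self):
        if self.total_length_km is None and self.transect_lengths_km is not None:
            self.total_length_km = float(np.sum(self.transect_lengths_km))


@dataclass
class NvEstimate:
    survey_id: object
    stratum_edges_m: np.ndarray
    nv: np.ndarray  # per range stratum

    @property
    def max_nv(self) -> float:
        return float(np.max(self.nv)) if len(self.nv) else 0.0


def coverage(total_length_km: float, area_km2: float) -> float:
    """Degree of coverage: L / sqrt(A) (dimensionless, km/km)."""
    if total_length_km <= 0 or area_km2 <= 0:
        raise ValueError("transect length and area must be positive")
    return float(total_length_km / np.sqrt(area_km2))


def equivalent_beam_angle_sr(half_power_beamwidth_deg: float) -> float:
    """Equivalent beam angle psi (sr) from the full half-power beamwidth,
    via the circular-aperture approximation psi ~= 5.78 * (theta_hp/2)^2."""
    half = np.radians(half_power_beamwidth_deg / 2.0)
    return float(5.78 * half**2)


def sawada_nv(
    density_per_m3: float,
    range_m: float,
    pulse_duration_s: float,
    eq_beam_angle_sr: float,
    sound_speed_m_s: float = 1490.0,
) -> float:
    """Nv = (c*tau/2) * psi * R^2 * rho: fish per reverberation volume."""
    if min(density_per_m3, range_m, pulse_duration_s, eq_beam_angle_sr) < 0:
        raise ValueError("inputs must be >= 0")
    return float(
        (sound_speed_m_s * pulse_duration_s / 2.0) * eq_beam_angle_sr * range_m**2 * density_per_m3
    )


def nv_profile(
    target_ranges_m: Sequence[float],
    total_track_length_m: float,
    config,
    stratum_m: float = 2.0,
    max_range_m: Optional[float] = None,
    max_comp_db: float = 15.0,
) -> NvEstimate:
    """Nv per range stratum with density estimated from detected targets.

    The insonified volume of stratum [R1, R2) along L metres of track is
    the swept wedge L * tan(theta_max) * (R2^2 - R1^2), with theta_max the
    off-axis angle admitted by the beam-compensation cap. Density is
    detected targets per insonified volume — a lower bound on true
    density (threshold losses), which is the quantity single-echo surveys
    can actually measure.
    """
    r = np.asarray(target_ranges_m, dtype=float)
    if max_range_m is None:
        max_range_m = float(config.mean_depth_m)
    edges = np.arange(0.0, max_range_m + stratum_m, stratum_m)
    theta = np.radians(max_offaxis_angle_deg(max_comp_db, config.half_power_beamwidth_deg))
    tau = config.pulse_duration_ms * 1e-3
    psi = equivalent_beam_angle_sr(config.half_power_beamwidth_deg)
    nv = np.zeros(len(edges) - 1)
    for i, (r1, r2) in enumerate(zip(edges[:-1], edges[1:])):
        cnt = int(np.sum((r >= r1) & (r < r2)))
        vol = total_track_length_m * np.tan(theta) * (r2**2 - r1**2)
        if vol <= 0 or cnt == 0:
            continue
        rho = cnt / vol
        rmid = 0.5 * (r1 + r2)
        nv[i] = sawada_nv(rho, rmid, tau, psi, config.sound_speed_m_s)
    return NvEstimate(survey_id=None, stratum_edges_m=edges, nv=nv)


def depth_summary(depths_m: Sequence[float]):
    """Mean target depth and 95% CI half-width (1.96 * SD / sqrt(n)).

    With fewer than two targets the CI is undefined (None).
    """
    d = np.asarray(depths_m, dtype=float)
    if len(d) == 0:
        raise ValueError("no targets")
    mean = float(np.mean(d))
    if len(d) < 2:
        return mean, None
    half = float(1.96 * np.std(d, ddof=1) / np.sqrt(len(d)))
    return mean, half


def survey_metrics(
    meta: SurveyMeta,
    area_km2: float,
    track_depths_m: Sequence[float],
    nv: Optional[NvEstimate] = None,
) -> Dict:
    out: Dict = {"survey_id": meta.survey_id}
    if meta.total_length_km:
        out["coverage"] = coverage(meta.total_length_km, area_km2)
    if len(track_depths_m):
        mean, half = depth_summary(track_depths_m)
        out["mean_depth_m"] = mean
        out["ci95_halfwidth_m"] = half
    if nv is not None:
        out["max_nv"] = nv.max_nv
    return out
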