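"""Echo integration: from filtered backscatter to areal fish density.

The estimator divides the average reflected energy per unit area by the
average reflection of one fish.  Per EDSU (here, a whole transect):

    s_a   = mean over pings of Σ (s_v · Δz)            [m²/m²]
    sA    = s_a × 10⁴                                  [m²/ha]
    σ̄_bs  = mean of 10^(TS/10) over that EDSU's SEDs   [m², in situ]
    ρ_A   = s_a / σ̄_bs × 10⁴                           [fish/ha]

Deriving fish/ha from the depth-integrated s_a (rather than from a volumetric
density times a water-column height) makes depth heterogeneity cancel.  The
multiple-echo bias check Nv = (c·τ/2)·ψ·R²·ρ_v must stay below 0.1 for the
single-target assumption behind in situ TS to hold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic import PingRecord, SingleEchoDetection

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyDesign",
    "TransectResult",
    "degree_of_coverage",
    "mean_sigma_bs",
    "area_backscatter",
    "areal_density",
    "nv_bias_check",
    "integrate_transects",
    "NoSedError",
]

#: Coverage adequacy threshold for Λ = D/√A.
COVERAGE_THRESHOLD = 6.0
#: Nominal equivalent beam angle (steradians) for a ~7° circular transducer.
DEFAULT_EQ_BEAM_ANGLE_SR = 0.0058
DEFAULT_SOUND_SPEED_M_S = 1500.0
DEFAULT_PULSE_S = 4e-4
NV_LIMIT = 0.1


class NoSedError(ValueError):
    """An EDSU produced no accepted SEDs: σ̄_bs and density are undefined."""


@dataclass(frozen=True)
class SurveyDesign:
    """Survey-coverage summary: Λ = track length / √area, adequate when ≥ 6."""

    track_length_D: float
    area_A: float
    coverage_lambda: float
    adequate: bool


@dataclass
class TransectResult:
    """Per-EDSU integration output (one transect)."""

    transect_id: str
    site_id: str
    n_sed: int
    mean_depth_m: float
    sv_mean: float  # linearized mean volume backscatter, m^2/m^3
    s_a: float  # area backscattering coefficient, m^2/m^2
    sA_m2_ha: float
    sigma_bs_m2: float
    density_fish_ha: float
    density_per_m3: float
    nv: float
    nv_pass: bool
    biomass_t_ha: float | None = None
    mean_length_cm: float | None = None
    sigma_bs_pooled: bool = False
    ts_values_dB: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def degree_of_coverage(track_length_m: float, area_m2: float) -> SurveyDesign:
    """Degree of coverage Λ = D/√A; adequate sampling effort requires Λ ≥ 6."""
    if area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    if track_length_m < 0:
        raise ValueError("track_length_m must be >= 0")
    lam = track_length_m / math.sqrt(area_m2)
    return SurveyDesign(track_length_m, area_m2, lam, lam >= COVERAGE_THRESHOLD)


def mean_sigma_bs(ts_list_dB) -> float:
    """Mean backscattering cross-section σ̄_bs (m²): linear-domain average of
    10^(TS/10) over an EDSU's SEDs."""
    ts = np.asarray(ts_list_dB, dtype=float)
    if ts.size == 0:
        raise NoSedError("no SEDs: sigma_bs undefined for this EDSU")
    return float(np.mean(10.0 ** (ts / 10.0)))


def area_backscatter(sv_profiles, bin_m: float) -> tuple[float, float]:
    """Depth-integrate masked s_v profiles to (s_a in m²/m², sA in m²/ha).

    ``sv_profiles`` is an iterable of per-ping linear s_v arrays; s_a is the
    ping-mean of the depth integrals.
    """
    integrals = [float(np.sum(p) * bin_m) for p in sv_profiles]
    if not integrals:
        raise ValueError("area_backscatter requires at least one ping")
    s_a = float(np.mean(integrals))
    return s_a, s_a * 1e4


def areal_density(s_a: float, sigma_bs_mean: float) -> float:
    """Areal fish density (fish/ha) = (s_a / σ̄_bs) × 10⁴."""
    if sigma_bs_mean <= 0:
        raise ValueError("sigma_bs_mean must be positive")
    return s_a / sigma_bs_mean * 1e4


def nv_bias_check(
    rho_v_fish_per_m3: float,
    sound_speed_m_s: float = DEFAULT_SOUND_SPEED_M_S,
    pulse_s: float = DEFAULT_PULSE_S,
    eq_beam_angle_sr: float = DEFAULT_EQ_BEAM_ANGLE_SR,
    range_m: float = 10.0,
) -> tuple[float, bool]:
    """Multiple-echo bias index Nv = (c·τ/2)·ψ·R²·ρ_v; passes when Nv < 0.1."""
    if rho_v_fish_per_m3 < 0:
        raise ValueError("rho_v must be >= 0")
    if min(sound_speed_m_s, pulse_s, eq_beam_angle_sr, range_m) <= 0:
        raise ValueError("physical parameters must be positive")
    nv = (
        (sound_speed_m_s * pulse_s / 2.0)
        * eq_beam_angle_sr
        * range_m**2
        * rho_v_fish_per_m3
    )
    return nv, nv < NV_LIMIT


def integrate_transects(
    pings: list[PingRecord],
    seds: list[SingleEchoDetection],
    site_of_transect: dict[str, str] | None = None,
    eq_beam_angle_sr: float = DEFAULT_EQ_BEAM_ANGLE_SR,
    sound_speed_m_s: float = DEFAULT_SOUND_SPEED_M_S,
    pulse_s: float = DEFAULT_PULSE_S,
) -> list[TransectResult]:
    """Integrate masked pings and accepted SEDs into per-transect results.

    σ̄_bs is taken in situ from each EDSU's own SEDs; an EDSU with no SEDs
    falls back to the pooled σ̄_bs of its site (flagged ``sigma_bs_pooled`` and
    logged loudly), and to a zero-density result only when the site has no
    SEDs at all.
    """
    by_tid_pings: dict[str, list[PingRecord]] = {}
    for p in pings:
        by_tid_pings.setdefault(p.transect_id, []).append(p)
    by_tid_ts: dict[str, list[float]] = {t: [] for t in by_tid_pings}
    for s in seds:
        by_tid_ts.setdefault(s.transect_id, []).append(s.ts_dB)

    site_of = site_of_transect or {}
    site_ts: dict[str, list[float]] = {}
    for tid, ts in by_tid_ts.items():
        site_ts.setdefault(site_of.get(tid, tid.rsplit("-", 1)[0]), []).extend(ts)

    results = []
    for tid in sorted(by_tid_pings):
        tr_pings = by_tid_pings[tid]
        site = site_of.get(tid, tid.rsplit("-", 1)[0])
        bin_m = tr_pings[0].bin_m
        s_a, sA = area_backscatter([p.sv_profile for p in tr_pings], bin_m)
        mean_depth = float(np.mean([p.bottom_depth_m for p in tr_pings]))
        sv_mean = s_a / mean_depth if mean_depth > 0 else 0.0

        ts = np.asarray(by_tid_ts.get(tid, []), dtype=float)
        pooled = False
        if ts.size == 0:
            pool = np.asarray(site_ts.get(site, []), dtype=float)
            if pool.size:
                logger.warning(
                    "EDSU %s has no SEDs; using pooled site sigma_bs (n=%d)",
                    tid,
                    pool.size,
                )
                sigma = mean_sigma_bs(pool)
                pooled = True
            else:
                logger.warning("EDSU %s and site %s have no SEDs at all", tid, site)
                sigma = float("nan")
        else:
            sigma = mean_sigma_bs(ts)

        if np.isfinite(sigma) and sigma > 0:
            density = areal_density(s_a, sigma)
            rho_v = sv_mean / sigma
        else:
            density = 0.0 if s_a == 0 else float("nan")
            rho_v = 0.0
        mean_range = float(np.mean([r for r in ts_ranges(seds, tid)]) if ts.size else mean_depth / 2.0)
        nv, nv_ok = nv_bias_check(
            rho_v, sound_speed_m_s, pulse_s, eq_beam_angle_sr, max(mean_range, 1e-6)
        )
        results.append(
            TransectResult(
                transect_id=tid,
                site_id=site,
                n_sed=int(ts.size),
                mean_depth_m=mean_depth,
                sv_mean=sv_mean,
                s_a=s_a,
                sA_m2_ha=sA,
                sigma_bs_m2=sigma,
                density_fish_ha=density,
                density_per_m3=rho_v,
                nv=nv,
                nv_pass=nv_ok,
                sigma_bs_pooled=pooled,
                ts_values_dB=ts,
            )
        )
    return results


def ts_ranges(seds: list[SingleEchoDetection], transect_id: str):
    return [s.range_m for s in seds if s.transect_id == transect_id]
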