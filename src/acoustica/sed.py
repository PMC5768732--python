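"""Single-echo-detection acceptance rules, TVG range compensation, thresholds
and exclusion layers.

Echo integration only makes sense on echoes that genuinely come from single
fish.  A split-beam sounder proposes candidate single echo detections (SEDs);
these are accepted only if the received pulse resembles the transmitted one
(relative echo length within [0.8, 1.2]), the target is stable in the beam
(angle SD ≤ 0.8°), the echo envelope has no deep secondary peak (dip < 1.5 dB
would indicate overlapping fish), and the compensated TS clears a −60 dB noise
threshold.  Volume backscattering samples below −66 dB are zeroed before
integration to suppress plankton and noise.  Exclusion layers remove the top
metre (surface bubbles/wind noise, occasionally extended to 5 m), the metre
above the seabed (dead zone; a SED there survives only when explicitly flagged
as clearly separated from the bottom echo), and everything beyond a 100 m
processing limit where the signal-to-noise ratio is unacceptable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

from .synthetic import PingRecord, SingleEchoDetection

__all__ = [
    "SedCriteria",
    "ExclusionConfig",
    "apply_tvg",
    "filter_seds",
    "threshold_sv",
    "apply_exclusion_layers",
]

#: Fixed order in which rejection reasons are assigned (first failing rule wins).
REJECTION_ORDER = ("echo_length", "angle_sd", "dip", "ts_threshold")


@dataclass(frozen=True)
class SedCriteria:
    """SED acceptance windows and thresholds.

    Echo length is the received/transmitted pulse-length ratio (dimensionless).
    """

    min_echo_length: float = 0.8
    max_echo_length: float = 1.2
    max_angle_sd_deg: float = 0.8
    multipeak_dip_dB: float = 1.5
    ts_threshold_dB: float = -60.0
    sv_threshold_dB: float = -66.0

    def __post_init__(self) -> None:
        if not self.min_echo_length < self.max_echo_length:
            raise ValueError("min_echo_length must be < max_echo_length")
        for v in (self.ts_threshold_dB, self.sv_threshold_dB):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class ExclusionConfig:
    """Surface/bottom exclusion layers and the maximum processing depth."""

    surface_m: float = 1.0
    bottom_m: float = 1.0
    max_depth_m: float = 100.0
    extended_surface_m: float | None = None  # per-transect manual override

    def __post_init__(self) -> None:
        if min(self.surface_m, self.bottom_m, self.max_depth_m) < 0:
            raise ValueError("exclusion depths must be >= 0")
        if self.extended_surface_m is not None and not (
            0 <= self.extended_surface_m <= 5
        ):
            raise ValueError("extended_surface_m must be within [0, 5] m")

    @property
    def effective_surface_m(self) -> float:
        return (
            self.extended_surface_m
            if self.extended_surface_m is not None
            else self.surface_m
        )


def apply_tvg(raw_dB, range_m, mode: str = "ts_40logR", alpha_dB_per_m: float = 0.0):
    """Time-varied-gain range compensation.

    ``compensated = raw + k·log10(R) + 2·alpha·R`` with k = 40 for point-target
    TS and k = 20 for volume backscattering; absorption alpha defaults to 0.
    """
    k = {"ts_40logR": 40.0, "sv_20logR": 20.0}.get(mode)
    if k is None:
        raise ValueError(f"unknown TVG mode {mode!r}")
    range_m = np.asarray(range_m, dtype=float)
    if np.any(range_m <= 0):
        raise ValueError("range_m must be positive")
    out = (
        np.asarray(raw_dB, dtype=float)
        + k * np.log10(range_m)
        + 2.0 * alpha_dB_per_m * range_m
    )
    return out.item() if out.ndim == 0 else out


def _rejection_reason(sed: SingleEchoDetection, c: SedCriteria) -> str | None:
    if not (c.min_echo_length <= sed.echo_length_rel <= c.max_echo_length):
        return "echo_length"
    if sed.angle_sd_deg > c.max_angle_sd_deg:
        return "angle_sd"
    if sed.peak_dip_dB >= c.multipeak_dip_dB:
        return "dip"
    if sed.ts_dB < c.ts_threshold_dB:
        return "ts_threshold"
    return None


def filter_seds(
    seds: list[SingleEchoDetection], criteria: SedCriteria | None = None
) -> tuple[list[SingleEchoDetection], list[tuple[SingleEchoDetection, str]]]:
    """Partition SEDs into accepted and (rejected, reason) with a fixed
    rule-evaluation order; each SED is labelled with its first failing rule."""
    criteria = criteria or SedCriteria()
    accepted, rejected = [], []
    for sed in seds:
        reason = _rejection_reason(sed, criteria)
        if reason is None:
            accepted.append(sed)
        else:
            rejected.append((sed, reason))
    return accepted, rejected


def threshold_sv(
    pings: list[PingRecord], sv_threshold_dB: float = -66.0
) -> list[PingRecord]:
    """Zero volume-backscattering samples below the linear-domain threshold."""
    thresh = 10.0 ** (sv_threshold_dB / 10.0)
    out = []
    for p in pings:
        sv = p.sv_profile.copy()
        sv[sv < thresh] = 0.0
        out.append(replace(p, sv_profile=sv))
    return out


def apply_exclusion_layers(
    pings: list[PingRecord],
    seds: list[SingleEchoDetection],
    cfg: ExclusionConfig | None = None,
) -> tuple[list[PingRecord], list[SingleEchoDetection]]:
    """Mask the surface layer, bottom layer and beyond-limit depths.

    Returns pings with excluded samples zeroed and the surviving SEDs.  A SED
    inside the bottom layer survives only when flagged ``clearly_separated``
    (manual identification of a fish echo distinct from the seabed return).
    """
    cfg = cfg or ExclusionConfig()
    surface = cfg.effective_surface_m
    bottom_by_ping = {(p.transect_id, p.ping_index): p.bottom_depth_m for p in pings}

    masked = []
    for p in pings:
        limit = min(p.bottom_depth_m - cfg.bottom_m, cfg.max_depth_m)
        if surface >= limit:
            logger.warning(
                "ping %s/%d fully masked: surface layer %.1f m reaches the bottom layer",
                p.transect_id,
                p.ping_index,
                surface,
            )
        sv = p.sv_profile.copy()
        centers = (np.arange(sv.size) + 0.5) * p.bin_m
        sv[(centers < surface) | (centers > limit)] = 0.0
        masked.append(replace(p, sv_profile=sv))

    surviving = []
    for s in seds:
        bottom = bottom_by_ping.get((s.transect_id, s.ping_index), np.inf)
        if s.depth_m > cfg.max_depth_m:
            continue
        if s.depth_m < surface:
            continue
        if s.depth_m > bottom - cfg.bottom_m and not s.clearly_separated:
            continue
        surviving.append(s)
    return masked, surviving
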