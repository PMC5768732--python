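"""Underwater visual census (UVC) belt transects and the acoustic-vs-UVC
comparison.

Divers swim fixed belts (default 50 m × 5 m = 250 m²) counting and sizing
every fish; densities scale counts by the belt area, biomass applies the
length–weight model (species-specific a/b where provided, otherwise the
generalist model) to each record's mean length.  The cross-method comparison
tests per-transect density and biomass with Mann–Whitney and the pooled
size-class distributions (acoustic per-SED lengths reassigned to the UVC
classes) with a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import WeightModel, length_to_weight
from .stats import two_sample

__all__ = [
    "UVCRecord",
    "UVCTransect",
    "read_uvc_table",
    "write_uvc_table",
    "uvc_density",
    "uvc_biomass",
    "uvc_mean_length",
    "compare_methods",
    "simulate_uvc_transects",
]

UVC_COLUMNS = [
    "site_id",
    "transect_id",
    "belt_length_m",
    "belt_width_m",
    "species",
    "count",
    "mean_length_cm",
    "trophic_group",
    "a_wl",
    "b_wl",
]


@dataclass
class UVCRecord:
    species: str
    count: int
    mean_length_cm: float
    trophic_group: str | None = None
    a_wl: float | None = None  # species-specific length-weight coefficients
    b_wl: float | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.mean_length_cm <= 0:
            raise ValueError("mean_length_cm must be positive")


@dataclass
class UVCTransect:
    site_id: str
    transect_id: str
    belt_length_m: float = 50.0
    belt_width_m: float = 5.0
    records: list[UVCRecord] = field(default_factory=list)

    @property
    def area_m2(self) -> float:
        return self.belt_length_m * self.belt_width_m

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError("belt area must be positive")


def read_uvc_table(path) -> list[UVCTransect]:
    """Read a UVC belt-transect CSV into validated transect objects."""
    df = pd.read_csv(path)
    missing = {"site_id", "transect_id", "species", "count", "mean_length_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"UVC table missing columns: {sorted(missing)}")
    transects: dict[str, UVCTransect] = {}
    for i, row in df.iterrows():
        tid = str(row["transect_id"])
        if tid not in transects:
            transects[tid] = UVCTransect(
                site_id=str(row["site_id"]),
                transect_id=tid,
                belt_length_m=float(row.get("belt_length_m", 50.0) or 50.0),
                belt_width_m=float(row.get("belt_width_m", 5.0) or 5.0),
            )
        try:
            transects[tid].records.append(
                UVCRecord(
                    species=str(row["species"]),
                    count=int(row["count"]),
                    mean_length_cm=float(row["mean_length_cm"]),
                    trophic_group=(
                        str(row["trophic_group"])
                        if "trophic_group" in df.columns and pd.notna(row["trophic_group"])
                        else None
                    ),
                    a_wl=float(row["a_wl"]) if "a_wl" in df.columns and pd.notna(row["a_wl"]) else None,
                    b_wl=float(row["b_wl"]) if "b_wl" in df.columns and pd.notna(row["b_wl"]) else None,
                )
            )
        except ValueError as e:
            raise ValueError(f"UVC table row {i + 2}: {e}") from e
    return list(transects.values())


def write_uvc_table(transects: list[UVCTransect], path) -> None:
    rows = []
    for t in transects:
        for r in t.records:
            rows.append(
                {
                    "site_id": t.site_id,
                    "transect_id": t.transect_id,
                    "belt_length_m": t.belt_length_m,
                    "belt_width_m": t.belt_width_m,
                    "species": r.species,
                    "count": r.count,
                    "mean_length_cm": r.mean_length_cm,
                    "trophic_group": r.trophic_group,
                    "a_wl": r.a_wl,
                    "b_wl": r.b_wl,
                }
            )
    pd.DataFrame(rows, columns=UVC_COLUMNS).to_csv(path, index=False)


def uvc_density(transect: UVCTransect) -> float:
    """Diver fish density in fish/ha: total count over belt area × 10⁴."""
    return sum(r.count for r in transect.records) / transect.area_m2 * 1e4


def uvc_biomass(transect: UVCTransect, default_wmodel: WeightModel | None = None) -> float:
    """Diver biomass in t/ha using species a/b where given, else the generalist
    length–weight model."""
    default_wmodel = default_wmodel or WeightModel()
    grams = 0.0
    for r in transect.records:
        wm = (
            WeightModel(a=r.a_wl, b=r.b_wl)
            if r.a_wl is not None and r.b_wl is not None
            else default_wmodel
        )
        grams += r.count * length_to_weight(r.mean_length_cm, wm)
    return grams / transect.area_m2 * 1e4 * 1e-6  # g/m2 -> g/ha -> t/ha


def uvc_mean_length(transect: UVCTransect) -> float:
    counts = np.array([r.count for r in transect.records], dtype=float)
    if counts.sum() == 0:
        return float("nan")
    lengths = np.array([r.mean_length_cm for r in transect.records])
    return float(np.sum(counts * lengths) / counts.sum())


def _expand_lengths(transects: list[UVCTransect]) -> np.ndarray:
    out = []
    for t in transects:
        for r in t.records:
            out.extend([r.mean_length_cm] * r.count)
    return np.asarray(out, dtype=float)


def _to_classes(lengths_cm, edges) -> np.ndarray:
    """Reassign individual lengths to class midpoints given class edges."""
    edges = np.asarray(edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, lengths_cm, side="right") - 1, 0, edges.size - 2)
    return 0.5 * (edges[idx] + edges[idx + 1])


def compare_methods(
    acoustic_results,
    acoustic_lengths_cm,
    uvc_transects: list[UVCTransect],
    size_class_edges=None,
) -> dict:
    """Cross-method comparison report.

    Parameters
    ----------
    acoustic_results
        Per-transect echo-integration results carrying ``density_fish_ha`` and
        ``biomass_t_ha``.
    acoustic_lengths_cm
        Pooled per-SED lengths from the same transects.
    uvc_transects
        Diver belt transects over the same habitat.
    size_class_edges
        Length-class edges (cm) for the KS comparison; default 5 cm classes
        from 0 to 205 cm.
    """
    if not acoustic_results or not uvc_transects:
        raise ValueError("compare_methods requires >= 1 transect per method")
    edges = (
        np.asarray(size_class_edges, dtype=float)
        if size_class_edges is not None
        else np.arange(0.0, 210.0, 5.0)
    )
    ac_density = np.array([t.density_fish_ha for t in acoustic_results])
    ac_biomass = np.array(
        [t.biomass_t_ha if t.biomass_t_ha is not None else np.nan for t in acoustic_results]
    )
    uv_density = np.array([uvc_density(t) for t in uvc_transects])
    uv_biomass = np.array([uvc_biomass(t) for t in uvc_transects])

    d_stat, d_p = two_sample(ac_density, uv_density, "mann_whitney")
    b_stat, b_p = two_sample(ac_biomass, uv_biomass, "mann_whitney")

    ac_classes = _to_classes(np.asarray(acoustic_lengths_cm, dtype=float), edges)
    uv_classes = _to_classes(_expand_lengths(uvc_transects), edges)
    ks_d, ks_p = two_sample(ac_classes, uv_classes, "ks")

    def class_table(classes):
        vals, counts = np.unique(classes, return_counts=True)
        return {float(v): int(c) for v, c in zip(vals, counts)}

    return {
        "density": {
            "mann_whitney_U": d_stat,
            "p": d_p,
            "acoustic_median": float(np.median(ac_density)),
            "uvc_median": float(np.median(uv_density)),
        },
        "biomass": {
            "mann_whitney_U": b_stat,
            "p": b_p,
            "acoustic_median": float(np.nanmedian(ac_biomass)),
            "uvc_median": float(np.median(uv_biomass)),
        },
        "size_classes": {
            "ks_D": ks_d,
            "p": ks_p,
            "acoustic_median_class_cm": float(np.median(ac_classes)) if ac_classes.size else None,
            "uvc_median_class_cm": float(np.median(uv_classes)) if uv_classes.size else None,
            "acoustic_table": class_table(ac_classes),
            "uvc_table": class_table(uv_classes),
        },
    }


def simulate_uvc_transects(
    scenario,
    n_transects: int,
    rng: np.random.Generator,
    belt_length_m: float = 50.0,
    belt_width_m: float = 5.0,
    cryptic_density_fish_ha: float = 0.0,
    cryptic_length_range_cm: tuple[float, float] = (2.0, 5.0),
) -> list[UVCTransect]:
    """Synthetic diver observations of the same community a site scenario
    describes, with an optional cryptic small-fish stratum divers see but the
    acoustic TS threshold does not.

    Counts are Poisson over the belt area; lengths are drawn from the
    scenario's (truncated lognormal) size distribution and recorded to the
    nearest cm, one record per 1 cm bin.
    """
    from .synthetic import _truncated_lognormal  # avoid cycle at module import

    area_ha = belt_length_m * belt_width_m / 1e4
    out = []
    for t in range(n_transects):
        n = int(rng.poisson(scenario.true_areal_density * area_ha))
        lengths = _truncated_lognormal(
            rng, scenario.length_meanlog, scenario.length_sdlog, n
        )
        n_cryptic = int(rng.poisson(cryptic_density_fish_ha * area_ha))
        if n_cryptic:
            lengths = np.concatenate(
                [lengths, rng.uniform(*cryptic_length_range_cm, n_cryptic)]
            )
        tr = UVCTransect(
            site_id=scenario.site_id,
            transect_id=f"{scenario.site_id}-UVC{t}",
            belt_length_m=belt_length_m,
            belt_width_m=belt_width_m,
        )
        rounded = np.maximum(np.round(lengths), 1.0)
        for L in np.unique(rounded):
            tr.records.append(
                UVCRecord(
                    species="synthetic",
                    count=int(np.sum(rounded == L)),
                    mean_length_cm=float(L),
                )
            )
        out.append(tr)
    return out
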