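"""Root-diameter traits from per-order measurements.

Per species, the mean diameter of each root order (1st-3rd, pooling all
measured locations and individuals) is computed first; the species mean
root diameter is the unweighted mean of those order means. Mesocosm mean
root diameter is the unweighted mean over harvested plants (a species
planted twice contributes twice).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRootDiameter",
    "read_root_measurements",
    "species_mean_diameter",
    "mesocosm_mean_diameter",
    "provenance_mean_diameter",
]

MEASUREMENT_COLUMNS = ["plant_species", "individual_id", "root_order",
                       "d1_mm", "d2_mm", "d3_mm"]


@dataclass(frozen=True)
class SpeciesRootDiameter:
    plant_species: str
    order_means_mm: Mapping[int, float]
    mean_diameter_mm: float


def read_root_measurements(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated root-measurement table
    (species, individual, order, d1_mm, d2_mm, d3_mm)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"root measurement table missing columns: {missing}")
    return validate_measurements(df)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["root_order"] = df["root_order"].astype(int)
    bad_order = sorted(set(df["root_order"]) - {1, 2, 3})
    if bad_order:
        raise ValueError(f"root orders outside 1-3: {bad_order}")
    diam = df[["d1_mm", "d2_mm", "d3_mm"]].to_numpy(dtype=float)
    if (diam <= 0).any():
        raise ValueError("non-positive root diameter measurement")
    return df


def species_mean_diameter(
    measurements: pd.DataFrame,
) -> dict[str, SpeciesRootDiameter]:
    """Per species: order means over all locations/individuals, then the
    unweighted mean of the order means."""
    df = validate_measurements(measurements)
    if df.empty:
        raise ValueError("no root measurements supplied")
    long = df.melt(
        id_vars=["plant_species", "individual_id", "root_order"],
        value_vars=["d1_mm", "d2_mm", "d3_mm"],
        value_name="diameter_mm",
    )
    order_means = (
        long.groupby(["plant_species", "root_order"])["diameter_mm"].mean()
    )
    out: dict[str, SpeciesRootDiameter] = {}
    for species, grp in order_means.groupby(level=0):
        means = {int(o): float(v) for (_, o), v in grp.items()}
        out[str(species)] = SpeciesRootDiameter(
            str(species), means, float(np.mean(list(means.values())))
        )
    return out


def mesocosm_mean_diameter(
    metadata: pd.DataFrame,
    species_diameters: Mapping[str, SpeciesRootDiameter | float],
) -> pd.Series:
    """Unweighted mean root diameter over the plants harvested from each
    mesocosm (one metadata row per harvested plant)."""
    def _value(sp: str) -> float:
        if sp not in species_diameters:
            raise KeyError(f"no root diameter for species {sp!r}")
        v = species_diameters[sp]
        return v.mean_diameter_mm if isinstance(v, SpeciesRootDiameter) else float(v)

    diam = metadata["plant_species"].map(_value)
    return diam.groupby(metadata["mesocosm_id"]).mean().rename("mean_root_diameter_mm")


def provenance_mean_diameter(
    species_diameters: Mapping[str, SpeciesRootDiameter],
    provenance_of: Mapping[str, str],
) -> dict[str, float]:
    """Grand mean diameter per provenance, weighting species equally."""
    sums: dict[str, list[float]] = {}
    for sp, sd in species_diameters.items():
        prov = provenance_of[sp]
        sums.setdefault(prov, []).append(sd.mean_diameter_mm)
    return {prov: float(np.mean(vals)) for prov, vals in sums.items()}
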