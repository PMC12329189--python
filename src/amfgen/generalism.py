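"""Partner generalism of arbuscular mycorrhizal fungal OTUs.

Two statistics:

* per-OTU **effective number of plant partners** — reads are pooled by
  plant species across the whole experiment; with species shares p_i the
  Hill number of order q is the effective number of equally used
  partners. At the default q = 1 this is exp(H) with
  H = -sum_i p_i ln p_i (exponential of Shannon entropy);

* mesocosm-level **weighted generalism score** — the abundance-weighted
  mean of the effective-partner numbers of the OTUs in a mesocosm,
  divided by the number of plant species present in that mesocosm at
  harvest (correcting for plant mortality):

      score = (sum_k a_k D_k) / richness_at_harvest,

  with a_k the OTU's share of the mesocosm's reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import OtuTable, check_metadata_covers

__all__ = [
    "PartnerProfile",
    "GeneralismScore",
    "hill_number",
    "partner_diversity",
    "weighted_generalism",
]


@dataclass(frozen=True)
class PartnerProfile:
    """Per-OTU read totals by plant species and the resulting effective
    partner number D (Hill number of the chosen order)."""

    otu_id: str
    reads_by_species: Mapping[str, int]
    effective_partners: float


@dataclass(frozen=True)
class GeneralismScore:
    mesocosm_id: str
    weighted_score: float
    richness_at_harvest: int
    otu_contributions: Mapping[str, tuple[float, float]]  # otu -> (a_k, D_k)


def hill_number(counts: np.ndarray, q: float = 1.0) -> float:
    """Hill number of order q of a non-negative count/abundance vector.

    q = 0 is richness, q = 1 the exponential of Shannon entropy, q = 2
    the inverse Simpson concentration. All-zero input returns 0.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    total = x.sum()
    if total == 0:
        return 0.0
    p = x[x > 0] / total
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def partner_diversity(
    table: OtuTable, metadata: pd.DataFrame, q: float = 1.0
) -> list[PartnerProfile]:
    """Effective number of plant partners per OTU, experiment-wide.

    Reads are aggregated by plant species over ALL samples in the table;
    the Hill number (default q = 1) of the species profile is the OTU's
    effective partner count. OTUs with zero total reads get D = 0 with a
    warning.
    """
    meta = check_metadata_covers(table, metadata)
    by_species = table.counts.groupby(meta["plant_species"].to_numpy()).sum()
    profiles: list[PartnerProfile] = []
    zero_otus = []
    for otu_id in table.otu_ids:
        reads = by_species[otu_id]
        d = hill_number(reads.to_numpy(), q)
        if d == 0.0:
            zero_otus.append(otu_id)
        profiles.append(
            PartnerProfile(otu_id, dict(reads[reads > 0].astype(int)), d)
        )
    if zero_otus:
        warnings.warn(
            f"{len(zero_otus)} OTU(s) with zero total reads were assigned "
            f"D = 0: {zero_otus[:5]}",
            stacklevel=2,
        )
    return profiles


def weighted_generalism(
    table: OtuTable,
    metadata: pd.DataFrame,
    profiles: Sequence[PartnerProfile],
) -> list[GeneralismScore]:
    """Abundance-weighted generalism score per mesocosm.

    Counts are aggregated by mesocosm; a_k is OTU k's share of the
    mesocosm's reads, D_k its experiment-wide effective partner number,
    and the score (sum_k a_k D_k) / richness_at_harvest.
    """
    meta = check_metadata_covers(table, metadata)
    d_of = {p.otu_id: p.effective_partners for p in profiles}
    missing = [o for o in table.otu_ids if o not in d_of]
    if missing:
        raise KeyError(f"no partner profile for OTU(s): {missing[:5]}")
    agg = table.counts.groupby(meta["mesocosm_id"].to_numpy()).sum()
    richness = (
        meta.groupby("mesocosm_id")["richness_at_harvest"].first().astype(int)
    )
    scores: list[GeneralismScore] = []
    for mesocosm_id, row in agg.iterrows():
        total = int(row.sum())
        if total == 0:
            raise ValueError(f"mesocosm {mesocosm_id!r} has zero reads")
        r = int(richness.loc[mesocosm_id])
        if r < 1:
            raise ValueError(f"mesocosm {mesocosm_id!r}: richness_at_harvest < 1")
        present = row[row > 0]
        a = present / total
        contrib = {
            otu: (float(a_k), float(d_of[otu])) for otu, a_k in a.items()
        }
        score = float(sum(a_k * d_k for a_k, d_k in contrib.values()) / r)
        scores.append(GeneralismScore(str(mesocosm_id), score, r, contrib))
    return scores
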