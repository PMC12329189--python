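"""Iterated random rarefaction and richness at sample (alpha) and
mesocosm (gamma) scale.

Rarefaction is subsampling without replacement (multivariate
hypergeometric). Richness of a unit at depth n has the closed form

    E[S] = sum_j (1 - C(N - N_j, n) / C(N, n))

where N_j are the unit's OTU counts and N their total; the Monte-Carlo
mean over iterated subsamples converges to this, and the closed form
serves as the independent oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import OtuTable, check_metadata_covers

__all__ = [
    "RarefactionSummary",
    "rarefy_once",
    "expected_rarefied_richness",
    "mean_rarefied_richness",
    "gamma_aggregate",
]


@dataclass(frozen=True)
class RarefactionSummary:
    """Mean and SD of richness of one unit over iterated subsampling."""

    unit_id: str
    depth: int
    iterations: int
    mean_richness: float
    sd_richness: float


def rarefy_once(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One multivariate-hypergeometric subsample of a count vector."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds unit total {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness under rarefaction without replacement.

    Uses log-gamma for the binomial ratios so large depths do not
    overflow.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds unit total {total}")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    p_absent = np.zeros(len(counts))
    ok = rest >= depth
    p_absent[ok] = np.exp(log_comb(rest[ok], depth) - log_comb(total, depth))
    return float(np.sum(1.0 - p_absent))


def mean_rarefied_richness(
    table: OtuTable,
    iterations: int = 500,
    depth: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[RarefactionSummary]:
    """Mean/SD richness per sample over iterated rarefaction.

    Depth defaults to the minimum sample total in the table. Each sample
    draws from its own child seed of ``seed``, so per-sample streams are
    independent and the result is reproducible and invariant to sample
    order.
    """
    if table.shape[0] == 0:
        raise ValueError("empty table")
    depths = table.sample_depths()
    if depth is None:
        depth = int(depths.min())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    too_shallow = depths.index[depths < depth].tolist()
    if too_shallow:
        raise ValueError(
            f"samples below rarefaction depth {depth}: {too_shallow[:5]}"
        )
    base = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    out: list[RarefactionSummary] = []
    for sample_id in table.sample_ids:
        counts = table.counts.loc[sample_id].to_numpy()
        # per-sample stream keyed by the sample id so ordering cannot matter
        child = np.random.SeedSequence(
            entropy=base.entropy,
            spawn_key=(int.from_bytes(sample_id.encode(), "big") % (2**63),),
        )
        rng = np.random.default_rng(child)
        if int(counts.sum()) == depth:
            richness = np.full(iterations, int((counts > 0).sum()), dtype=float)
        else:
            draws = rng.multivariate_hypergeometric(
                counts, depth, size=iterations, method="marginals"
            )
            richness = (draws > 0).sum(axis=1).astype(float)
        out.append(
            RarefactionSummary(
                sample_id,
                depth,
                iterations,
                float(richness.mean()),
                float(richness.std(ddof=1)) if iterations > 1 else 0.0,
            )
        )
    return out


def gamma_aggregate(table: OtuTable, metadata: pd.DataFrame) -> OtuTable:
    """Sum counts within mesocosm, producing a mesocosm-level table.

    Gamma diversity is then :func:`mean_rarefied_richness` on the
    aggregated table (depth defaulting to the minimum mesocosm total).
    """
    meta = check_metadata_covers(table, metadata)
    mesocosm = meta["mesocosm_id"]
    agg = table.counts.groupby(mesocosm.to_numpy()).sum()
    agg.index.name = "sample_id"
    return OtuTable(agg, table.otu_annotations)
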