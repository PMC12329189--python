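"""Assembled analysis workflows over simulated (or loaded) experiments.

These functions wire the module-level operations into the study's three
model-ready data frames — per-plant rarefied richness, mesocosm gamma
richness, and mesocosm weighted generalism — and fit the corresponding
mixed models. They are what the numbered analysis drivers, the
acceptance machinery and the replication loops call.
"""

from __future__ import annotations


import pandas as pd

from .diversity import gamma_aggregate, mean_rarefied_richness
from .generalism import partner_diversity, weighted_generalism
from .io_formats import OtuTable, check_metadata_covers
from .models import ModelCandidate, ModelSpec, fit_lmm
from .otu_table import min_depth_filter, subset_mycorrhizal_hosts
from .simulate import SimConfig, simulate_experiment, synthetic_species_pool
from .traits import mesocosm_mean_diameter

__all__ = [
    "prepare_analysis_table",
    "sample_richness_frame",
    "mesocosm_frame",
    "fit_richness_model",
    "fit_mesocosm_model",
    "experiment_slopes",
    "INDIVIDUAL_RANDOM_TERMS",
    "MESOCOSM_RANDOM_TERMS",
]

# random intercepts of the individual-plant models: plant species crossed
# with mesocosm nested in community
INDIVIDUAL_RANDOM_TERMS = (
    ("species", "0 + C(plant_species)"),
    ("community", "0 + C(community_id)"),
    ("mesocosm", "0 + C(mesocosm_id)"),
)
MESOCOSM_RANDOM_TERMS = (("community", "0 + C(community_id)"),)


def prepare_analysis_table(
    table: OtuTable, metadata: pd.DataFrame, min_reads: int = 1000
) -> OtuTable:
    """Depth-filter and restrict to mycorrhizal hosts (the steps that
    apply when starting from a pre-built count table)."""
    out = min_depth_filter(table, min_reads)
    return subset_mycorrhizal_hosts(out, metadata).drop_empty_otus()


def sample_richness_frame(
    table: OtuTable,
    metadata: pd.DataFrame,
    iterations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant mean rarefied richness joined to metadata and species
    root diameter."""
    summaries = mean_rarefied_richness(table, iterations=iterations, seed=seed)
    rich = pd.DataFrame(
        [(s.unit_id, s.mean_richness) for s in summaries],
        columns=["sample_id", "richness"],
    )
    meta = check_metadata_covers(table, metadata).reset_index()
    pool = synthetic_species_pool().set_index("plant_species")
    meta["root_diameter"] = meta["plant_species"].map(
        pool["mean_root_diameter_mm"]
    )
    return meta.merge(rich, on="sample_id")


def mesocosm_frame(
    table: OtuTable,
    metadata: pd.DataFrame,
    iterations: int = 500,
    seed: int = 0,
    gamma: bool = True,
) -> pd.DataFrame:
    """Mesocosm-level frame: gamma richness (iterated rarefaction of the
    aggregated table), weighted generalism score, and design covariates
    including the mean root diameter of harvested plants."""
    meta = check_metadata_covers(table, metadata).reset_index()
    agg = gamma_aggregate(table, metadata)
    rows = meta.drop_duplicates("mesocosm_id")[
        ["mesocosm_id", "community_id", "prop_exotic_planted", "herbivore",
         "soil", "soil_amn", "richness_at_harvest"]
    ].set_index("mesocosm_id")
    pool = synthetic_species_pool().set_index("plant_species")
    diam = mesocosm_mean_diameter(
        meta, pool["mean_root_diameter_mm"].to_dict()
    )
    rows["root_diameter"] = diam
    profiles = partner_diversity(table, metadata)
    scores = weighted_generalism(table, metadata, profiles)
    rows["generalism"] = pd.Series(
        {s.mesocosm_id: s.weighted_score for s in scores}
    )
    if gamma:
        summaries = mean_rarefied_richness(agg, iterations=iterations, seed=seed)
        rows["gamma_richness"] = pd.Series(
            {s.unit_id: s.mean_richness for s in summaries}
        )
    return rows.reset_index()


def fit_richness_model(
    df: pd.DataFrame, maximal: bool = False
) -> ModelCandidate:
    """Individual rarefied-richness LMM.

    ``maximal`` fits the full three-way structure (root diameter x
    provenance x proportion exotic, plus the design treatments);
    otherwise the proportion-exotic model used for the replication
    loops.
    """
    if maximal:
        terms = frozenset(
            {
                ("root_diameter",), ("provenance",), ("prop_exotic_planted",),
                ("prop_exotic_planted", "root_diameter"),
                ("provenance", "root_diameter"),
                ("prop_exotic_planted", "provenance"),
                ("prop_exotic_planted", "provenance", "root_diameter"),
                ("herbivore",), ("soil",),
            }
        )
    else:
        terms = frozenset({("prop_exotic_planted",)})
    spec = ModelSpec("richness", terms, INDIVIDUAL_RANDOM_TERMS)
    return fit_lmm(spec, df)


def fit_mesocosm_model(
    df: pd.DataFrame, response: str, maximal: bool = False
) -> ModelCandidate:
    """Mesocosm-level LMM (gamma richness or generalism score)."""
    if maximal:
        terms = frozenset(
            {
                ("prop_exotic_planted",), ("root_diameter",),
                ("prop_exotic_planted", "root_diameter"),
                ("herbivore",), ("soil",), ("soil_amn",),
            }
        )
    else:
        terms = frozenset({("prop_exotic_planted",)})
    random = MESOCOSM_RANDOM_TERMS
    if response == "gamma_richness":
        random = random + (("richness_at_harvest", "0 + C(richness_at_harvest)"),)
    spec = ModelSpec(response, terms, random)
    return fit_lmm(spec, df)


def experiment_slopes(
    seed: int,
    config: SimConfig = SimConfig(),
    rarefaction_iters: int = 100,
) -> dict[str, float]:
    """One replicate experiment -> fitted proportion-exotic effects.

    Simulates a full default-scale experiment, builds the analysis
    table, and returns the proportion-exotic coefficients of the
    individual rarefied-richness LMM and the mesocosm generalism LMM.
    """
    metadata, table, _ = simulate_experiment(config, seed=seed)
    tab = prepare_analysis_table(table, metadata)
    rdf = sample_richness_frame(tab, metadata, iterations=rarefaction_iters, seed=seed)
    rich = fit_richness_model(rdf)
    gdf = mesocosm_frame(tab, metadata, gamma=False)
    gen = fit_mesocosm_model(gdf, "generalism")

    def coef(c):
        return float(
            c.fit_summary.set_index("term").loc["prop_exotic_planted", "estimate"]
        )

    return {"richness_slope": coef(rich), "generalism_slope": coef(gen)}
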