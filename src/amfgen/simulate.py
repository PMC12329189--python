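"""Synthetic mesocosm experiments with the statistical structure the
analysis assumes.

The generator emulates a pot experiment in which 20 eight-species plant
communities, replicated eight times (160 mesocosms), vary in the planted
proportion of exotic species (0, 0.25, 0.5, 0.75, 1), crossed with
home/away soil and herbivore addition/exclusion treatments. Roots of
surviving plants are "sequenced": per-plant OTU counts follow a
Dirichlet-multinomial whose mean composition combines heavily
right-skewed OTU base abundances (lognormal; the skew default is
calibrated so the two most abundant OTUs hold more than half of all
reads in expectation), per-OTU host-affinity profiles (generalists
near-uniform over plant species, specialists concentrated on a few), and
two planted effects:

* per-plant occupancy of specialist OTUs is thinned by
  exp(richness_decline_beta * p) with p the exotic proportion, while
  generalists are exempt (multiplier capped at 1), so expected richness
  declines with exotic dominance;
* generalist OTU abundance is additionally tilted by
  exp(generalism_shift_beta * p), so the generalist read share rises
  with exotic dominance.

``simulate_fastq`` additionally renders a count table as per-sample
FASTQ files with known spiked short reads, low-quality reads and a
negative-control contaminant, together with the exact table the read
pipeline should recover — the basis of the end-to-end truth-recovery
test.

All randomness flows from an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .io_formats import METADATA_COLUMNS, OtuTable, ReadRecord, write_fastq

__all__ = [
    "SimConfig",
    "synthetic_species_pool",
    "synthetic_root_measurements",
    "simulate_design",
    "simulate_counts",
    "simulate_fastq",
    "simulate_experiment",
]

_FAMILIES = [
    ("Glomeraceae", "Glomerales", 0.45),
    ("Acaulosporaceae", "Diversisporales", 0.19),
    ("Archaeosporaceae", "Archaeosporales", 0.13),
    ("Claroideoglomeraceae", "Glomerales", 0.09),
    ("Diversisporaceae", "Diversisporales", 0.06),
    ("Paraglomeraceae", "Paraglomerales", 0.05),
    ("Gigasporaceae", "Diversisporales", 0.03),
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study conditions."""

    n_communities: int = 20
    reps_per_community: int = 8
    species_per_community: int = 8
    species_pool: int = 39
    n_nonmycorrhizal: int = 4
    exotic_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_otus: int = 95
    prop_generalist_otus: float = 0.2
    abundance_skew: float = 2.5  # lognormal sigma of OTU base abundances
    generalist_affinity_conc: float = 5.0
    specialist_affinity_conc: float = 0.15
    base_occupancy: float = 0.4
    occupancy_abundance_exp: float = 0.8
    nonmyco_occupancy_factor: float = 0.05
    richness_decline_beta: float = -0.3
    generalism_shift_beta: float = 0.5
    dm_concentration: float = 50.0
    depth_median: float = 15_000.0
    depth_sigma: float = 1.0
    depth_min: int = 300
    depth_max: int = 170_000
    mortality_prob: float = 0.25
    # FASTQ rendering
    read_length: int = 250
    read_quality: int = 40
    read_error_rate: float | None = None  # None: implied by read_quality
    spike_short_rate: float = 0.02
    spike_lowq_rate: float = 0.02
    contaminant_control_reads: int = 5
    contaminant_sample_reads: int = 10
    n_unmatched_otus: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prop_generalist_otus <= 1:
            raise ValueError("prop_generalist_otus outside [0, 1]")
        if not 0 <= self.mortality_prob <= 1:
            raise ValueError("mortality_prob outside [0, 1]")
        if min(self.n_communities, self.reps_per_community,
               self.species_per_community, self.n_otus, self.species_pool) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")

    @classmethod
    def small_pipeline(cls, **overrides) -> "SimConfig":
        """A reduced configuration for end-to-end read-pipeline tests."""
        base = dict(
            n_communities=2, reps_per_community=2, n_otus=12,
            abundance_skew=1.5, depth_median=2500.0, depth_sigma=0.3,
            depth_min=700, depth_max=6000, base_occupancy=0.5,
        )
        base.update(overrides)
        return cls(**base)


def synthetic_species_pool(config: SimConfig = SimConfig()) -> pd.DataFrame:
    """Synthetic plant species pool (stand-in for the study's species list).

    20 exotic and 19 native species with per-species mean root diameters
    constructed so the equal-species-weighted provenance means are
    0.302 mm (exotic) and 0.317 mm (native); the last two species of
    each provenance are flagged non-mycorrhizal (4 of 39).
    """
    if config.species_pool != 39 or config.n_nonmycorrhizal != 4:
        raise ValueError(
            "the synthetic species pool is defined for the default "
            "39-species / 4-nonmycorrhizal design"
        )
    rows = []
    n_exo, n_nat = 20, 19
    for i in range(n_exo):
        rows.append(
            {
                "plant_species": f"Exo{i + 1:02d}",
                "provenance": "exotic",
                "mean_root_diameter_mm": round(0.302 + 0.01 * (i - (n_exo - 1) / 2), 4),
                "mycorrhizal_host": i < n_exo - 2,
            }
        )
    for i in range(n_nat):
        rows.append(
            {
                "plant_species": f"Nat{i + 1:02d}",
                "provenance": "native",
                "mean_root_diameter_mm": round(0.317 + 0.01 * (i - (n_nat - 1) / 2), 4),
                "mycorrhizal_host": i < n_nat - 2,
            }
        )
    return pd.DataFrame(rows)


def synthetic_root_measurements(config: SimConfig = SimConfig()) -> pd.DataFrame:
    """Synthetic per-order root-diameter measurements.

    Stand-in for the study's supplementary species trait table, which is
    not redistributable here. Three individuals per species, orders 1-3,
    three locations per order; offsets are mean-preserving, so each
    species' order means are d - 0.06, d, d + 0.06 around its target
    mean d and the provenance grand means are exactly 0.302 / 0.317 mm.
    """
    pool = synthetic_species_pool(config)
    rows = []
    ind_offsets = (-0.004, 0.0, 0.004)
    loc_offsets = (-0.002, 0.0, 0.002)
    for _, sp in pool.iterrows():
        d = sp["mean_root_diameter_mm"]
        for j, ind_off in enumerate(ind_offsets):
            for order, order_off in ((1, -0.06), (2, 0.0), (3, 0.06)):
                base = d + order_off + ind_off
                rows.append(
                    {
                        "plant_species": sp["plant_species"],
                        "individual_id": f"{sp['plant_species']}_i{j + 1}",
                        "root_order": order,
                        "d1_mm": round(base + loc_offsets[0], 6),
                        "d2_mm": round(base + loc_offsets[1], 6),
                        "d3_mm": round(base + loc_offsets[2], 6),
                    }
                )
    return pd.DataFrame(rows)


def simulate_design(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Experimental design and plant survival: one metadata row per
    surviving (sampled) plant.

    Communities cycle through the exotic levels; each community's eight
    replicate mesocosms fully cross soil (home/away) and herbivore
    (added/excluded) treatments. Mortality is independent Bernoulli per
    plant, with at least one survivor kept per mesocosm so every
    mesocosm yields samples.
    """
    pool = synthetic_species_pool(config)
    exotics = pool[pool["provenance"] == "exotic"]["plant_species"].tolist()
    natives = pool[pool["provenance"] == "native"]["plant_species"].tolist()
    info = pool.set_index("plant_species")
    levels = list(config.exotic_levels)
    rows = []
    for c in range(config.n_communities):
        p_exotic = levels[c % len(levels)]
        community_id = f"C{c + 1:02d}"
        n_exo = int(round(config.species_per_community * p_exotic))
        n_nat = config.species_per_community - n_exo
        if n_exo > len(exotics) or n_nat > len(natives):
            raise ValueError("species pool too small for community composition")
        members = sorted(
            rng.choice(exotics, size=n_exo, replace=False).tolist()
            + rng.choice(natives, size=n_nat, replace=False).tolist()
        )
        soil_amn = rng.lognormal(np.log(40.0), 0.3)
        for r in range(config.reps_per_community):
            mesocosm_id = f"{community_id}M{r + 1}"
            soil = "home" if (r // 2) % 2 == 0 else "away"
            herbivore = "added" if r % 2 == 0 else "excluded"
            alive = rng.random(len(members)) >= config.mortality_prob
            if not alive.any():
                alive[int(rng.integers(len(members)))] = True
            survivors = [m for m, a in zip(members, alive) if a]
            for j, sp in enumerate(survivors):
                rows.append(
                    {
                        "sample_id": f"{mesocosm_id}_P{j + 1}",
                        "plant_species": sp,
                        "provenance": info.loc[sp, "provenance"],
                        "mesocosm_id": mesocosm_id,
                        "community_id": community_id,
                        "prop_exotic_planted": p_exotic,
                        "herbivore": herbivore,
                        "soil": soil,
                        "soil_amn": round(float(soil_amn), 3),
                        "richness_at_harvest": len(survivors),
                        "mycorrhizal_host": bool(info.loc[sp, "mycorrhizal_host"]),
                    }
                )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def _otu_parameters(config: SimConfig, rng: np.random.Generator) -> dict:
    """Base abundances, generalist flags, host affinities, taxonomy."""
    pool = synthetic_species_pool(config)
    species = pool["plant_species"].tolist()
    base = rng.lognormal(0.0, config.abundance_skew, size=config.n_otus)
    order = np.argsort(-base)  # OTU ids in decreasing base abundance
    base = base[order]
    n_gen = int(round(config.prop_generalist_otus * config.n_otus))
    # the dominant taxa are generalists (widespread fungi dominate read
    # counts in root amplicon data) but generalism is not confined to
    # them: flags go to the two top-abundance OTUs plus evenly spaced
    # mid-abundance ranks, so specialists collectively retain a
    # substantial read share and the generalist share has room to move
    generalist = np.zeros(config.n_otus, dtype=bool)
    n_top = min(2, n_gen)
    generalist[:n_top] = True
    if n_gen > n_top:
        spread = np.unique(
            np.round(np.linspace(n_top, config.n_otus - 1, n_gen - n_top)).astype(int)
        )
        generalist[spread] = True
    conc = np.where(
        generalist, config.generalist_affinity_conc, config.specialist_affinity_conc
    )
    affinity = np.vstack(
        [rng.dirichlet(np.full(len(species), c)) for c in conc]
    )
    fam_probs = np.array([w for _, _, w in _FAMILIES])
    fam_idx = rng.choice(len(_FAMILIES), size=config.n_otus, p=fam_probs / fam_probs.sum())
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(config.n_otus)]
    annotations = {
        otu: {
            "family": _FAMILIES[f][0],
            "order": _FAMILIES[f][1],
            "vt_match": f"VTX{5000 + i:05d}",
        }
        for i, (otu, f) in enumerate(zip(otu_ids, fam_idx))
    }
    return {
        "otu_ids": otu_ids,
        "species": species,
        "base_abundance": base,
        "generalist": generalist,
        "affinity": affinity,
        "annotations": annotations,
    }


def simulate_counts(
    metadata: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> tuple[OtuTable, dict]:
    """Per-sample OTU counts via occupancy thinning + Dirichlet-multinomial.

    Returns the count table and the ground-truth generator parameters
    (base abundances, generalist flags, affinities) for recovery tests.
    """
    params = _otu_parameters(config, rng)
    species_index = {s: i for i, s in enumerate(params["species"])}
    n_otus = config.n_otus
    base = params["base_abundance"]
    affinity = params["affinity"]
    generalist = params["generalist"]
    counts = np.zeros((len(metadata), n_otus), dtype=np.int64)
    log_depth_median = np.log(config.depth_median)
    # abundance-occupancy coupling: regionally abundant OTUs are also
    # widespread (dominant taxa near-ubiquitous, rare taxa sparse)
    rel_abund = base / base.sum()
    occ_abund = (n_otus * rel_abund) ** config.occupancy_abundance_exp
    for i, row in enumerate(metadata.itertuples(index=False)):
        s_idx = species_index[row.plant_species]
        p = float(row.prop_exotic_planted)
        # occupancy thinning with exotic proportion, offset for
        # generalists by the tilt (rare/specialist taxa are lost while
        # widespread generalists persist), so richness falls with p
        # while the generalist read share rises; the multiplier is
        # capped at 1 so occupancy never exceeds its baseline
        thin = np.minimum(
            1.0,
            np.exp(
                config.richness_decline_beta * p
                + config.generalism_shift_beta * p * generalist
            ),
        )
        occ_prob = (
            np.minimum(
                0.95,
                config.base_occupancy
                * occ_abund
                * len(species_index)
                * affinity[:, s_idx],
            )
            * thin
        )
        if not row.mycorrhizal_host:
            occ_prob = occ_prob * config.nonmyco_occupancy_factor
        occupied = rng.random(n_otus) < occ_prob
        if not occupied.any():
            occupied[int(np.argmax(occ_prob))] = True
        w = base[occupied] * affinity[occupied, s_idx]
        w = w * np.exp(config.generalism_shift_beta * p * generalist[occupied])
        w = w / w.sum()
        depth = int(
            np.clip(
                rng.lognormal(log_depth_median, config.depth_sigma),
                config.depth_min,
                config.depth_max,
            )
        )
        comp = rng.dirichlet(config.dm_concentration * w + 1e-9)
        counts[i, occupied] = rng.multinomial(depth, comp)
    table = OtuTable(
        pd.DataFrame(
            counts,
            index=pd.Index(metadata["sample_id"], name="sample_id"),
            columns=params["otu_ids"],
        ),
        params["annotations"],
    )
    return table, params


def simulate_experiment(
    config: SimConfig = SimConfig(), seed: int | None = None
) -> tuple[pd.DataFrame, OtuTable, dict]:
    """Design + counts in one call; seed defaults to ``config.seed``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    metadata = simulate_design(config, rng)
    table, params = simulate_counts(metadata, config, rng)
    return metadata, table, params


# ---------------------------------------------------------------------------
# FASTQ rendering with known truth


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.where(rng.random(len(arr)) < rate)[0]
    bases = np.array(list("ACGT"), dtype="S1")
    for i in hit:
        arr[i] = rng.choice(bases[bases != arr[i]])
    return arr.tobytes().decode()


def simulate_fastq(
    table: OtuTable,
    config: SimConfig,
    rng: np.random.Generator,
    out_dir: str | Path,
) -> dict:
    """Render a count table as per-sample FASTQ files with known truth.

    Every read is its OTU's random 250-mer reference (mutually divergent
    far below any clustering threshold), mutated at the per-base error
    rate implied by the emitted quality score (or ``read_error_rate`` if
    set). Spiked into each sample at known rates: short reads (< 170 bp)
    and low-quality reads (Phred 2). A negative-control sample carries a
    contaminant sequence also spiked into the lexicographically first
    sample; the lowest-abundance ``n_unmatched_otus`` OTUs receive
    failing taxonomy hits. The returned truth dict contains the exact
    analysis table the filter -> dereplicate -> remove-rare -> cluster ->
    taxonomy -> control-subtraction -> depth-filter chain should produce.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    error_rate = (
        config.read_error_rate
        if config.read_error_rate is not None
        else 10.0 ** (-config.read_quality / 10.0)
    )
    refs = {otu: _random_reference(rng, config.read_length) for otu in table.otu_ids}
    contaminant_seq = _random_reference(rng, config.read_length)
    control_id = "NEGCTRL1"
    q_good = (config.read_quality,) * config.read_length
    q_short = (config.read_quality,) * 150
    q_low = (2,) * config.read_length

    by_total = table.counts.sum(axis=0).sort_values(kind="stable")
    unmatched = set(by_total.index[: config.n_unmatched_otus])

    spike_counts: dict[str, dict[str, int]] = {}
    first_sample = sorted(table.sample_ids)[0]
    for sample_id in table.sample_ids:
        row = table.counts.loc[sample_id]
        depth = int(row.sum())
        n_short = int(round(config.spike_short_rate * depth))
        n_lowq = int(round(config.spike_lowq_rate * depth))
        spike_counts[sample_id] = {"short": n_short, "low_quality": n_lowq}
        reads: list[ReadRecord] = []
        i = 0
        for otu, c in row[row > 0].items():
            for _ in range(int(c)):
                i += 1
                reads.append(
                    ReadRecord(
                        f"{sample_id}_r{i}",
                        _mutate(refs[otu], error_rate, rng),
                        q_good,
                    )
                )
        if sample_id == first_sample:
            for _ in range(config.contaminant_sample_reads):
                i += 1
                reads.append(ReadRecord(f"{sample_id}_r{i}", contaminant_seq, q_good))
        for k in range(n_short):
            src = refs[table.otu_ids[k % len(table.otu_ids)]]
            reads.append(ReadRecord(f"{sample_id}_short{k}", src[:150], q_short))
        for k in range(n_lowq):
            src = refs[table.otu_ids[k % len(table.otu_ids)]]
            reads.append(ReadRecord(f"{sample_id}_lowq{k}", src, q_low))
        write_fastq(reads, out_dir / f"{sample_id}.fastq")

    ctrl_reads = [
        ReadRecord(f"{control_id}_r{k + 1}", contaminant_seq, q_good)
        for k in range(config.contaminant_control_reads)
    ]
    write_fastq(ctrl_reads, out_dir / f"{control_id}.fastq")

    # expected analysis table, by direct arithmetic on the generative counts
    work = table.counts.copy()
    work["CONTAM"] = 0
    work.loc[first_sample, "CONTAM"] = config.contaminant_sample_reads
    # rare-unique removal: at zero error each OTU is one unique sequence
    # with global abundance = column total (+ control contaminant reads)
    global_totals = work.sum(axis=0)
    global_totals["CONTAM"] += config.contaminant_control_reads
    work = work.loc[:, global_totals >= 3]
    # taxonomy: unmatched OTUs removed, contaminant passes
    work = work.drop(columns=[c for c in unmatched if c in work.columns])
    # control subtraction
    if "CONTAM" in work.columns:
        work["CONTAM"] = (work["CONTAM"] - config.contaminant_control_reads).clip(lower=0)
    # depth filter, then drop all-zero OTU columns
    work = work.loc[work.sum(axis=1) >= 1000]
    work = work.loc[:, (work > 0).any(axis=0)]

    truth = {
        "references": refs,
        "contaminant_sequence": contaminant_seq,
        "control_sample_id": control_id,
        "first_sample_id": first_sample,
        "unmatched_otus": sorted(unmatched),
        "spike_counts": spike_counts,
        "error_rate": error_rate,
        "expected_table": work,
        "annotations": dict(table.otu_annotations),
    }
    (out_dir / "truth.json").write_text(
        json.dumps(
            {
                k: v
                for k, v in truth.items()
                if k not in ("expected_table", "references")
            }
            | {"references": refs,
               "expected_table": {
                   "samples": list(work.index),
                   "otus": list(work.columns),
                   "counts": work.to_numpy().tolist(),
               }},
            indent=1,
        )
    )
    return truth
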