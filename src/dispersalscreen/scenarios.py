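"""Coalescent simulation of nine hypothetical dispersal scenarios.

A long-lived rainforest tree is modelled as a chain of demes strung along
the east Australian coast.  All scenarios share a panmictic ancestral
phase ending 200 kya.  The large-fruited scenarios (iso, hd1–hd6) then
share a weak, distance-limited "megafauna era" background connectivity —
large seeds moved mostly locally, keeping demes connected but structured —
until the megafauna extinction (30 kya in these presets, inside the
50–16 kya extinction window).  The small-fruit faunal scenarios instead
keep continuous bird/bat-mediated connectivity throughout.  What happens
after 30 kya distinguishes the scenarios:

===========  ===============================================================
scenario id  migration history (years before present)
===========  ===============================================================
``fd1``      faunal: distance-weighted migration m0*exp(-d/lambda)
             throughout (volant dispersers unaffected by megafauna loss)
``fd2``      fd1 with a dispersal barrier in mid-chain: migration across it
             is reduced 100-fold
``iso``      post-megafauna isolation: all migration zero from 30 kya to
             the present
``hd1``      human dispersal: symmetric island-model migration 8–0 kya
             after iso-style isolation
``hd2``      hd1 with 10x lower migration
``hd3``      island-model migration confined to the 5000–4000 BP window
``hd4``      range expansion: no migration; one disjunct deme beyond the
             range edge founded from the edge deme 4 kya
``hd5``      one-way chain (directional) migration 8–0 kya
``hd6``      one-way chain migration confined to 5000–4000 BP
===========  ===============================================================

Each simulation yields a nuclear SNP genotype matrix (diploid samples,
biallelic segregating sites) and a chloroplast alignment (haploid,
uniparentally transmitted, effective size half the deme size, no
recombination).  Chloroplast lineages move with the same migration
matrices as nuclear ones: seed dispersal carries both genomes.

Times are user-facing years BP and converted to generations internally
(floor).  Migration matrices are forwards-in-time: entry ``[i, j]`` is the
fraction of deme i replaced by migrants from deme j per generation (this
equals msprime's backwards lineage-movement rate from i to j).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np
import pandas as pd
import yaml

from . import genio
from .diffstats import haversine_km, pairwise_fst
from .genio import Alignment, GenotypeMatrix

SCENARIO_IDS = ("fd1", "fd2", "iso", "hd1", "hd2", "hd3", "hd4", "hd5", "hd6")


class ScenarioError(ValueError):
    pass


class NoVariationError(ScenarioError):
    """Simulation produced zero segregating sites."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """A time slice [start_time, end_time) in years BP with a fixed
    per-generation forward migration matrix."""

    start_time: float
    end_time: float
    migration: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "migration", np.asarray(self.migration, dtype=float))


@dataclass(frozen=True)
class FoundingEvent:
    """Deme ``deme`` founded at ``time`` years BP from ``source``."""

    deme: int
    time: float
    source: int


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_id: str
    n_demes: int
    deme_coordinates: tuple[tuple[float, float], ...]  # (lat, lon) per deme
    deme_size: float
    epochs: tuple[Epoch, ...]  # ordered present -> past, contiguous from 0
    founding_events: tuple[FoundingEvent, ...]
    split_time: float  # years BP at which demes merge into the ancestor
    ancestral_size: float
    generation_time: float  # years
    mutation_rate: float  # per site per generation
    recombination_rate: float
    n_nuclear_sites: float  # bp simulated for SNP ascertainment
    cp_sequence_length: int
    samples_per_deme_nuclear: int
    samples_per_deme_cp: int
    seed: int

    def validate(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ScenarioError(f"unknown scenario_id {self.scenario_id!r}; valid: {SCENARIO_IDS}")
        if self.n_demes < 1:
            raise ScenarioError("n_demes must be >= 1")
        if len(self.deme_coordinates) != self.n_demes:
            raise ScenarioError("deme_coordinates length != n_demes")
        t = 0.0
        for e in self.epochs:
            if e.start_time != t:
                raise ScenarioError(
                    f"epochs must be contiguous, ordered present->past; epoch starts at "
                    f"{e.start_time}, expected {t}"
                )
            if e.end_time <= e.start_time:
                raise ScenarioError("epoch end_time must exceed start_time")
            m = e.migration
            if m.shape != (self.n_demes, self.n_demes):
                raise ScenarioError(f"migration matrix shape {m.shape} != ({self.n_demes}, {self.n_demes})")
            if (m < 0).any():
                raise ScenarioError("migration rates must be non-negative")
            if np.diag(m).any():
                raise ScenarioError("migration matrix diagonal must be zero")
            if (m.sum(axis=1) >= 1).any():
                raise ScenarioError("migration matrix row sums must be < 1")
            t = e.end_time
        if self.epochs and t != self.split_time:
            raise ScenarioError("epochs must cover exactly (0, split_time]")
        for f in self.founding_events:
            if not 0 < f.time < self.split_time:
                raise ScenarioError("founding times must fall inside the simulated time span")
            if not (0 <= f.deme < self.n_demes and 0 <= f.source < self.n_demes) or f.deme == f.source:
                raise ScenarioError("founding event deme/source out of range")
        for name in ("deme_size", "ancestral_size", "generation_time", "mutation_rate"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be positive")

    def years_to_gens(self, years: float) -> int:
        return int(math.floor(years / self.generation_time))


def zero_migration(n_demes: int) -> np.ndarray:
    return np.zeros((n_demes, n_demes))


def island_migration_matrix(n_demes: int, m_total: float) -> np.ndarray:
    """Symmetric island model: each deme receives a total migrant fraction
    ``m_total`` per generation, drawn equally from the other demes."""
    if n_demes < 2:
        return zero_migration(n_demes)
    m = np.full((n_demes, n_demes), m_total / (n_demes - 1))
    np.fill_diagonal(m, 0.0)
    return m


def distance_weighted_matrix(
    coords: Sequence[tuple[float, float]], m0: float, decay_km: float
) -> np.ndarray:
    """Faunal model: pairwise migrant fraction m0 * exp(-d_ij / decay_km)."""
    k = len(coords)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                d = haversine_km(*coords[i], *coords[j])
                m[i, j] = m0 * math.exp(-d / decay_km)
    return m


def one_way_chain_matrix(n_demes: int, m: float) -> np.ndarray:
    """Directional dispersal: deme i receives migrants only from deme i-1."""
    mat = zero_migration(n_demes)
    for i in range(1, n_demes):
        mat[i, i - 1] = m
    return mat


def _apply_barrier(m: np.ndarray, boundary: int, factor: float) -> np.ndarray:
    """Reduce migration across the boundary between demes boundary-1|boundary."""
    m = m.copy()
    left = np.arange(m.shape[0]) < boundary
    cross = np.logical_xor.outer(left, left)
    m[cross] *= factor
    return m


def _chain_coordinates(n_demes: int, lat0: float = -30.0, lon: float = 152.5,
                       spacing_km: float = 100.0) -> tuple[tuple[float, float], ...]:
    dlat = spacing_km / 111.195  # km per degree of latitude
    return tuple((lat0 + i * dlat, lon) for i in range(n_demes))


def _expansion_coordinates(n_demes: int, spacing_km: float = 100.0,
                           disjunct_km: float = 400.0) -> tuple[tuple[float, float], ...]:
    """Range-expansion geometry: a chain of n-1 demes plus one disjunct
    site well beyond the range edge, founded by human dispersal."""
    chain = _chain_coordinates(n_demes - 1, spacing_km=spacing_km)
    dlat = (spacing_km + disjunct_km) / 111.195
    return chain + ((chain[-1][0] + dlat, chain[-1][1]),)


# Default study conditions: a long-lived tree (30-year generations) in six
# demes of 1000 diploids spaced 100 km apart, split from a panmictic
# ancestor 200 kya.  Large-fruited scenarios share a weak, distance-limited
# "megafauna era" background connectivity from the deep split until the
# megafauna extinction: large seeds moved mostly locally, so demes were
# connected but far from panmictic.  Small-fruit faunal scenarios instead
# keep continuous volant-frugivore connectivity to the present.  Free rate
# constants, chosen once:
#   island migration 0.01/gen during human-dispersal windows (strong
#   homogenisation), bird-mediated faunal m0 = 2e-3 with an 80 km decay
#   (low Fst between neighbours, pronounced isolation by distance),
#   megafauna-era m0 = 2e-4 with a 120 km decay (connected, structured),
#   barrier factor 0.01.
_DEFAULTS = dict(
    n_demes=6,
    deme_size=1000.0,
    generation_time=30.0,
    mutation_rate=1e-8,
    # high per-bp recombination emulates a genome-wide sparse marker panel:
    # SNPs ~750 bp apart decorrelate, as DArT markers scattered across
    # chromosomes would be, instead of behaving as one linked window
    recombination_rate=1e-7,
    n_nuclear_sites=1_500_000.0,
    cp_sequence_length=100_000,
    samples_per_deme_nuclear=10,
    samples_per_deme_cp=3,
    seed=1,
)

DEEP_SPLIT = 200_000.0  # demes emerge from the panmictic ancestor
ISOLATION_START = 30_000.0  # megafauna gone; all large-fruit dispersal ceases
HUMAN_WINDOW = (8_000.0, 0.0)  # sustained human dispersal
HUMAN_PULSE = (5_000.0, 4_000.0)  # short ancient dispersal pulse
FOUNDING_TIME = 4_000.0
M_ISLAND = 0.01
M_FAUNAL = 2e-3
FAUNAL_DECAY_KM = 80.0
M_MEGAFAUNA = 2e-4
MEGAFAUNA_DECAY_KM = 120.0
M_CHAIN = 0.01
BARRIER_FACTOR = 0.01

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def _preset_epochs(scenario_id: str, n_demes: int, coords) -> tuple[tuple[Epoch, ...], tuple[FoundingEvent, ...], float]:
    zeros = zero_migration(n_demes)
    island = island_migration_matrix(n_demes, M_ISLAND)
    meg = distance_weighted_matrix(coords, M_MEGAFAUNA, MEGAFAUNA_DECAY_KM)
    T = DEEP_SPLIT
    if scenario_id in ("fd1", "fd2"):
        w = distance_weighted_matrix(coords, M_FAUNAL, FAUNAL_DECAY_KM)
        if scenario_id == "fd2":
            w = _apply_barrier(w, boundary=n_demes // 2, factor=BARRIER_FACTOR)
        return (Epoch(0, T, w),), (), T
    if scenario_id == "iso":
        return (Epoch(0, ISOLATION_START, zeros), Epoch(ISOLATION_START, T, meg)), (), T
    if scenario_id in ("hd1", "hd2"):
        mat = island if scenario_id == "hd1" else island_migration_matrix(n_demes, M_ISLAND / 10)
        return (
            Epoch(0, HUMAN_WINDOW[0], mat),
            Epoch(HUMAN_WINDOW[0], ISOLATION_START, zeros),
            Epoch(ISOLATION_START, T, meg),
        ), (), T
    if scenario_id in ("hd3", "hd6"):
        mat = island if scenario_id == "hd3" else one_way_chain_matrix(n_demes, M_CHAIN)
        return (
            Epoch(0, HUMAN_PULSE[1], zeros),
            Epoch(HUMAN_PULSE[1], HUMAN_PULSE[0], mat),
            Epoch(HUMAN_PULSE[0], ISOLATION_START, zeros),
            Epoch(ISOLATION_START, T, meg),
        ), (), T
    if scenario_id == "hd4":
        founding = (
            (FoundingEvent(deme=n_demes - 1, time=FOUNDING_TIME, source=n_demes - 2),)
            if n_demes >= 2
            else ()
        )
        return (Epoch(0, ISOLATION_START, zeros), Epoch(ISOLATION_START, T, meg)), founding, T
    if scenario_id == "hd5":
        chain = one_way_chain_matrix(n_demes, M_CHAIN)
        return (
            Epoch(0, HUMAN_WINDOW[0], chain),
            Epoch(HUMAN_WINDOW[0], ISOLATION_START, zeros),
            Epoch(ISOLATION_START, T, meg),
        ), (), T
    raise ScenarioError(f"unknown scenario_id {scenario_id!r}; valid ids: {SCENARIO_IDS}")


def build_scenario(scenario_id: str, **overrides) -> ScenarioConfig:
    """Build a fully populated, validated config for one of the nine presets.

    Deterministic: no randomness.  ``overrides`` may touch any declared
    :class:`ScenarioConfig` field; structural overrides (``n_demes``,
    ``deme_coordinates``) are applied before the preset migration history is
    constructed, so preset matrices come out at the right dimension.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ScenarioError(f"unknown scenario_id {scenario_id!r}; valid ids: {SCENARIO_IDS}")
    unknown = set(overrides) - _CONFIG_FIELDS
    if unknown:
        raise ScenarioError(f"unknown override fields {sorted(unknown)}")
    if "scenario_id" in overrides and overrides["scenario_id"] != scenario_id:
        raise ScenarioError("scenario_id override conflicts with argument")
    base = dict(_DEFAULTS)
    n_demes = int(overrides.get("n_demes", base["n_demes"]))
    default_coords = (
        _expansion_coordinates(n_demes) if scenario_id == "hd4" and n_demes >= 3
        else _chain_coordinates(n_demes)
    )
    coords = overrides.get("deme_coordinates") or default_coords
    coords = tuple((float(a), float(b)) for a, b in coords)
    epochs, founding, split = _preset_epochs(scenario_id, n_demes, coords)
    cfg = dict(
        base,
        scenario_id=scenario_id,
        n_demes=n_demes,
        deme_coordinates=coords,
        epochs=epochs,
        founding_events=founding,
        split_time=split,
        ancestral_size=n_demes * base["deme_size"],
    )
    for k, v in overrides.items():
        if k in ("n_demes", "deme_coordinates"):
            continue
        if k == "epochs":
            v = tuple(e if isinstance(e, Epoch) else Epoch(*e) for e in v)
        if k == "founding_events":
            v = tuple(f if isinstance(f, FoundingEvent) else FoundingEvent(*f) for f in v)
        cfg[k] = v
    config = ScenarioConfig(**cfg)
    config.validate()
    return config


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    """Load a scenario config from a YAML file mirroring the field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    scenario_id = data.pop("scenario_id")
    if "epochs" in data:
        data["epochs"] = tuple(
            Epoch(e["start_time"], e["end_time"], np.asarray(e["migration"])) for e in data["epochs"]
        )
    if "founding_events" in data:
        data["founding_events"] = tuple(
            FoundingEvent(f["deme"], f["time"], f["source"]) for f in data["founding_events"]
        )
    if "deme_coordinates" in data:
        data["deme_coordinates"] = tuple(tuple(c) for c in data["deme_coordinates"])
    return build_scenario(scenario_id, **data)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    genotype_matrix: GenotypeMatrix
    cp_alignment: Alignment
    sample_metadata: pd.DataFrame
    truth: dict

    @property
    def site_assignment(self) -> dict[str, str]:
        return dict(zip(self.sample_metadata["sample_id"], self.sample_metadata["site_code"]))


def _build_demography(config: ScenarioConfig, size_scale: float = 1.0) -> msprime.Demography:
    dem = msprime.Demography()
    names = [f"d{i}" for i in range(config.n_demes)]
    for n in names:
        dem.add_population(name=n, initial_size=config.deme_size * size_scale)
    dem.add_population(name="anc", initial_size=config.ancestral_size * size_scale)
    split_gens = config.years_to_gens(config.split_time)
    founded_at = {f.deme: config.years_to_gens(f.time) for f in config.founding_events}
    # Epoch migration: epoch 0 sets the initial rates; later epochs switch
    # rates at their (floored) start generation.  A founded deme does not
    # exist pastwards of its founding, so no route touching it may be
    # re-enabled by a deeper epoch.
    for k, epoch in enumerate(config.epochs):
        t = config.years_to_gens(epoch.start_time)
        if t >= split_gens and k > 0:
            continue
        for i in range(config.n_demes):
            for j in range(config.n_demes):
                if i == j:
                    continue
                if any(t >= ft for d, ft in founded_at.items() if d in (i, j)) and k > 0:
                    continue
                rate = float(epoch.migration[i, j])
                prev = float(config.epochs[k - 1].migration[i, j]) if k else None
                if k == 0:
                    if rate:
                        dem.set_migration_rate(source=names[i], dest=names[j], rate=rate)
                elif rate != prev:
                    dem.add_migration_rate_change(time=t, rate=rate, source=names[i], dest=names[j])
    for f in config.founding_events:
        t = config.years_to_gens(f.time)
        dem.add_mass_migration(time=t, source=names[f.deme], dest=names[f.source], proportion=1.0)
        # The founded deme does not exist pastwards of its founding: silence
        # every migration route touching it from that point back.
        for j in range(config.n_demes):
            if j != f.deme:
                dem.add_migration_rate_change(time=t, rate=0.0, source=names[f.deme], dest=names[j])
                dem.add_migration_rate_change(time=t, rate=0.0, source=names[j], dest=names[f.deme])
    dem.add_population_split(time=split_gens, derived=names, ancestral="anc")
    dem.sort_events()
    return dem


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 2)) + 1 for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_dataset(config: ScenarioConfig, seed: int | None = None) -> SimulatedDataset:
    """Run the nuclear and chloroplast coalescent simulations for a config.

    Returns biallelic nuclear SNPs (monomorphic sites dropped before
    export) from diploid samples plus a haploid chloroplast alignment of
    length ``cp_sequence_length``.  The chloroplast locus does not
    recombine and has effective size ``deme_size / 2`` per deme.  The same
    ``(config, seed)`` reproduces the dataset bit-identically.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    s_nuc_anc, s_nuc_mut, s_cp_anc, s_cp_mut, s_ref = _derive_seeds(seed, 5)
    names = [f"d{i}" for i in range(config.n_demes)]

    # nuclear
    dem = _build_demography(config)
    ts = msprime.sim_ancestry(
        samples={n: config.samples_per_deme_nuclear for n in names},
        demography=dem,
        sequence_length=config.n_nuclear_sites,
        recombination_rate=config.recombination_rate,
        random_seed=s_nuc_anc,
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, random_seed=s_nuc_mut,
        model=msprime.BinaryMutationModel(),
    )
    hap = ts.genotype_matrix()  # (sites, haploid samples)
    if hap.shape[0] == 0:
        raise NoVariationError(
            f"scenario {config.scenario_id}: no segregating nuclear sites "
            f"(n_nuclear_sites={config.n_nuclear_sites:g}, mu={config.mutation_rate:g})"
        )
    dip = hap[:, 0::2] + hap[:, 1::2]  # (sites, individuals)
    n_hap = hap.shape[1]
    seg = (hap.sum(axis=1) > 0) & (hap.sum(axis=1) < n_hap)
    if not seg.any():
        raise NoVariationError(f"scenario {config.scenario_id}: all nuclear sites monomorphic")
    dip = dip[seg]
    positions = ts.tables.sites.position[seg].astype(int)

    ind_pop = [ts.node(ind.nodes[0]).population for ind in ts.individuals()]
    sample_ids, rows = [], []
    counters: dict[str, int] = {}
    for pop in ind_pop:
        deme = ts.population(pop).metadata.get("name", f"d{pop}") if ts.population(pop).metadata else f"d{pop}"
        k = counters.get(deme, 0)
        counters[deme] = k + 1
        sid = f"{config.scenario_id}_{deme}_n{k:02d}"
        sample_ids.append(sid)
        lat, lon = config.deme_coordinates[int(deme[1:])]
        rows.append((sid, deme, lat, lon, "nuclear"))

    locus_ids = [f"snp_{p:09d}" for p in positions]
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        calls=dip.T.astype(np.int16),
        reproducibility=np.ones(len(locus_ids)),
        call_rate=np.ones(len(locus_ids)),
    )

    # chloroplast: haploid, uniparental -> effective size = deme_size / 2
    cp_ids: list[str] = []
    cp_seqs: list[str] = []
    if config.samples_per_deme_cp > 0 and config.cp_sequence_length > 0:
        dem_cp = _build_demography(config, size_scale=0.5)
        ts_cp = msprime.sim_ancestry(
            samples={n: config.samples_per_deme_cp for n in names},
            demography=dem_cp,
            sequence_length=config.cp_sequence_length,
            recombination_rate=0.0,
            ploidy=1,
            random_seed=s_cp_anc,
        )
        ts_cp = msprime.sim_mutations(ts_cp, rate=config.mutation_rate, random_seed=s_cp_mut)
        rng = np.random.default_rng(s_ref)
        ref = rng.choice(np.array(list("ACGT")), size=config.cp_sequence_length)
        n_cp = ts_cp.num_samples
        seqs = np.tile(ref, (n_cp, 1))
        for v in ts_cp.variants():
            pos = int(v.site.position)
            alleles = np.array([a if a else "N" for a in v.alleles])
            seqs[:, pos] = alleles[v.genotypes]
        cp_counters: dict[str, int] = {}
        for node in ts_cp.samples():
            pop = ts_cp.node(node).population
            deme = f"d{pop}"
            k = cp_counters.get(deme, 0)
            cp_counters[deme] = k + 1
            sid = f"{config.scenario_id}_{deme}_cp{k:02d}"
            cp_ids.append(sid)
            lat, lon = config.deme_coordinates[pop]
            rows.append((sid, deme, lat, lon, "cp"))
        cp_seqs = ["".join(s) for s in seqs]

    mid_lat = float(np.median([c[0] for c in config.deme_coordinates]))
    meta = pd.DataFrame(rows, columns=["sample_id", "site_code", "latitude", "longitude", "datatype"])
    meta.insert(1, "species_id", f"sim_{config.scenario_id}")
    meta["region_label"] = np.where(meta["latitude"] >= mid_lat, "north", "south")
    meta = meta[["sample_id", "species_id", "site_code", "latitude", "longitude", "region_label", "datatype"]]

    return SimulatedDataset(
        genotype_matrix=gm,
        cp_alignment=Alignment(ids=cp_ids, sequences=cp_seqs),
        sample_metadata=meta,
        truth={"scenario_id": config.scenario_id, "seed": seed, "config": config},
    )


# ---------------------------------------------------------------------------
# Replicated Fst profiles
# ---------------------------------------------------------------------------


def scenario_fst_profile(
    config: ScenarioConfig, n_replicates: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Fst across seeded replicate simulations of one scenario.

    Returns ``(per_replicate, summary)``: the first holds one row per
    (replicate, deme pair) with the Weir–Hill Fst; the second the mean and
    sd per deme pair across replicates, keyed (scenario, deme_i, deme_j).
    """
    if n_replicates < 1:
        raise ScenarioError("n_replicates must be >= 1")
    rep_seeds = _derive_seeds(seed, n_replicates)
    rows = []
    for r, rs in enumerate(rep_seeds):
        try:
            ds = simulate_dataset(config, seed=rs)
            fst = pairwise_fst(ds.genotype_matrix, ds.site_assignment)
        except ScenarioError as e:
            raise ScenarioError(f"replicate {r} (seed {rs}): {e}") from e
        for i in range(len(fst.site_codes)):
            for j in range(i + 1, len(fst.site_codes)):
                rows.append(
                    (config.scenario_id, r, fst.site_codes[i], fst.site_codes[j],
                     fst.values[i, j], fst.n_loci_used[i, j])
                )
    per_rep = pd.DataFrame(
        rows, columns=["scenario", "replicate", "deme_i", "deme_j", "fst", "n_loci_used"]
    )
    summary = (
        per_rep.groupby(["scenario", "deme_i", "deme_j"])["fst"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return per_rep, summary


def island_model_expected_fst(n_demes: int, four_nm: float) -> float:
    """Equilibrium pairwise Fst of the finite symmetric island model.

    For two demes of N diploids each receiving a total immigrant fraction m
    per generation from the d - 1 other demes, the coalescent expectations
    are E[T_within] = 2Nd and E[T_between] = 2Nd + (d - 1) / (2m), and the
    pairwise estimand (T_b - T_w) / T_b reduces to

        Fst = 1 / (1 + 4Nm d / (d - 1)).

    (The better-known (d/(d-1))^2 correction applies to the Fst of one
    deme against the pooled metapopulation, not to two-deme pairwise Fst.)
    """
    d = n_demes
    return 1.0 / (1.0 + four_nm * d / (d - 1))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + DArT CSV + FASTA + metadata CSV for a simulated dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = ds.truth["scenario_id"]
    paths = {
        "vcf": outdir / f"{sid}_genotypes.vcf",
        "dart_csv": outdir / f"{sid}_genotypes.csv",
        "fasta": outdir / f"{sid}_cp.fasta",
        "metadata": outdir / f"{sid}_metadata.csv",
    }
    genio.write_genotypes_vcf(ds.genotype_matrix, paths["vcf"])
    genio.write_genotypes_dart_csv(ds.genotype_matrix, paths["dart_csv"])
    if ds.cp_alignment.ids:
        genio.write_alignment(ds.cp_alignment, paths["fasta"])
    else:
        paths.pop("fasta")
    ds.sample_metadata.to_csv(paths["metadata"], index=False)
    return paths
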