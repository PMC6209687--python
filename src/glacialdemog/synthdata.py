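"""Synthetic multilocus studies with the statistical structure the
analysis pipeline assumes.

Emulates the study design end-to-end: 21 populations x 5 diploid
individuals, two phased nuclear loci (336 and 434 bp; 210 gene copies)
and one concatenated plastid locus (1814 bp; 105 copies, optionally
carrying 5 indel columns), an optional two-cluster split inducing
hierarchical structure, population coordinates on a jittered grid, and
eight ecological covariates with tunable cluster-linked (isolation by
ecology) and spatially autocorrelated (isolation by distance)
components. True parameters, cluster labels and ancestral sequences are
returned in the truth manifest so every downstream stage is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import coalsim
from .coalsim import (
    SCENARIOS,
    DemographicParams,
    Genealogy,
    LocusSpec,
    _coal_kernel,
    _epoch_arrays,
    default_labels,
    mutate_hky,
    sample_prior,
    study_design,
)
from .seqdata import HaplotypeAlignment, PopulationTable, StudyDataset

#: Ecological covariates: five bioclimatic variables and three soil
#: descriptors, with field-plausible means and spreads.
ENV_VARIABLES = {
    "BIO1": (8.0, 2.0),  # annual mean temperature, degC
    "BIO4": (950.0, 60.0),  # temperature seasonality (sd x 100)
    "BIO12": (550.0, 120.0),  # annual precipitation, mm
    "BIO15": (85.0, 10.0),  # precipitation seasonality, %
    "BIO17": (15.0, 8.0),  # precipitation of driest quarter, mm
    "carbon_density": (60.0, 15.0),  # t/ha
    "soil_moisture": (30.0, 8.0),  # %
    "soil_pH": (7.0, 0.5),
}

#: Default demographic history for generated studies: an
#: expansion-then-decline (S4-shaped) history with moderate sizes,
#: chosen to land per-site nuclear diversity in the ~0.001-0.02 range
#: typical of low-polymorphism nuclear genes in temperate oaks.
DEFAULT_PARAMS = DemographicParams(
    Ne=1.2e4, Na=1.0e4, Ndb=3.5e4, Ta=2.5e4, Tdb=900.0,
    mu_cp=6e-8, mu_nr=1.7e-7,
)


@dataclass
class ClusterSplit:
    n_pops_cluster2: int = 6
    split_time: float = 3600.0  # generations (~290 ka at 80 y/gen)


@dataclass
class SynthConfig:
    seed: int = 0
    scenario: str = "S4"
    params: DemographicParams | None = None  # None with from_prior=False -> defaults
    from_prior: bool = False
    n_populations: int = 21
    inds_per_pop: int = 5
    cluster_split: ClusterSplit | None = None
    ibe_strength: float = 0.5
    ibd_strength: float = 0.3
    plastid_indels: int = 5
    fix_plastid: bool = False
    env_variables: tuple[str, ...] = tuple(ENV_VARIABLES)

    def __post_init__(self):
        if self.n_populations < 2:
            raise ValueError("need >= 2 populations")
        for s in (self.ibe_strength, self.ibd_strength):
            if not (0 <= s <= 1):
                raise ValueError("strengths must lie in [0, 1]")
        if self.cluster_split is not None:
            cs = self.cluster_split
            if not (0 < cs.n_pops_cluster2 < self.n_populations):
                raise ValueError("inconsistent cluster sizing")


def _split_genealogy(
    n1: int,
    n2: int,
    t_split: float,
    scenario,
    params: DemographicParams,
    locus: LocusSpec,
    rng: np.random.Generator,
) -> Genealogy:
    """Two demes of constant size Ne exchanging no migrants, merging at
    t_split into an ancestor that follows the scenario's trajectory."""
    n = n1 + n2
    at, asz, rates = _epoch_arrays(*scenario.anchors(params), locus.size_multiplier)
    deme_at = np.array([0.0])
    deme_sz = np.array([2.0 * params.Ne * locus.size_multiplier])
    deme_rates = np.array([0.0])
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    ntimes = np.zeros(2 * n - 1)
    next_node = n
    remaining = []
    for lo, hi in ((0, n1), (n1, n)):
        active = np.arange(lo, hi, dtype=np.int64)
        k = active.size
        exps = rng.exponential(size=k + 1)
        u1, u2 = rng.random(k + 1), rng.random(k + 1)
        k_left, _, _, next_node = _coal_kernel(
            active, k, parent, ntimes, 0.0, t_split,
            deme_at, deme_sz, deme_rates, exps, u1, u2, next_node,
        )
        remaining.append(active[:k_left])
    active = np.concatenate(remaining)
    k = active.size
    exps = rng.exponential(size=k + 1)
    u1, u2 = rng.random(k + 1), rng.random(k + 1)
    _coal_kernel(
        active, k, parent, ntimes, t_split, 1e300,
        at, asz, rates, exps, u1, u2, next_node,
    )
    # compact: unused node slots only occur if a deme coalesced fully;
    # they cannot (total events is always n-1), so arrays are dense.
    return Genealogy(parent, ntimes, n)


def generate_env_only(cfg: SynthConfig) -> tuple[PopulationTable, dict]:
    """Coordinates plus ecological covariates; reusable against external
    genetic data.

    Noise components are orthogonalized across variables, so covariates
    are uncorrelated by construction unless linked through the shared
    spatial field (ibd_strength) or the cluster shift (ibe_strength).
    """
    rng = np.random.default_rng([cfg.seed, 7])
    P = cfg.n_populations
    # jittered grid over ~10 deg x 8 deg
    side = math.ceil(math.sqrt(P))
    cells = [(r, c) for r in range(side) for c in range(side)][:P]
    rng.shuffle(cells)
    lat = np.array([33.0 + r * 8.0 / max(side - 1, 1) for r, _ in cells])
    lon = np.array([104.0 + c * 10.0 / max(side - 1, 1) for _, c in cells])
    lat = lat + rng.uniform(-0.4, 0.4, P)
    lon = lon + rng.uniform(-0.4, 0.4, P)
    cluster = np.ones(P, dtype=int)
    if cfg.cluster_split is not None:
        c2 = rng.choice(P, size=cfg.cluster_split.n_pops_cluster2, replace=False)
        cluster[c2] = 2
    V = len(cfg.env_variables)
    noise = rng.standard_normal((P, max(V, 2)))
    Q, _ = np.linalg.qr(noise - noise.mean(axis=0))
    ortho = Q[:, :V] * math.sqrt(P)  # unit-ish variance, zero correlation
    lat_z = (lat - lat.mean()) / lat.std()
    lon_z = (lon - lon.mean()) / lon.std()
    w = cfg.ibd_strength
    data = {}
    for j, name in enumerate(cfg.env_variables):
        mean, sd = ENV_VARIABLES.get(name, (0.0, 1.0))
        theta = rng.uniform(0, 2 * np.pi)
        spatial = math.cos(theta) * lat_z + math.sin(theta) * lon_z
        spatial = spatial / max(spatial.std(), 1e-12)
        fieldv = math.sqrt(max(1 - w**2, 0.0)) * ortho[:, j] + w * spatial
        x = mean + sd * fieldv
        if name == "BIO4":
            # 3 sd at full strength: a clear niche contrast between the
            # clusters that survives z-rescaling of the pooled variable
            x = x + cfg.ibe_strength * 3.0 * sd * (cluster == 2)
        if name == "BIO15":
            spread = 1.0 + cfg.ibe_strength * (cluster == 2)
            x = mean + sd * spread * fieldv
        data[name] = x
    pops = [f"P{p + 1:02d}" for p in range(P)]
    df = pd.DataFrame(
        dict(latitude=lat, longitude=lon, group=cluster, **data), index=pops
    )
    truth = dict(cluster=dict(zip(pops, cluster.tolist())))
    return PopulationTable(df), truth


def _insert_indel_columns(
    aln: HaplotypeAlignment, n_indels: int, rng: np.random.Generator
) -> HaplotypeAlignment:
    """Overwrite n random columns with presence/absence gap patterns.

    Carriers follow the minor-allele pattern of a randomly chosen
    segregating column, so indels are phylogenetically consistent (a
    deletion arises once on the genealogy) rather than scattered."""
    M = aln.to_matrix()
    n, L = M.shape
    seg_cols = [
        j for j in range(L)
        if len(set(M[:, j])) > 1
    ]
    cols = rng.choice(L, size=min(n_indels, L), replace=False)
    for c in cols:
        if seg_cols:
            ref = M[:, seg_cols[rng.integers(len(seg_cols))]]
            vals, counts = np.unique(ref, return_counts=True)
            carriers = ref == vals[np.argmin(counts)]
        else:
            carriers = np.zeros(n, dtype=bool)
            carriers[rng.integers(n)] = True
        M[carriers, c] = "-"
    return HaplotypeAlignment(
        locus_name=aln.locus_name,
        sequences=["".join(r) for r in M],
        sample_ids=list(aln.sample_ids),
        population_of=dict(aln.population_of),
        ploidy_tag=aln.ploidy_tag,
    )


def generate_study(cfg: SynthConfig) -> StudyDataset:
    """Generate a complete synthetic study (alignments + population
    table + truth manifest). Deterministic under cfg.seed."""
    rng = np.random.default_rng([cfg.seed, 1])
    scen = SCENARIOS[cfg.scenario]
    if cfg.params is not None:
        params = cfg.params
    elif cfg.from_prior:
        params = sample_prior(scen, rng)
    else:
        params = DEFAULT_PARAMS
    if cfg.cluster_split and not cfg.cluster_split.split_time < params.Ta:
        raise ValueError("cluster split time must predate Ta")
    pop_table, truth = generate_env_only(cfg)
    design = study_design(cfg.n_populations, cfg.inds_per_pop)
    # cluster-2 populations (from the env stage) are contiguous in leaf
    # order: re-order population ids so cluster 1 comes first
    cluster = np.array([truth["cluster"][p] for p in pop_table.population_ids])
    order = np.argsort(cluster, kind="stable")
    pops_ordered = [pop_table.population_ids[i] for i in order]
    n_c1 = int(np.sum(cluster == 1))
    loci, groups, ancestral = [], {}, {}
    for spec in design:
        mu = getattr(params, spec.mu_name)
        copies = 2 if spec.group == "nuclear" else 1
        if cfg.fix_plastid and spec.group == "plastid":
            n_per_pop = 1
        else:
            n_per_pop = copies * cfg.inds_per_pop
        n1, n2 = n_c1 * n_per_pop, (cfg.n_populations - n_c1) * n_per_pop
        sim_spec = LocusSpec(
            spec.name, spec.group, spec.length, n1 + n2,
            spec.size_multiplier, spec.kappa, spec.base_frequencies,
        )
        if cfg.cluster_split is not None:
            tree = _split_genealogy(
                n1, n2, cfg.cluster_split.split_time, scen, params, sim_spec, rng
            )
        else:
            tree = coalsim.simulate_genealogy(params, scen, sim_spec, rng)
        aln, anc = mutate_hky(tree, mu, sim_spec, rng)
        # relabel to the population design, cluster-1 populations first
        ids, pop_of, _ = default_labels(
            cfg.n_populations, cfg.inds_per_pop, phased=spec.group == "nuclear"
        )
        if cfg.fix_plastid and spec.group == "plastid":
            # one maternal lineage per population, fixed within it
            seqs = []
            out_ids, out_pop = [], {}
            base_ids, base_pop, _ = default_labels(
                cfg.n_populations, cfg.inds_per_pop, phased=False
            )
            for pi, pop in enumerate(pops_ordered):
                for sid in (s for s in base_ids if base_pop[s] == pop):
                    seqs.append(aln.sequences[pi])
                    out_ids.append(sid)
                    out_pop[sid] = pop
            aln = HaplotypeAlignment(
                spec.name, seqs, out_ids, out_pop, "plastid"
            )
        else:
            by_pop: dict[str, list[str]] = {}
            for sid in ids:
                by_pop.setdefault(pop_of[sid], []).append(sid)
            out_ids = [sid for pop in pops_ordered for sid in by_pop[pop]]
            aln = HaplotypeAlignment(
                spec.name,
                list(aln.sequences),
                out_ids,
                {sid: pop_of[sid] for sid in out_ids},
                aln.ploidy_tag,
            )
        if spec.group == "plastid" and cfg.plastid_indels:
            aln = _insert_indel_columns(aln, cfg.plastid_indels, rng)
        loci.append(aln)
        groups.setdefault(spec.group, []).append(spec.name)
        ancestral[spec.name] = anc
    truth.update(
        scenario=cfg.scenario,
        params=params.as_dict(),
        ancestral=ancestral,
        config=dict(
            seed=cfg.seed,
            n_populations=cfg.n_populations,
            inds_per_pop=cfg.inds_per_pop,
            ibe_strength=cfg.ibe_strength,
            ibd_strength=cfg.ibd_strength,
            cluster_split=(
                asdict(cfg.cluster_split) if cfg.cluster_split else None
            ),
        ),
    )
    return StudyDataset(
        loci=loci,
        locus_groups=groups,
        populations=pop_table,
        truth=truth,
    )
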