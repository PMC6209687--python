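"""Single-population coalescent simulator under piecewise-exponential
demography, with HKY mutation.

Seven demographic scenarios are parameterized as ordered anchor points
(time in generations, diploid effective size) with exponential
interpolation between anchors and a constant size beyond the last
anchor:

* S1 - constant size ``Ne``;
* S2 - exponential decline (forward in time) from ``Na`` to ``Ne``;
* S3 - exponential growth from ``Na`` to ``Ne``;
* S4/S5 - expansion to ``Ndb`` followed by decline to ``Ne``, the
  expansion-decline turn ``Tdb`` placed in a pre-glacial (S4, LIG-LGM)
  or post-glacial (S5, LGM-Holocene) window;
* S6/S7 - decline to ``Ndb`` followed by growth to ``Ne``, with the same
  two ``Tdb`` windows.

Coalescence waiting times are drawn by inverting the integrated pair-
coalescence rate, which is closed-form within each exponential epoch.
Scaling: a locus's effective chromosome count is ``2 N x multiplier``
(multiplier 1 for nuclear diploid loci, 0.5 for the maternally inherited
plastid locus), giving pair-coalescence rate ``k(k-1)/2 / (2 N m)``.

Mutations follow an HKY process with the rate matrix normalized so the
mean substitution rate equals ``mu`` per site per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .seqdata import HaplotypeAlignment, StudyDataset

BASES = "ACGT"
TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T

# Table 3 prior windows (generations for times)
PRIOR = {
    "Ne": (1e3, 1e5),
    "Na": (1e3, 1e5),
    "Ndb": (1e3, 1e5),
    "Ta": (1.25e4, 3.75e4),
    "mu_cp": (5e-8, 7e-8),
    "mu_nr": (1e-7, 3e-7),
}
TDB_PREGLACIAL = (2.5e2, 1.5e3)  # LIG -> LGM response, 20-120 ka at 80 y/gen
TDB_POSTGLACIAL = (75.0, 275.0)  # LGM -> Holocene, 6-22 ka


class PriorError(RuntimeError):
    pass


@dataclass(frozen=True)
class DemographicParams:
    Ne: float
    Na: float
    Ndb: float
    Ta: float
    Tdb: float
    mu_cp: float
    mu_nr: float

    def as_dict(self) -> dict:
        return asdict(self)

    NAMES = ("Ne", "Na", "Ndb", "Ta", "Tdb", "mu_cp", "mu_nr")


@dataclass(frozen=True)
class DemographicScenario:
    id: str
    n_anchors: int  # 1 (S1), 2 (S2/S3), 3 (S4-S7)
    tdb_window: tuple[float, float] | None
    description: str

    def anchors(self, p: DemographicParams) -> tuple[np.ndarray, np.ndarray]:
        """(times, diploid sizes); constant size beyond the last anchor."""
        if self.n_anchors == 1:
            return np.array([0.0]), np.array([p.Ne])
        if self.n_anchors == 2:
            return np.array([0.0, p.Ta]), np.array([p.Ne, p.Na])
        return np.array([0.0, p.Tdb, p.Ta]), np.array([p.Ne, p.Ndb, p.Na])

    def satisfies(self, p: DemographicParams) -> bool:
        if self.n_anchors >= 2 and not (p.Tdb < p.Ta):
            return False
        if self.id == "S2":
            return p.Na > p.Ne
        if self.id == "S3":
            return p.Na < p.Ne
        if self.id in ("S4", "S5"):
            return p.Ndb > p.Na and p.Ndb > p.Ne
        if self.id in ("S6", "S7"):
            return p.Ndb < p.Na and p.Ndb < p.Ne
        return True

    @property
    def free_parameters(self) -> tuple[str, ...]:
        base = ("mu_cp", "mu_nr")
        if self.n_anchors == 1:
            return ("Ne",) + base
        if self.n_anchors == 2:
            return ("Ne", "Na", "Ta") + base
        return ("Ne", "Na", "Ndb", "Ta", "Tdb") + base

    def size_at(self, t: float, p: DemographicParams) -> float:
        """Diploid size N(t) at backward time t (generations)."""
        at, asz = self.anchors(p)
        if t >= at[-1]:
            return float(asz[-1])
        k = int(np.searchsorted(at, t, side="right") - 1)
        r = math.log(asz[k + 1] / asz[k]) / (at[k + 1] - at[k])
        return float(asz[k] * math.exp(r * (t - at[k])))


SCENARIOS: dict[str, DemographicScenario] = {
    "S1": DemographicScenario("S1", 1, None, "constant size"),
    "S2": DemographicScenario("S2", 2, None, "exponential decline"),
    "S3": DemographicScenario("S3", 2, None, "exponential growth"),
    "S4": DemographicScenario("S4", 3, TDB_PREGLACIAL, "expansion then pre-glacial decline"),
    "S5": DemographicScenario("S5", 3, TDB_POSTGLACIAL, "expansion then post-glacial decline"),
    "S6": DemographicScenario("S6", 3, TDB_PREGLACIAL, "decline then pre-glacial expansion"),
    "S7": DemographicScenario("S7", 3, TDB_POSTGLACIAL, "decline then post-glacial expansion"),
}
SCENARIO_IDS = tuple(SCENARIOS)


@dataclass(frozen=True)
class LocusSpec:
    name: str
    group: str  # "plastid" | "nuclear"
    length: int
    sample_size: int
    size_multiplier: float = 1.0  # on the 2N chromosome scaling
    kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.length <= 0 or self.sample_size < 0:
            raise ValueError("invalid locus spec")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    @property
    def mu_name(self) -> str:
        return "mu_cp" if self.group == "plastid" else "mu_nr"


def study_design(
    n_pops: int = 21, inds_per_pop: int = 5
) -> list[LocusSpec]:
    """The study's sampling design: two phased nuclear loci (336 and
    434 bp, 2 copies x inds) and one concatenated plastid locus
    (1814 bp, 1 copy x inds)."""
    n_ind = n_pops * inds_per_pop
    return [
        LocusSpec("RPc", "nuclear", 336, 2 * n_ind, 1.0),
        LocusSpec("SAP", "nuclear", 434, 2 * n_ind, 1.0),
        LocusSpec("cpDNA", "plastid", 1814, n_ind, 0.5),
    ]


def sample_prior(
    scenario: DemographicScenario | str,
    rng: np.random.Generator,
    max_tries: int = 10**6,
) -> DemographicParams:
    """One uniform prior draw, with scenario ordering constraints
    enforced by rejection. Sizes and times are drawn uniformly on their
    natural scale (Table-3-style bounds)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    lo_t, hi_t = scenario.tdb_window or TDB_PREGLACIAL
    for _ in range(max_tries):
        p = DemographicParams(
            Ne=rng.uniform(*PRIOR["Ne"]),
            Na=rng.uniform(*PRIOR["Na"]),
            Ndb=rng.uniform(*PRIOR["Ndb"]),
            Ta=rng.uniform(*PRIOR["Ta"]),
            Tdb=rng.uniform(lo_t, hi_t),
            mu_cp=rng.uniform(*PRIOR["mu_cp"]),
            mu_nr=rng.uniform(*PRIOR["mu_nr"]),
        )
        if scenario.satisfies(p):
            return p
    raise PriorError(f"no admissible draw for {scenario.id} in {max_tries} tries")


# ---------------------------------------------------------------------------
# Coalescent kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _coal_kernel(active, n_active, parent, ntimes, t, t_stop,
                 at, asz, rates, exps, u1, u2, next_node):
    """Coalesce `active` lineages from time t until one remains or t_stop.

    at/asz/rates describe chromosome-count epochs: on epoch k,
    Nc(s) = asz[k] * exp(rates[k] * (s - at[k])); the last epoch is
    constant (rates[-1] == 0) and unbounded.
    Returns (n_active, t, n_events_used, next_node).
    """
    K = at.shape[0]
    ev = 0
    # locate current epoch
    ep = 0
    while ep < K - 1 and t >= at[ep + 1]:
        ep += 1
    k = n_active
    while k > 1:
        C = k * (k - 1) / 2.0
        E = exps[ev]
        fired = False
        while True:
            r = rates[ep]
            N0 = asz[ep] * math.exp(r * (t - at[ep]))
            end = at[ep + 1] if ep < K - 1 else 1e300
            if end > t_stop:
                end = t_stop
            if r == 0.0:
                w = E * N0 / C
                if t + w < end:
                    t = t + w
                    fired = True
                    break
                E -= C * (end - t) / N0
            else:
                arg = 1.0 - E * N0 * r / C
                if arg > 0.0:
                    w = -math.log(arg) / r
                else:
                    w = 1e300
                if t + w < end:
                    t = t + w
                    fired = True
                    break
                # integrated hazard to epoch end
                E -= C / (N0 * r) * (1.0 - math.exp(-r * (end - t)))
            t = end
            if t >= t_stop:
                return k, t, ev + 1, next_node
            ep += 1
        # merge a uniform pair
        i = int(u1[ev] * k)
        if i >= k:
            i = k - 1
        j = int(u2[ev] * (k - 1))
        if j >= k - 1:
            j = k - 2
        if j >= i:
            j += 1
        ev += 1
        a = active[i]
        b = active[j]
        parent[a] = next_node
        parent[b] = next_node
        ntimes[next_node] = t
        lo = i if i < j else j
        hi = j if i < j else i
        active[lo] = next_node
        active[hi] = active[k - 1]
        next_node += 1
        k -= 1
    return k, t, ev, next_node


@dataclass
class Genealogy:
    """A coalescent tree: node i's parent and time (generations).

    Leaves are nodes 0..n-1 at time 0; internal nodes are numbered in
    coalescence order, so a parent's index always exceeds its child's.
    The root has parent -1.
    """

    parent: np.ndarray
    node_times: np.ndarray
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_times[self.root]) if self.n_leaves > 1 else 0.0

    @property
    def total_branch_length(self) -> float:
        if self.n_leaves < 2:
            return 0.0
        bl = self.node_times[self.parent[:-1]] - self.node_times[:-1]
        return float(bl.sum())

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        return self.node_times[self.parent[:-1]] - self.node_times[:-1]


def _epoch_arrays(at: np.ndarray, asz_dip: np.ndarray, multiplier: float):
    """Chromosome-count epochs (sizes 2*N*multiplier) with per-epoch
    exponential rates; final epoch constant."""
    sz = 2.0 * asz_dip * multiplier
    K = len(at)
    rates = np.zeros(K)
    for k in range(K - 1):
        rates[k] = math.log(sz[k + 1] / sz[k]) / (at[k + 1] - at[k])
    return at.astype(float), sz.astype(float), rates


def simulate_genealogy(
    params: DemographicParams,
    scenario: DemographicScenario | str,
    locus: LocusSpec,
    rng: np.random.Generator,
) -> Genealogy:
    """Draw one n-coalescent genealogy for a locus under the scenario."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    n = locus.sample_size
    if n == 0:
        return Genealogy(np.empty(0, dtype=np.int64), np.empty(0), 0)
    if n == 1:
        return Genealogy(np.array([-1], dtype=np.int64), np.zeros(1), 1)
    at, asz, rates = _epoch_arrays(*scenario.anchors(params), locus.size_multiplier)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    ntimes = np.zeros(2 * n - 1)
    active = np.arange(n, dtype=np.int64)
    exps = rng.exponential(size=n + 1)
    u1 = rng.random(n + 1)
    u2 = rng.random(n + 1)
    _coal_kernel(active, n, parent, ntimes, 0.0, 1e300,
                 at, asz, rates, exps, u1, u2, n)
    return Genealogy(parent, ntimes, n)


# ---------------------------------------------------------------------------
# HKY mutation
# ---------------------------------------------------------------------------

def hky_model(kappa: float, freqs, mu: float):
    """Event rate and cumulative jump table for a uniformized HKY chain.

    Returns (q_event, cum) where mutation events occur at rate q_event
    per site per generation and cum[s] is the cumulative probability over
    target states 0..3 (self-transitions realize state-dependent rates);
    the generator is normalized so the mean substitution rate at
    stationarity is exactly mu.
    """
    freqs = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = freqs[j] * (kappa if (i, j) in TRANSITION else 1.0)
    leave = Q.sum(axis=1)
    mean_rate = float(freqs @ leave)
    if mu == 0.0:
        return 0.0, np.cumsum(np.eye(4), axis=1)
    Q *= mu / mean_rate
    leave = Q.sum(axis=1)
    q_event = float(leave.max())
    P = Q / q_event
    for i in range(4):
        P[i, i] = 1.0 - leave[i] / q_event
    return q_event, np.cumsum(P, axis=1)


@njit(cache=True)
def _propagate_mutations(parent, n_nodes, n_leaves, node_of, site_col, u_jump,
                         order, root_states, cum, tips):
    """Drop sorted mutation events down the tree; fill tip states.

    `order` indexes events sorted by (node, descending time) so that
    events on one branch apply oldest-first. `site_col` maps each event
    to a column of the per-site state matrix.
    """
    S = root_states.shape[0]
    states = np.empty((n_nodes, S), dtype=np.int8)
    for s in range(S):
        states[n_nodes - 1, s] = root_states[s]
    n_ev = order.shape[0]
    # order is sorted by node descending, time descending within node,
    # matching the descending-node traversal below
    ev_i = 0
    for v in range(n_nodes - 2, -1, -1):
        p = parent[v]
        for s in range(S):
            states[v, s] = states[p, s]
        while ev_i < n_ev and node_of[order[ev_i]] == v:
            e = order[ev_i]
            col = site_col[e]
            cur = states[v, col]
            u = u_jump[e]
            tgt = 3
            for j in range(4):
                if u < cum[cur, j]:
                    tgt = j
                    break
            states[v, col] = tgt
            ev_i += 1
    for i in range(n_leaves):
        for s in range(S):
            tips[i, s] = states[i, s]


@dataclass
class SiteData:
    """Segregating sites of one simulated locus.

    genotypes: (S, n) int8 matrix of base codes (0..3) per site x tip;
    positions: site coordinates in [0, L); ancestral: root base per site.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    ancestral: np.ndarray
    n: int
    length: int


def drop_mutations(
    tree: Genealogy,
    mu: float,
    locus: LocusSpec,
    rng: np.random.Generator,
    root_sequence: np.ndarray | None = None,
    segregating_only: bool = True,
) -> SiteData:
    """Place HKY mutations on a genealogy.

    Returns segregating sites only by default; with
    ``segregating_only=False`` every mutation-hit site is returned (a
    site where all tips share a derived state is invisible to summary
    statistics but matters when reconstructing full sequences)."""
    L = locus.length
    n = tree.n_leaves
    if n < 2:
        return SiteData(np.empty((0, max(n, 0)), np.int8), np.empty(0, np.int64),
                        np.empty(0, np.int8), n, L)
    q_event, cum = hky_model(locus.kappa, locus.base_frequencies, mu)
    T = tree.total_branch_length
    n_ev = rng.poisson(q_event * L * T)
    if n_ev == 0:
        return SiteData(np.empty((0, n), np.int8), np.empty(0, np.int64),
                        np.empty(0, np.int8), n, L)
    bl = tree.branch_lengths()
    nodes = rng.choice(tree.n_nodes - 1, size=n_ev, p=bl / T)
    sites = rng.integers(0, L, size=n_ev)
    times = tree.node_times[nodes] + rng.random(n_ev) * bl[nodes]
    u_jump = rng.random(n_ev)
    upos, site_col = np.unique(sites, return_inverse=True)
    S = upos.shape[0]
    if root_sequence is not None:
        root_states = root_sequence[upos].astype(np.int8)
    else:
        root_states = rng.choice(4, size=S, p=np.asarray(locus.base_frequencies)).astype(np.int8)
    order = np.lexsort((-times, -nodes))  # node desc, then time desc
    tips = np.empty((n, S), dtype=np.int8)
    _propagate_mutations(tree.parent, tree.n_nodes, n, nodes,
                         site_col.astype(np.int64), u_jump, order,
                         root_states, cum, tips)
    if segregating_only:
        keep = (tips != tips[0]).any(axis=0)
    else:
        keep = (tips != root_states[None, :]).any(axis=0)
    return SiteData(
        genotypes=np.ascontiguousarray(tips[:, keep].T),
        positions=upos[keep],
        ancestral=root_states[keep],
        n=n,
        length=L,
    )


def mutate_hky(
    tree: Genealogy,
    mu: float,
    locus: LocusSpec,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
    population_of: dict[str, str] | None = None,
) -> tuple[HaplotypeAlignment, str]:
    """Full sequences for the tips of a genealogy under HKY.

    Returns (alignment, ancestral_sequence). The root sequence is drawn
    from the stationary base frequencies.
    """
    L = locus.length
    n = tree.n_leaves
    root_seq = rng.choice(4, size=L, p=np.asarray(locus.base_frequencies))
    sd = drop_mutations(
        tree, mu, locus, rng, root_sequence=root_seq, segregating_only=False
    )
    mat = np.tile(root_seq.astype(np.int8), (n, 1))
    if sd.genotypes.size:
        mat[:, sd.positions] = sd.genotypes.T
    base = np.array(list(BASES), dtype="U1")
    seqs = ["".join(base[row]) for row in mat]
    if sample_ids is None:
        sample_ids = [f"seq{i}" for i in range(n)]
    if population_of is None:
        population_of = {sid: "pop1" for sid in sample_ids}
    aln = HaplotypeAlignment(
        locus_name=locus.name,
        sequences=seqs,
        sample_ids=sample_ids,
        population_of=population_of,
        ploidy_tag="plastid" if locus.group == "plastid" else "nuclear-phased",
    )
    return aln, "".join(base[root_seq])


def default_labels(n_pops: int, inds_per_pop: int, phased: bool):
    """Sequence labels / popmap for a 21x5-style design, input order."""
    ids, pop_of, ind_of = [], {}, {}
    for p in range(n_pops):
        pop = f"P{p + 1:02d}"
        for i in range(inds_per_pop):
            ind = f"{pop}_I{i + 1}"
            copies = (f"{ind}_a", f"{ind}_b") if phased else (ind,)
            for sid in copies:
                ids.append(sid)
                pop_of[sid] = pop
                ind_of[sid] = ind
    return ids, pop_of, ind_of


def simulate_dataset(
    scenario: DemographicScenario | str,
    params: DemographicParams,
    design: list[LocusSpec] | None = None,
    rng: np.random.Generator | None = None,
    n_pops: int = 21,
    inds_per_pop: int = 5,
) -> StudyDataset:
    """Simulate a full multilocus dataset: independent genealogies per
    locus, population labels assigned in input order (the single
    panmictic deme of the inference model carries arbitrary labels)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    rng = rng or np.random.default_rng()
    design = design or study_design(n_pops, inds_per_pop)
    loci, groups, ancestrals = [], {}, {}
    for spec in design:
        mu = getattr(params, spec.mu_name)
        tree = simulate_genealogy(params, scenario, spec, rng)
        ids, pop_of, _ = default_labels(
            n_pops, inds_per_pop, phased=spec.group == "nuclear"
        )
        if len(ids) != spec.sample_size:
            ids = [f"seq{i}" for i in range(spec.sample_size)]
            pop_of = {s: "pop1" for s in ids}
        aln, anc = mutate_hky(tree, mu, spec, rng, ids, pop_of)
        loci.append(aln)
        groups.setdefault(spec.group, []).append(spec.name)
        ancestrals[spec.name] = anc
    return StudyDataset(
        loci=loci,
        locus_groups=groups,
        truth=dict(
            scenario=scenario.id, params=params.as_dict(), ancestral=ancestrals
        ),
    )


def simulate_site_data(
    scenario: DemographicScenario | str,
    params: DemographicParams,
    design: list[LocusSpec],
    rng: np.random.Generator,
) -> list[SiteData]:
    """Fast path for mass simulation: segregating sites only, no
    sequence strings. Used to build ABC reference tables."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    out = []
    for spec in design:
        mu = getattr(params, spec.mu_name)
        tree = simulate_genealogy(params, scenario, spec, rng)
        out.append(drop_mutations(tree, mu, spec, rng))
    return out
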