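"""Analysis of molecular variance (AMOVA) on sequence data.

Excoffier-style variance decomposition computed from squared pairwise
distances (here: counts of differing sites), with Phi-statistics and
permutation significance. One-level (populations) and two-level
(groups / populations-within-groups) designs, plus pairwise F_ST
matrices between populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import encode, pairwise_differences
from .seqdata import HaplotypeAlignment


@dataclass
class AmovaResult:
    levels: str  # "one-level" | "two-level"
    df: dict[str, int]
    sums_of_squares: dict[str, float]
    variance_components: dict[str, float]  # raw, may be negative
    percent_variation: dict[str, float]  # after flooring negatives at 0
    phi_stats: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum in self.sums_of_squares:
            rows.append(
                dict(
                    source=stratum,
                    df=self.df[stratum],
                    sum_of_squares=self.sums_of_squares[stratum],
                    variance=self.variance_components[stratum],
                    percent=self.percent_variation[stratum],
                )
            )
        return pd.DataFrame(rows)


def _group_ss(D2: np.ndarray, index_sets: list[np.ndarray]) -> float:
    """Sum over sets of (sum of squared distances within set) / set size."""
    total = 0.0
    for idx in index_sets:
        if idx.size > 1:
            total += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def _percent(components: dict[str, float]) -> dict[str, float]:
    floored = {k: max(v, 0.0) for k, v in components.items()}
    tot = sum(floored.values())
    if tot <= 0:
        return {k: float("nan") for k in components}
    return {k: 100.0 * v / tot for k, v in floored.items()}


def _one_level_components(D2, labels, pops):
    n = len(labels)
    P = len(pops)
    sets = [np.flatnonzero(labels == p) for p in pops]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = _group_ss(D2, sets)
    ss_among = ss_total - ss_within
    df_a, df_w = P - 1, n - P
    ms_w = ss_within / df_w if df_w else 0.0
    ms_a = ss_among / df_a
    sizes = np.array([s.size for s in sets], dtype=float)
    n0 = (n - np.sum(sizes**2) / n) / (P - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    return ss_among, ss_within, sigma_a, sigma_w, df_a, df_w


def amova_one_level(
    aln: HaplotypeAlignment,
    n_permutations: int = 1000,
    indels_informative: bool = True,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """One-level AMOVA: among vs within populations.

    F_ST significance by permuting sequences among populations; the
    observed configuration is counted, so p >= 1/(n_permutations + 1).
    Returns F_ST = NaN when the dataset carries no molecular variance.
    """
    rng = rng or np.random.default_rng()
    X = encode(aln, indels_informative)
    D2 = pairwise_differences(X).astype(float)
    labels = np.asarray(aln.population_labels())
    pops = aln.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    ss_a, ss_w, sig_a, sig_w, df_a, df_w = _one_level_components(D2, labels, pops)
    total = sig_a + sig_w
    if total <= 0:
        phi = float("nan")
        p = float("nan")
    else:
        phi = sig_a / total
        exceed = 0
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            _, _, pa, pw, _, _ = _one_level_components(D2, perm, pops)
            if pa + pw > 0 and pa / (pa + pw) >= phi:
                exceed += 1
        p = (1.0 + exceed) / (n_permutations + 1.0)
    comps = {"among_populations": sig_a, "within_populations": sig_w}
    return AmovaResult(
        levels="one-level",
        df={"among_populations": df_a, "within_populations": df_w},
        sums_of_squares={"among_populations": ss_a, "within_populations": ss_w},
        variance_components=comps,
        percent_variation=_percent(comps),
        phi_stats={"F_ST": phi},
        p_values={"F_ST": p},
        n_permutations=n_permutations,
    )


def _two_level_components(D2, labels, group_of_pop, pops, groups):
    n = len(labels)
    P = len(pops)
    G = len(groups)
    pop_sets = {p: np.flatnonzero(labels == p) for p in pops}
    group_sets = {
        g: np.concatenate([pop_sets[p] for p in pops if group_of_pop[p] == g])
        for g in groups
    }
    ss_total = D2.sum() / (2.0 * n)
    ss_wp = _group_ss(D2, list(pop_sets.values()))
    ss_groups = _group_ss(D2, list(group_sets.values()))
    ss_ap_wg = ss_groups - ss_wp
    ss_ag = ss_total - ss_groups
    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    ms_ap = ss_ap_wg / df_ap if df_ap else 0.0
    ms_ag = ss_ag / df_ag
    sizes = {p: pop_sets[p].size for p in pops}
    gsizes = {g: group_sets[g].size for g in groups}
    sum_np2_over_ng = sum(
        sum(sizes[p] ** 2 for p in pops if group_of_pop[p] == g) / gsizes[g]
        for g in groups
    )
    n2 = (sum_np2_over_ng - sum(sizes[p] ** 2 for p in pops) / n) / (G - 1)
    n3 = (n - sum(gsizes[g] ** 2 for g in groups) / n) / (G - 1)
    sig_c = ms_wp
    if P == G:  # one population per group: no within-group stratum
        sig_b = 0.0
    else:
        n1 = (n - sum_np2_over_ng) / (P - G)
        sig_b = (ms_ap - sig_c) / n1
    sig_a = (ms_ag - sig_c - n2 * sig_b) / n3
    return (ss_ag, ss_ap_wg, ss_wp, sig_a, sig_b, sig_c, df_ag, df_ap, df_wp)


def amova_two_level(
    aln: HaplotypeAlignment,
    groups: dict[str, str],
    n_permutations: int = 1000,
    indels_informative: bool = True,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: among groups / among populations within groups /
    within populations, with F_CT, F_SC and F_ST.

    Permutation schemes: F_CT permutes whole populations among groups;
    F_SC permutes sequences among populations within their group; F_ST
    permutes sequences among all populations.
    """
    rng = rng or np.random.default_rng()
    pops = aln.populations
    group_ids = sorted(set(groups[p] for p in pops))
    if len(group_ids) < 2:
        import warnings

        warnings.warn("single group: falling back to one-level AMOVA")
        return amova_one_level(aln, n_permutations, indels_informative, rng)
    X = encode(aln, indels_informative)
    D2 = pairwise_differences(X).astype(float)
    labels = np.asarray(aln.population_labels())
    (ss_ag, ss_ap, ss_wp, sig_a, sig_b, sig_c, df_ag, df_ap, df_wp) = (
        _two_level_components(D2, labels, groups, pops, group_ids)
    )
    total = sig_a + sig_b + sig_c
    if total <= 0:
        phis = dict(F_CT=float("nan"), F_SC=float("nan"), F_ST=float("nan"))
        ps = dict(phis)
    else:
        phis = dict(
            F_CT=sig_a / total,
            F_SC=sig_b / (sig_b + sig_c) if (sig_b + sig_c) > 0 else float("nan"),
            F_ST=(sig_a + sig_b) / total,
        )
        exceed = dict(F_CT=0, F_SC=0, F_ST=0)
        # F_CT: permute populations among groups
        for _ in range(n_permutations):
            shuffled = rng.permutation(pops)
            g_perm = {p: groups[q] for p, q in zip(shuffled, pops)}
            _, _, _, pa, pb, pc, *_ = _two_level_components(
                D2, labels, g_perm, pops, group_ids
            )
            tot = pa + pb + pc
            if tot > 0 and pa / tot >= phis["F_CT"]:
                exceed["F_CT"] += 1
        # F_SC: permute sequences among populations within groups
        for _ in range(n_permutations):
            perm = labels.copy()
            for g in group_ids:
                in_g = np.flatnonzero(
                    np.isin(labels, [p for p in pops if groups[p] == g])
                )
                perm[in_g] = perm[rng.permutation(in_g)]
            _, _, _, pa, pb, pc, *_ = _two_level_components(
                D2, perm, groups, pops, group_ids
            )
            if (pb + pc) > 0 and pb / (pb + pc) >= phis["F_SC"]:
                exceed["F_SC"] += 1
        # F_ST: permute sequences among all populations
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            _, _, _, pa, pb, pc, *_ = _two_level_components(
                D2, perm, groups, pops, group_ids
            )
            tot = pa + pb + pc
            if tot > 0 and (pa + pb) / tot >= phis["F_ST"]:
                exceed["F_ST"] += 1
        ps = {
            k: (1.0 + exceed[k]) / (n_permutations + 1.0)
            for k in ("F_CT", "F_SC", "F_ST")
        }
    comps = {
        "among_groups": sig_a,
        "among_populations_within_groups": sig_b,
        "within_populations": sig_c,
    }
    return AmovaResult(
        levels="two-level",
        df={
            "among_groups": df_ag,
            "among_populations_within_groups": df_ap,
            "within_populations": df_wp,
        },
        sums_of_squares={
            "among_groups": ss_ag,
            "among_populations_within_groups": ss_ap,
            "within_populations": ss_wp,
        },
        variance_components=comps,
        percent_variation=_percent(comps),
        phi_stats=phis,
        p_values=ps,
        n_permutations=n_permutations,
    )


def pairwise_fst(
    aln: HaplotypeAlignment, indels_informative: bool = True
) -> pd.DataFrame:
    """Symmetric matrix of two-population AMOVA F_ST values.

    Diagonal 0; negative estimates retained; a pair with zero total
    molecular variance yields NaN.
    """
    pops = aln.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    X = encode(aln, indels_informative)
    D2 = pairwise_differences(X).astype(float)
    labels = np.asarray(aln.population_labels())
    F = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            idx = np.flatnonzero(np.isin(labels, [pops[a], pops[b]]))
            sub = D2[np.ix_(idx, idx)]
            _, _, sa, sw, _, _ = _one_level_components(
                sub, labels[idx], [pops[a], pops[b]]
            )
            tot = sa + sw
            F[a, b] = F[b, a] = sa / tot if tot > 0 else float("nan")
    return pd.DataFrame(F, index=pops, columns=pops)
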