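"""Per-locus diversity and neutrality statistics.

Implements the classical summary table machinery for a sequence locus:
segregating sites S, haplotype count Nh and diversity Hd, per-site
nucleotide diversity pi, the per-site Watterson estimator theta_W,
Tajima's D, the maximum-frequency-of-derived-mutations (MFDM) neutrality
test, haplotype accounting with private-haplotype flags, and the
Hudson-Kaplan lower bound Rm on the number of recombination events.

Missing data ('N') are excluded pairwise-complete; alignment gaps ('-')
are treated as a fifth informative state by default (set
``indels_informative=False`` to ignore gapped columns instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import HaplotypeAlignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": -1}


class SampleSizeError(ValueError):
    pass


class PolarizationError(ValueError):
    pass


def encode(aln: HaplotypeAlignment, indels_informative: bool = True) -> np.ndarray:
    """(n, L) int8 matrix; A,C,G,T,- -> 0..4; N -> -1 (missing).

    With ``indels_informative=False`` gaps are recoded as missing.
    """
    M = aln.to_matrix()
    X = np.empty(M.shape, dtype=np.int8)
    for ch, code in _CODE.items():
        X[M == ch] = code
    if not indels_informative:
        X[X == 4] = -1
    return X


def pairwise_differences(X: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts, pairwise-complete in N."""
    n, L = X.shape
    miss = X < 0
    # differ and both observed
    diff = (X[:, None, :] != X[None, :, :]) & ~miss[:, None, :] & ~miss[None, :, :]
    return diff.sum(axis=2)


def segregating_sites(X: np.ndarray) -> np.ndarray:
    """Boolean mask over columns with >= 2 distinct observed states."""
    n, L = X.shape
    seg = np.zeros(L, dtype=bool)
    for j in range(L):
        col = X[:, j]
        obs = col[col >= 0]
        seg[j] = obs.size > 0 and np.unique(obs).size > 1
    return seg


def _haplotype_groups(X: np.ndarray) -> list[list[int]]:
    """Group sequence indices into haplotypes, N acting as a wildcard.

    Sequences differing only at missing positions collapse into one
    haplotype; the group representative accumulates observed states.
    """
    n, L = X.shape
    reps: list[np.ndarray] = []
    groups: list[list[int]] = []
    for i in range(n):
        row = X[i]
        placed = False
        for g, rep in enumerate(reps):
            both = (row >= 0) & (rep >= 0)
            if np.all(row[both] == rep[both]):
                groups[g].append(i)
                fill = (rep < 0) & (row >= 0)
                rep[fill] = row[fill]
                placed = True
                break
        if not placed:
            reps.append(row.copy())
            groups.append([i])
    return groups


def tajimas_d(n: int, S: int, k_hat: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (per locus, not per site). NaN when S == 0 or n < 4 makes
    the variance non-positive."""
    if S == 0 or n < 2:
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((k_hat - S / a1) / np.sqrt(var))


@dataclass
class DiversityStats:
    n: int
    L: int
    L_complete: int  # columns without any missing character
    S: int
    Nh: int
    Hd: float
    pi: float  # per site
    theta_w: float  # per site
    tajima_d: float  # NaN when undefined (S == 0)
    mfdm_p: float = float("nan")

    def as_dict(self) -> dict:
        return dict(
            n=self.n, L=self.L, L_complete=self.L_complete, S=self.S,
            Nh=self.Nh, Hd=round(self.Hd, 4), pi=round(self.pi, 6),
            theta_w=round(self.theta_w, 6),
            tajima_d=round(self.tajima_d, 4) if np.isfinite(self.tajima_d) else float("nan"),
            mfdm_p=round(self.mfdm_p, 4) if np.isfinite(self.mfdm_p) else float("nan"),
        )


def compute_diversity(
    aln: HaplotypeAlignment, indels_informative: bool = True
) -> DiversityStats:
    """Standard diversity statistics for one locus.

    Hd uses the n/(n-1) small-sample correction; pi and theta_W are
    reported per site over the full alignment length L (multiply by L for
    per-locus values). Tajima's D follows the e1/e2 normalisation and is
    NaN when S = 0.
    """
    if aln.n < 2:
        raise SampleSizeError("need at least 2 sequences")
    X = encode(aln, indels_informative)
    n, L = X.shape
    seg = segregating_sites(X)
    S = int(seg.sum())
    D = pairwise_differences(X)
    iu = np.triu_indices(n, 1)
    k_hat = float(D[iu].mean())
    groups = _haplotype_groups(X)
    Nh = len(groups)
    counts = np.array([len(g) for g in groups], dtype=float)
    p = counts / n
    Hd = float(n * (1.0 - np.sum(p**2)) / (n - 1))
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    return DiversityStats(
        n=n,
        L=L,
        L_complete=int((~(X < 0).any(axis=0)).sum()),
        S=S,
        Nh=Nh,
        Hd=Hd,
        pi=k_hat / L,
        theta_w=S / (a1 * L),
        tajima_d=tajimas_d(n, S, k_hat),
    )


def mfdm_test(
    aln: HaplotypeAlignment,
    ancestral: str,
    indels_informative: bool = True,
) -> float:
    """MFDM neutrality test p-value.

    With e the maximum derived-allele count over usable segregating sites,
    p = min(1, 2(n-e)/(n-1)); an unbalanced basal split (one derived
    mutation carried by nearly all sequences) gives a small p. Sites with
    an ambiguous or missing ancestral state are skipped. Returns NaN when
    no usable segregating site exists.
    """
    if len(ancestral) != aln.length:
        raise PolarizationError("ancestral sequence length mismatch")
    X = encode(aln, indels_informative)
    anc = np.array([_CODE.get(c, -1) for c in ancestral.upper()], dtype=np.int8)
    n, L = X.shape
    e_max = 0
    usable = False
    for j in np.flatnonzero(segregating_sites(X)):
        if anc[j] < 0:
            continue
        col = X[:, j]
        obs = col[col >= 0]
        if anc[j] not in obs:
            continue  # ancestral state absent: polarization unreliable
        derived = int(np.sum((obs != anc[j])))
        if derived == 0:
            continue
        usable = True
        e_max = max(e_max, derived)
    if not usable:
        return float("nan")
    return float(min(1.0, 2.0 * (n - e_max) / (n - 1)))


def min_recomb_events(
    aln_or_X, indels_informative: bool = True
) -> int:
    """Hudson-Kaplan minimum number of recombination events (Rm).

    Scans biallelic site pairs for all four gametes (using sequences
    complete at both sites) and reduces the incompatibility intervals to
    a maximal set of non-overlapping intervals; intervals may share
    endpoints, since a recombination event falls strictly between sites.
    """
    if isinstance(aln_or_X, HaplotypeAlignment):
        X = encode(aln_or_X, indels_informative)
    else:
        X = np.asarray(aln_or_X)
    n, L = X.shape
    # biallelic segregating columns only
    sites = []
    for j in range(L):
        col = X[:, j]
        obs = col[col >= 0]
        if obs.size and np.unique(obs).size == 2:
            sites.append(j)
    if len(sites) < 2:
        return 0
    intervals = []
    for a_idx in range(len(sites) - 1):
        for b_idx in range(a_idx + 1, len(sites)):
            ja, jb = sites[a_idx], sites[b_idx]
            ca, cb = X[:, ja], X[:, jb]
            ok = (ca >= 0) & (cb >= 0)
            gametes = {(int(x), int(y)) for x, y in zip(ca[ok], cb[ok])}
            if len(gametes) == 4:
                intervals.append((ja, jb))
    if not intervals:
        return 0
    # greedy maximum set of disjoint (endpoint-sharing allowed) intervals
    intervals.sort(key=lambda iv: iv[1])
    count = 0
    last_end = -1
    for left, right in intervals:
        if left >= last_end:
            count += 1
            last_end = right
    return count


@dataclass
class HaplotypeRecord:
    haplotype_id: str
    sequence: str
    count: int
    populations: frozenset
    private_to: str | None


def haplotype_table(
    aln: HaplotypeAlignment, indels_informative: bool = True
) -> list[HaplotypeRecord]:
    """Distinct haplotypes numbered by descending count then first
    occurrence, with private haplotypes (confined to one population)
    flagged."""
    X = encode(aln, indels_informative)
    groups = _haplotype_groups(X)
    labels = aln.population_labels()
    order = sorted(range(len(groups)), key=lambda g: (-len(groups[g]), groups[g][0]))
    out = []
    for rank, g in enumerate(order, start=1):
        members = groups[g]
        pops = frozenset(labels[i] for i in members)
        out.append(
            HaplotypeRecord(
                haplotype_id=f"H{rank}",
                sequence=aln.sequences[members[0]],
                count=len(members),
                populations=pops,
                private_to=next(iter(pops)) if len(pops) == 1 else None,
            )
        )
    return out
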