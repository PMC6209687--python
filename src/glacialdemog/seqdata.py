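"""Shared data model and file I/O for multilocus haplotype studies.

The pipeline works on phased, aligned haplotype sequences per locus
(FASTA) together with a sample->population map (TSV), a per-population
table of coordinates and ecological covariates (TSV), and groups loci
into a plastid and a nuclear partition.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTN-")
#: Characters excluded from pairwise-difference and segregating-site
#: counts (pairwise-complete treatment).
MISSING = "N"
GAP = "-"


class AlignmentError(ValueError):
    """Sequences of unequal length, or an empty alignment."""


class MappingError(KeyError):
    """A sequence label without a population assignment."""


class ContentError(ValueError):
    """A character outside the {A,C,G,T,N,-} alphabet."""


@dataclass
class HaplotypeAlignment:
    """Aligned phased sequences for one locus with population labels.

    Parameters
    ----------
    locus_name : str
        Locus identifier (e.g. ``"RPc"``).
    sequences : list of str
        Equal-length strings over ``{A,C,G,T,N,-}``, input order preserved.
    sample_ids : list of str
        One label per sequence; phased copies of a diploid individual are
        conventionally named ``<ind>_a`` / ``<ind>_b``.
    population_of : dict
        Maps every sequence label to a population id.
    ploidy_tag : str
        ``"nuclear-phased"`` or ``"plastid"``.
    """

    locus_name: str
    sequences: list[str]
    sample_ids: list[str]
    population_of: dict[str, str]
    ploidy_tag: str = "nuclear-phased"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.locus_name}: empty alignment")
        L = len(self.sequences[0])
        if L < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length sequences")
        for sid, s in zip(self.sample_ids, self.sequences):
            if len(s) != L:
                raise AlignmentError(
                    f"{self.locus_name}: sequence {sid} has length {len(s)} != {L}"
                )
            bad = set(s) - VALID_CHARS
            if bad:
                raise ContentError(
                    f"{self.locus_name}: sequence {sid} contains {sorted(bad)}"
                )
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        missing = [sid for sid in self.sample_ids if sid not in self.population_of]
        if missing:
            raise MappingError(
                f"{self.locus_name}: no population for labels {missing[:5]}"
            )

    @property
    def n(self) -> int:
        """Number of gene copies (phased sequences)."""
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def populations(self) -> list[str]:
        """Distinct population ids, in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            seen.setdefault(self.population_of[sid], None)
        return list(seen)

    def population_labels(self) -> list[str]:
        """Population id per sequence, in sequence order."""
        return [self.population_of[sid] for sid in self.sample_ids]

    def population_counts(self) -> Counter:
        return Counter(self.population_labels())

    def subset(self, keep: Iterable[str]) -> "HaplotypeAlignment":
        """Alignment restricted to the given sequence labels (order kept)."""
        keep = set(keep)
        idx = [i for i, sid in enumerate(self.sample_ids) if sid in keep]
        return HaplotypeAlignment(
            locus_name=self.locus_name,
            sequences=[self.sequences[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            population_of={
                sid: self.population_of[sid]
                for sid in (self.sample_ids[i] for i in idx)
            },
            ploidy_tag=self.ploidy_tag,
        )

    def subset_populations(self, pops: Iterable[str]) -> "HaplotypeAlignment":
        pops = set(pops)
        keep = [sid for sid in self.sample_ids if self.population_of[sid] in pops]
        return self.subset(keep)

    def to_matrix(self) -> np.ndarray:
        """(n, L) array of single-character strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


@dataclass
class PopulationTable:
    """Per-population coordinates, optional cluster labels and covariates."""

    table: pd.DataFrame  # index: population_id; columns incl. latitude, longitude

    REQUIRED = ("latitude", "longitude")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"population table lacks column {col!r}")
        lat = self.table["latitude"].to_numpy(float)
        lon = self.table["longitude"].to_numpy(float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinate out of range")

    @property
    def population_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def env_variables(self) -> list[str]:
        skip = {"latitude", "longitude", "group"}
        return [c for c in self.table.columns if c not in skip]

    @property
    def groups(self) -> pd.Series | None:
        return self.table["group"] if "group" in self.table.columns else None

    def env_matrix(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        variables = list(variables) if variables is not None else self.env_variables
        return self.table[variables].astype(float)


@dataclass
class StudyDataset:
    """A full multilocus study: alignments, locus groups, population table."""

    loci: list[HaplotypeAlignment]
    locus_groups: dict[str, list[str]]  # group name -> locus names
    populations: PopulationTable | None = None
    generation_time_years: float = 80.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be > 0")
        named = {a.locus_name for a in self.loci}
        grouped = [name for names in self.locus_groups.values() for name in names]
        if len(grouped) != len(set(grouped)):
            raise ValueError("a locus belongs to more than one group")
        if set(grouped) != named:
            raise ValueError("locus_groups do not cover the loci exactly")

    def locus(self, name: str) -> HaplotypeAlignment:
        for a in self.loci:
            if a.locus_name == name:
                return a
        raise KeyError(name)

    def group_alignments(self, group: str) -> list[HaplotypeAlignment]:
        return [self.locus(name) for name in self.locus_groups[group]]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a 3-column popmap TSV: sequence_label, individual_id, population_id.

    Returns (population_of, individual_of) keyed by sequence label.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["label", "individual", "population"],
        dtype=str, comment="#",
    )
    # repeated rows are fine (concatenated per-locus popmaps); conflicting
    # assignments for one label are not
    conflicts = df.drop_duplicates().loc[lambda d: d["label"].duplicated()]
    if len(conflicts):
        raise MappingError(
            f"conflicting popmap rows for label {conflicts['label'].iloc[0]!r}"
        )
    return (
        dict(zip(df["label"], df["population"])),
        dict(zip(df["label"], df["individual"])),
    )


def read_fasta(
    path: str | Path,
    popmap: str | Path | Mapping[str, str],
    locus_name: str | None = None,
    ploidy_tag: str = "nuclear-phased",
) -> HaplotypeAlignment:
    """Read an aligned FASTA and attach populations from a popmap.

    Raises :class:`AlignmentError` for unequal lengths, :class:`MappingError`
    for labels missing from the popmap, :class:`ContentError` for characters
    outside ``{A,C,G,T,N,-}`` ('N' is allowed and treated as missing).
    """
    if isinstance(popmap, (str, Path)):
        population_of, _ = read_popmap(popmap)
    else:
        population_of = dict(popmap)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    name = locus_name or Path(path).stem
    return HaplotypeAlignment(
        locus_name=name,
        sequences=[str(r.seq).upper() for r in records],
        sample_ids=[r.id for r in records],
        population_of=population_of,
        ploidy_tag=ploidy_tag,
    )


def write_fasta(aln: HaplotypeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def write_popmap(
    aln_or_map, path: str | Path, individual_of: Mapping[str, str] | None = None
) -> None:
    if isinstance(aln_or_map, HaplotypeAlignment):
        labels = aln_or_map.sample_ids
        pops = aln_or_map.population_of
    else:
        pops = dict(aln_or_map)
        labels = list(pops)
    with open(path, "w") as fh:
        for sid in labels:
            ind = individual_of[sid] if individual_of else sid.rsplit("_", 1)[0]
            fh.write(f"{sid}\t{ind}\t{pops[sid]}\n")


def read_population_table(path: str | Path) -> PopulationTable:
    """TSV with columns population, latitude, longitude[, group, <env vars...>]."""
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    if "population" not in df.columns:
        raise ValueError("population table needs a 'population' column")
    df = df.set_index("population")
    return PopulationTable(df)


def write_population_table(pt: PopulationTable, path: str | Path) -> None:
    pt.table.rename_axis("population").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Column operations
# ---------------------------------------------------------------------------

def drop_gap_columns(
    aln: HaplotypeAlignment, return_removed: bool = False
):
    """Remove every alignment column containing a gap character.

    Mirrors the treatment of indels in the ABC stage, where gapped columns
    are discarded before summary statistics are computed. Idempotent.
    """
    M = aln.to_matrix()
    gapped = (M == GAP).any(axis=0)
    if gapped.all():
        raise AlignmentError(f"{aln.locus_name}: all columns contain gaps")
    kept = M[:, ~gapped]
    out = HaplotypeAlignment(
        locus_name=aln.locus_name,
        sequences=["".join(row) for row in kept],
        sample_ids=list(aln.sample_ids),
        population_of=dict(aln.population_of),
        ploidy_tag=aln.ploidy_tag,
    )
    if return_removed:
        return out, np.flatnonzero(gapped).tolist()
    return out
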