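"""Sequence alignment I/O, haplotype collapsing and site classification.

The central container is :class:`Alignment`: a rectangular set of aligned,
uppercase IUPAC DNA sequences (gaps ``-``, missing ``N``) with a locus label
and an inheritance mode (``mitochondrial``, ``x_linked`` or ``autosomal``)
that downstream coalescent machinery uses for gene-copy scaling.

Haplotype identity and all site-based statistics use *complete deletion*:
any alignment column containing a gap or an ``N`` in any sequence is excluded
before sequences are compared.  This makes the haplotype count invariant to
indel placement and reproducible across tools.  Site indices in reports are
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN-")
INHERITANCE_MODES = ("mitochondrial", "x_linked", "autosomal")

# gene copies contributed per effective (census-style) size unit N
COPY_SCALING = {"mitochondrial": 0.5, "x_linked": 1.5, "autosomal": 2.0}


class InputError(ValueError):
    """Malformed user input (bad characters, missing records, bad tables)."""


class AlignmentError(ValueError):
    """Sequences that do not form a rectangular alignment."""


@dataclass
class Alignment:
    """An aligned set of DNA sequences for one locus.

    Parameters
    ----------
    locus_name
        Free-text locus label (e.g. ``"control_region"``).
    inheritance
        One of ``mitochondrial``, ``x_linked``, ``autosomal``; controls the
        gene-copy scaling used by the coalescent simulator.
    sequences
        Ordered ``(sample_id, sequence)`` pairs; sequences are uppercased on
        construction and must share a common length.
    """

    locus_name: str
    inheritance: str
    sequences: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise InputError(
                f"inheritance must be one of {INHERITANCE_MODES}, "
                f"got {self.inheritance!r}"
            )
        if not self.sequences:
            raise InputError("alignment has no sequences")
        normalized = []
        lengths = set()
        seen_ids: set[str] = set()
        for sid, seq in self.sequences:
            seq = seq.upper()
            bad = set(seq) - VALID_CHARS
            if bad:
                raise InputError(
                    f"record {sid!r} contains illegal characters: {sorted(bad)}"
                )
            if sid in seen_ids:
                raise InputError(f"duplicate sample id {sid!r}")
            seen_ids.add(sid)
            lengths.add(len(seq))
            normalized.append((sid, seq))
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths in {self.locus_name}: {sorted(lengths)}"
            )
        self.sequences = normalized
        self._matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.sequences]

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) uint8 matrix of ASCII codes."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(s for _, s in self.sequences).encode(), dtype=np.uint8
            ).reshape(self.n, self.length)
        return self._matrix

    def complete_sites(self) -> np.ndarray:
        """Boolean mask of columns free of gaps and N in every sequence."""
        m = self.matrix()
        return ~np.any((m == ord("-")) | (m == ord("N")), axis=0)

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        wanted = set(sample_ids)
        seqs = [(sid, s) for sid, s in self.sequences if sid in wanted]
        return Alignment(self.locus_name, self.inheritance, seqs)


@dataclass
class PopulationMap:
    """sample → population assignments plus population → region labels."""

    assignments: dict[str, str]
    regions: dict[str, str] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def population_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise InputError(f"sample {sample_id!r} has no population assignment")

    def check_alignment(self, aln: Alignment) -> None:
        missing = [sid for sid in aln.sample_ids if sid not in self.assignments]
        if missing:
            raise InputError(f"samples without population assignment: {missing[:5]}")


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-population frequency counts.

    Haplotype ids are ``Hap_1``, ``Hap_2``, ... in first-occurrence order of
    the input alignment, which makes ids deterministic.
    """

    haplotypes: list[str]           # full-length sequences (gaps retained)
    counts: pd.DataFrame            # haplotype_id × population, ints
    complete_mask: np.ndarray       # columns used for identity comparisons

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def ids(self) -> list[str]:
        return list(self.counts.index)

    def total_counts(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    def core_matrix(self) -> np.ndarray:
        """Haplotype sequences restricted to complete (comparison) sites."""
        m = np.frombuffer(
            "".join(self.haplotypes).encode(), dtype=np.uint8
        ).reshape(len(self.haplotypes), -1)
        return m[:, self.complete_mask]


@dataclass
class SiteClasses:
    """Per-column classification of an alignment under complete deletion."""

    n_variable: int
    n_gap_sites: int
    n_singleton_2var: int
    n_pi_2var: int
    n_pi_3var: int
    n_other_variable: int
    labels: list[str]   # one per column, 1-based positions implied by order

    def __post_init__(self) -> None:
        parts = (
            self.n_singleton_2var + self.n_pi_2var + self.n_pi_3var
            + self.n_other_variable
        )
        assert parts == self.n_variable, "variable-site classes do not partition"


def read_fasta(path: str | Path, locus_name: str, inheritance: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased; input order is preserved.  Raises
    :class:`AlignmentError` on unequal lengths and :class:`InputError` on an
    empty file or illegal characters.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(locus_name, inheritance, records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences:
            fh.write(f">{sid}\n{seq}\n")


def read_tables(
    popmap_path: str | Path, coords_path: str | Path
) -> tuple[PopulationMap, pd.DataFrame]:
    """Read the sample→population map and population coordinate table.

    The popmap TSV has columns ``sample_id``, ``population`` and optionally
    ``region``; the coordinate TSV has ``population``, ``latitude_deg``,
    ``longitude_deg`` in signed decimal degrees (west/south negative).
    Returns the :class:`PopulationMap` and a coordinate DataFrame indexed by
    population.
    """
    popmap = pd.read_csv(popmap_path, sep="\t", dtype=str)
    required = {"sample_id", "population"}
    if not required <= set(popmap.columns):
        raise InputError(f"popmap must have columns {sorted(required)}")
    if popmap["sample_id"].duplicated().any():
        dups = popmap.loc[popmap["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in popmap: {dups[:5]}")
    assignments = dict(zip(popmap["sample_id"], popmap["population"]))
    regions: dict[str, str] = {}
    if "region" in popmap.columns:
        for pop, reg in zip(popmap["population"], popmap["region"]):
            if isinstance(reg, str) and reg:
                regions[pop] = reg

    coords = pd.read_csv(coords_path, sep="\t")
    needed = {"population", "latitude_deg", "longitude_deg"}
    if not needed <= set(coords.columns):
        raise InputError(f"coords must have columns {sorted(needed)}")
    coords = coords.set_index("population")[["latitude_deg", "longitude_deg"]]
    coords = coords.astype(float)
    if (coords["latitude_deg"].abs() > 90).any():
        raise InputError("latitude outside [-90, 90]")
    if (coords["longitude_deg"].abs() > 180).any():
        raise InputError("longitude outside [-180, 180]")
    return PopulationMap(assignments, regions), coords


def collapse_haplotypes(aln: Alignment, popmap: PopulationMap) -> HaplotypeTable:
    """Collapse aligned sequences into distinct haplotypes.

    Identity is judged only at complete sites (no gap or N in *any*
    sequence); the representative sequence stored for each haplotype is the
    first-seen full-length sequence.  Counts are tabulated per population.
    """
    popmap.check_alignment(aln)
    mask = aln.complete_sites()
    core = aln.matrix()[:, mask]
    pops = popmap.populations
    pop_index = {p: i for i, p in enumerate(pops)}

    key_to_idx: dict[bytes, int] = {}
    haplotypes: list[str] = []
    counts = np.zeros((0, len(pops)), dtype=int)
    rows: list[np.ndarray] = []
    for i, (sid, seq) in enumerate(aln.sequences):
        key = core[i].tobytes()
        if key not in key_to_idx:
            key_to_idx[key] = len(haplotypes)
            haplotypes.append(seq)
            rows.append(np.zeros(len(pops), dtype=int))
        rows[key_to_idx[key]][pop_index[popmap.population_of(sid)]] += 1

    counts = pd.DataFrame(
        np.vstack(rows),
        index=[f"Hap_{i + 1}" for i in range(len(haplotypes))],
        columns=pops,
    )
    return HaplotypeTable(haplotypes=haplotypes, counts=counts, complete_mask=mask)


def classify_sites(aln: Alignment) -> SiteClasses:
    """Classify alignment columns: gap/N sites, then polymorphism classes.

    A column with any gap or N anywhere is a *gap site* and excluded from
    polymorphism classes.  Among complete columns: ``singleton_2var`` has two
    variants with the minor one in exactly one sequence;
    ``parsimony-informative`` columns have ≥2 variants each carried by ≥2
    sequences (split by variant count 2 vs 3); remaining variable columns
    (e.g. 3 variants with two singletons, or 4 variants) are counted once
    under ``other_variable``.
    """
    m = aln.matrix()
    labels: list[str] = []
    n_gap = n_singleton2 = n_pi2 = n_pi3 = n_other = 0
    for j in range(aln.length):
        col = m[:, j]
        if np.any((col == ord("-")) | (col == ord("N"))):
            n_gap += 1
            labels.append("gap")
            continue
        vals, cnts = np.unique(col, return_counts=True)
        if len(vals) == 1:
            labels.append("invariant")
            continue
        n_var_alleles = len(vals)
        n_ge2 = int(np.sum(cnts >= 2))
        if n_var_alleles == 2 and cnts.min() == 1:
            n_singleton2 += 1
            labels.append("singleton_2var")
        elif n_ge2 >= 2:
            if n_var_alleles == 2:
                n_pi2 += 1
                labels.append("pi_2var")
            elif n_var_alleles == 3:
                n_pi3 += 1
                labels.append("pi_3var")
            else:
                n_other += 1
                labels.append("other_variable")
        else:
            n_other += 1
            labels.append("other_variable")
    n_variable = n_singleton2 + n_pi2 + n_pi3 + n_other
    return SiteClasses(
        n_variable=n_variable,
        n_gap_sites=n_gap,
        n_singleton_2var=n_singleton2,
        n_pi_2var=n_pi2,
        n_pi_3var=n_pi3,
        n_other_variable=n_other,
        labels=labels,
    )


def write_haplotype_table(haps: HaplotypeTable, path: str | Path) -> None:
    """Write haplotype_id, sequence and one count column per population."""
    df = haps.counts.copy()
    df.insert(0, "sequence", haps.haplotypes)
    df.index.name = "haplotype_id"
    df.to_csv(path, sep="\t")


def expand_haplotypes(haps: HaplotypeTable) -> list[str]:
    """Repeat each haplotype sequence by its total count (round-trip check)."""
    out: list[str] = []
    for seq, cnt in zip(haps.haplotypes, haps.total_counts()):
        out.extend([seq] * int(cnt))
    return out
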