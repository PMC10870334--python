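"""Genotype data model and VCF / population-map I/O.

The central container is :class:`GenotypeMatrix`: diploid biallelic
genotypes coded as alternate-allele dosage (0, 1, 2) with ``MISSING = -1``
for uncalled cells, samples in rows and loci in columns.  Loci are
identified as ``"CHROM:POS"`` (1-based, VCF convention).  Genotypes are
treated as unphased; ``/`` and ``|`` separators are equivalent and
half-calls (e.g. ``0/.``) are conservatively mapped to missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be interpreted as biallelic SNP genotypes."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls for samples x loci.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (rows).
    locus_ids
        Ordered unique locus identifiers (columns), conventionally
        ``"CHROM:POS"``.
    calls
        ``int8`` array of shape ``(n_samples, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}`` counting copies of the alternate allele.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x loci array")
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes present: {np.unique(self.calls[bad])}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the loci selected by `index`."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.sample_ids,
            [self.locus_ids[i] for i in index],
            self.calls[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index],
            self.locus_ids,
            self.calls[index, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMap:
    """Assignment of sample ids to population/group labels.

    Group order is the first-seen order of the input; every group has at
    least one sample.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("population map is empty")
        self.assignments = dict(self.assignments)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def group_indices(self, sample_ids: list[str], groups: list[str] | None = None):
        """Map `sample_ids` to integer group codes.

        Returns ``(groups, codes)`` where ``codes[i]`` is the index into
        `groups` of sample i's group, or -1 for samples outside `groups`
        or absent from the map.
        """
        if groups is None:
            groups = self.groups
        lookup = {g: k for k, g in enumerate(groups)}
        codes = np.array(
            [lookup.get(self.assignments.get(s, ""), -1) for s in sample_ids],
            dtype=np.int64,
        )
        return groups, codes


def _dosage(a1: int, a2: int) -> int:
    if a1 < 0 or a2 < 0:
        return MISSING
    return a1 + a2


def read_vcf(path: str | os.PathLike, on_multiallelic: str = "skip") -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of alternate-allele dosages.

    Only the GT subfield is used.  Multiallelic or non-SNP records are
    skipped (``on_multiallelic="skip"``) or raise (``"error"``).  ``./.``
    and half-calls become :data:`MISSING`.  Locus ids are ``"CHROM:POS"``.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("skip", "error"):
        raise ValueError("on_multiallelic must be 'skip' or 'error'")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for line_no, v in enumerate(vcf, start=1):
        alts = v.ALT
        is_snp = len(v.REF) == 1 and len(alts) == 1 and len(alts[0]) == 1 and alts[0] in "ACGT"
        if not is_snp:
            if on_multiallelic == "error":
                raise VcfParseError(
                    f"record {line_no} ({v.CHROM}:{v.POS}) is not a biallelic SNP"
                )
            continue
        lid = f"{v.CHROM}:{v.POS}"
        if lid in seen:
            raise VcfParseError(f"duplicate position {lid} at record {line_no}")
        seen.add(lid)
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            # gt is [allele1, allele2, ..., phased]; -1 marks a missing allele
            col[i] = _dosage(gt[0], gt[1]) if len(gt) >= 3 else MISSING
        locus_ids.append(lid)
        columns.append(col)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, locus_ids, calls)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _split_locus_id(lid: str) -> tuple[str, int]:
    chrom, _, pos = lid.rpartition(":")
    if chrom and pos.isdigit():
        return chrom, int(pos)
    # ids not shaped like CHROM:POS get a synthetic position
    return lid, 1


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 (GT only) that round-trips through :func:`read_vcf`.

    Locus ids of the form ``CHROM:POS`` are emitted at that coordinate;
    REF/ALT are written as A/C placeholders (dosage, not nucleotide,
    carries the information here).
    """
    chroms: dict[str, None] = {}
    records = []
    for j, lid in enumerate(g.locus_ids):
        chrom, pos = _split_locus_id(lid)
        chroms.setdefault(chrom, None)
        records.append((chrom, pos, j))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for chrom, pos, j in records:
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a two-column (sample, group) delimited text file.

    Tab is the canonical delimiter; any run of whitespace is accepted.
    Duplicate samples and malformed lines raise ``ValueError``.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{line_no}: expected 'sample<TAB>group', got {line!r}")
            sample, group = parts
            if sample in assignments:
                raise ValueError(f"{path}:{line_no}: duplicate sample {sample!r}")
            assignments[sample] = group
    if not assignments:
        raise ValueError(f"{path}: empty population map")
    return PopulationMap(assignments)


def write_popmap(pops: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, group in pops.assignments.items():
            fh.write(f"{sample}\t{group}\n")
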