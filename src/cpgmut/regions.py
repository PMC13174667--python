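"""Genomic sequence, interval and variant I/O.

All coordinates are 0-based half-open internally.  VCF positions (1-based)
are converted on read; BED is consumed natively.  Only uppercase A/C/G/T are
considered analyzable sequence: N and lowercase bases are treated as masked,
so soft-masked inputs are handled conservatively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "RegionSet",
    "VariantRecord",
    "MethylationObservation",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_vcf_snvs",
]

ANALYZABLE = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig with bases preserved verbatim (case and N)."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise ValueError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """Base at 0-based ``pos``; raises IndexError out of bounds."""
        if not 0 <= pos < len(self.bases):
            raise IndexError(f"position {pos} out of bounds for {self.name} (len {len(self.bases)})")
        return self.bases[pos]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with allele counts; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0 <= self.ac <= self.an:
            raise ValueError(f"AC={self.ac} outside [0, AN={self.an}] at {self.chrom}:{self.pos}")

    @property
    def minor_allele_count(self) -> int:
        return min(self.ac, self.an - self.ac)

    @property
    def is_singleton(self) -> bool:
        """Minor-allele count equals 1 (covers AC=1 and AC=AN-1)."""
        return self.minor_allele_count == 1


@dataclass(frozen=True)
class MethylationObservation:
    """Read counts for one cytosine in one sample; ``pos`` is 0-based."""

    chrom: str
    pos: int
    strand: str
    meth_reads: int
    total_reads: int
    sample: str

    def __post_init__(self) -> None:
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"methylated reads {self.meth_reads} outside [0, {self.total_reads}] "
                f"at {self.chrom}:{self.pos}"
            )


class RegionSet:
    """A set of genomic intervals, normalized per chromosome.

    Intervals are 0-based half-open, stored sorted and non-overlapping
    (overlapping or book-ended input intervals are merged).  Supports the
    set algebra used to define the analyzable genome: union on
    construction, :meth:`subtract`, :meth:`intersect`, membership and
    total length.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._ivals: dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            self._ivals[chrom] = _merge(np.array(sorted(ivs), dtype=np.int64))

    # -- queries ---------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self._ivals)

    def intervals(self, chrom: str | None = None) -> list[tuple[str, int, int]]:
        chroms = [chrom] if chrom is not None else self.chroms
        out = []
        for c in chroms:
            for s, e in self._ivals.get(c, np.empty((0, 2), dtype=np.int64)):
                out.append((c, int(s), int(e)))
        return out

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._ivals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals() == other.intervals()

    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._ivals.values()))

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self._ivals.get(chrom)
        if arr is None or arr.shape[0] == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of positions on one chromosome."""
        arr = self._ivals.get(chrom)
        if arr is None or arr.shape[0] == 0:
            return np.zeros(len(positions), dtype=bool)
        i = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = i >= 0
        ok[ok] &= positions[ok] < arr[i[ok], 1]
        return ok

    # -- algebra ---------------------------------------------------------
    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Positions in ``self`` and not in ``other``."""
        out = RegionSet()
        for chrom, arr in self._ivals.items():
            out._ivals[chrom] = _subtract_arrays(arr, other._ivals.get(chrom))
        out._drop_empty()
        return out

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Positions in both ``self`` and ``other``."""
        out = RegionSet()
        for chrom, arr in self._ivals.items():
            oth = other._ivals.get(chrom)
            if oth is None:
                continue
            out._ivals[chrom] = _intersect_arrays(arr, oth)
        out._drop_empty()
        return out

    def _drop_empty(self) -> None:
        self._ivals = {c: a for c, a in self._ivals.items() if a.shape[0]}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RegionSet({self.intervals()!r})"


def _merge(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] <= 1:
        return arr
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _subtract_arrays(a: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    if b is None or b.shape[0] == 0:
        return a.copy()
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < b.shape[0] and b[j, 1] <= cur:
            j += 1
        k = j
        while k < b.shape[0] and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < a.shape[0] and j < b.shape[0]:
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def subtract_regions(universe: RegionSet, excluded: RegionSet) -> RegionSet:
    return universe.subtract(excluded)


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.intersect(b)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, GenomeSequence]:
    """Read a (possibly multi-record) FASTA into GenomeSequence objects.

    Bases are preserved verbatim, including case and N.  An empty file
    yields an empty mapping.
    """
    out: dict[str, GenomeSequence] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    return out


def write_fasta(seqs: Mapping[str, GenomeSequence] | Iterable[GenomeSequence], path: str | os.PathLike) -> None:
    records = seqs.values() if isinstance(seqs, Mapping) else seqs
    SeqIO.write(
        [SeqRecord(Seq(g.bases), id=g.name, description="") for g in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> RegionSet:
    """Read a 3+ column BED (0-based half-open) into a normalized RegionSet."""
    ivals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {ln}: expected >=3 BED columns, got {len(fields)}")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path} line {ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path} line {ln}: start {start} >= end {end}")
            ivals.append((chrom, start, end))
    return RegionSet(ivals)


def write_bed(regions: RegionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_snvs(
    path: str | os.PathLike,
    require_biallelic: bool = True,
    mappability: RegionSet | None = None,
    singleton_policy: str = "keep",
) -> list[VariantRecord]:
    """Read biallelic SNVs with allele counts from a VCF.

    AC/AN are taken from INFO when present, otherwise derived from sample
    genotypes.  ``singleton_policy`` is one of ``keep``, ``drop`` and
    ``drop-unless-in-regionset`` (the last retains singletons only inside
    the ``mappability`` RegionSet, emulating a uniquely-mappable-read
    filter for rare variants).
    """
    if singleton_policy not in {"keep", "drop", "drop-unless-in-regionset"}:
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    if singleton_policy == "drop-unless-in-regionset" and mappability is None:
        raise ValueError("singleton_policy 'drop-unless-in-regionset' requires a mappability RegionSet")

    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if require_biallelic and len(alts) != 1:
                continue
            if len(alts) != 1:
                continue  # multiallelic handling out of contract
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in ANALYZABLE or alt not in ANALYZABLE:
                continue
            ac, an = _allele_counts(rec)
            v = VariantRecord(rec.chrom, rec.pos - 1, ref, alt, ac, an)
            if v.is_singleton:
                if singleton_policy == "drop":
                    continue
                if singleton_policy == "drop-unless-in-regionset" and not mappability.contains(v.chrom, v.pos):
                    continue
            out.append(v)
    return out


def _allele_counts(rec) -> tuple[int, int]:
    info = rec.info
    if "AC" in info and "AN" in info:
        ac = info["AC"]
        if isinstance(ac, tuple):
            ac = ac[0]
        return int(ac), int(info["AN"])
    # fall back to genotypes
    ac = an = 0
    found = False
    for sample in rec.samples.values():
        gt = sample.get("GT")
        if gt is None:
            continue
        for allele in gt:
            if allele is None:
                continue
            found = True
            an += 1
            if allele >= 1:
                ac += 1
    if not found:
        raise ValueError(f"{rec.chrom}:{rec.pos}: no AC/AN in INFO and no genotypes to derive them")
    return ac, an
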