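"""Assemble the model-ready CpG site table.

Joins strand-resolved CpG records with pooled methylation levels and
MAF-polarized variants into one row per cytosine carrying the methylation
fraction ``m`` and the binary polymorphism indicator ``y`` (1 iff a
polarized C>T event hits the focal cytosine on its strand — a forward-strand
G>A is a reverse-strand C>T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contexts import StrandCytosine
from .regions import MethylationObservation, RegionSet, VariantRecord

__all__ = [
    "PolarizedVariant",
    "pool_methylation",
    "pool_methylation_table",
    "polarize_maf",
    "assemble_site_table",
    "exclude_sites",
    "read_methylation_tsv",
    "read_site_table",
    "SITE_TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

SITE_TABLE_COLUMNS = ["chrom", "cpg_start", "strand", "context4", "context6", "m", "y"]

DEFAULT_MIN_COVERAGE = 5


def read_site_table(path) -> pd.DataFrame:
    """Read a site-table TSV ('.' marks a missing context)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "strand": str, "context4": str, "context6": str}
    )
    for col in ("context4", "context6"):
        if col in df.columns:
            df[col] = df[col].replace(".", pd.NA)
    return df


@dataclass(frozen=True)
class PolarizedVariant:
    """A variant with ancestral/derived states assigned by allele frequency."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int
    an: int
    ancestral: str
    derived: str

    @property
    def substitution(self) -> str:
        """Forward-strand substitution type, e.g. 'C>T'."""
        return f"{self.ancestral}>{self.derived}"


def polarize_maf(v: VariantRecord) -> PolarizedVariant | None:
    """Polarize by minor allele frequency: major allele is ancestral.

    Returns None for an exact tie (AC = AN/2), where the ancestral state
    cannot be called; such sites are excluded entirely downstream.
    """
    if v.an == 0:
        raise ValueError(f"AN=0 at {v.chrom}:{v.pos}")
    alt_count, ref_count = v.ac, v.an - v.ac
    if alt_count == ref_count:
        return None
    if alt_count < ref_count:
        anc, der = v.ref, v.alt
    else:
        anc, der = v.alt, v.ref
    return PolarizedVariant(v.chrom, v.pos, v.ref, v.alt, v.ac, v.an, anc, der)


def pool_methylation(
    observations: Sequence[MethylationObservation],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> float | None:
    """Pooled methylation fraction: sum(meth) / sum(total) across samples.

    Pooling read counts across samples dampens the bias that a C/T SNP
    introduces into per-individual bisulfite calls.  Returns None when the
    pooled coverage is below ``min_coverage``.
    """
    if not observations:
        raise ValueError("no observations to pool")
    total = sum(o.total_reads for o in observations)
    meth = sum(o.meth_reads for o in observations)
    if total < min_coverage:
        return None
    return meth / total


def read_methylation_tsv(path) -> pd.DataFrame:
    """Read a methylation table: chrom, pos, strand, meth_reads, total_reads, sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "sample": str})
    required = {"chrom", "pos", "strand", "meth_reads", "total_reads", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing methylation columns {sorted(missing)}")
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValueError(f"{path}: methylated read count exceeds total")
    return df


def pool_methylation_table(
    meth: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    strand_resolved: bool = False,
) -> dict:
    """Pool read counts per site across samples.

    Returns a mapping keyed by (chrom, pos) — or (chrom, pos, strand) when
    ``strand_resolved`` — to the pooled fraction; sites below the coverage
    threshold are omitted.
    """
    keys = ["chrom", "pos", "strand"] if strand_resolved else ["chrom", "pos"]
    grouped = meth.groupby(keys, sort=False)[["meth_reads", "total_reads"]].sum()
    grouped = grouped[grouped["total_reads"] >= min_coverage]
    frac = grouped["meth_reads"] / grouped["total_reads"]
    return frac.to_dict()


def assemble_site_table(
    cytosines: Iterable[StrandCytosine],
    methylation: Mapping,
    variants: Iterable[PolarizedVariant],
    model_k: int = 4,
    strand_resolved_methylation: bool = False,
    drop_nonancestral_cpg: bool = False,
    unpolarizable_positions: set[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build the model-ready site table and a drop-count summary.

    ``methylation`` maps (chrom, pos) — or (chrom, pos, strand) when
    strand-resolved — to a pooled fraction in [0, 1].  With CpG-level
    methylation (the default, matching per-CpG WGBS reporting) the one
    value keyed by the forward-C position applies to both strand records.

    y = 1 iff a polarized variant with substitution C>T sits at the focal
    cytosine's forward-strand position for a '+' record, or G>A for a '-'
    record.  Other substitutions at the focal position leave y = 0; with
    ``drop_nonancestral_cpg`` sites whose ancestral allele is not the
    expected C/G are removed instead (the ancestral state is then not a
    CpG).  Records whose focal position carries an unpolarizable variant
    (exact frequency tie) are excluded entirely — the polymorphism state
    can be neither trusted as 0 nor 1.  Variants at positions never
    extracted as CpG cytosines are ignored with a counted warning.
    """
    ties = unpolarizable_positions or set()
    by_pos: dict[tuple[str, int], PolarizedVariant] = {}
    for v in variants:
        by_pos[(v.chrom, v.pos)] = v

    focal_positions = set()
    rows = []
    counts = {
        "input": 0,
        "kept": 0,
        "missing_context": 0,
        "missing_m": 0,
        "tie_dropped": 0,
        "nonancestral_dropped": 0,
        "variants_ignored_not_cpg": 0,
    }
    expected_sub = {"+": "C>T", "-": "G>A"}
    expected_anc = {"+": "C", "-": "G"}

    for site in cytosines:
        counts["input"] += 1
        if site.context(model_k) is None:
            counts["missing_context"] += 1
            continue
        if strand_resolved_methylation:
            m = methylation.get((site.chrom, site.focal_pos, site.strand))
        else:
            m = methylation.get((site.chrom, site.cpg_start))
        if m is None:
            counts["missing_m"] += 1
            continue
        if (site.chrom, site.focal_pos) in ties:
            counts["tie_dropped"] += 1
            continue
        focal_positions.add((site.chrom, site.focal_pos))
        v = by_pos.get((site.chrom, site.focal_pos))
        y = 0
        if v is not None:
            if v.substitution == expected_sub[site.strand]:
                y = 1
            elif drop_nonancestral_cpg and v.ancestral != expected_anc[site.strand]:
                counts["nonancestral_dropped"] += 1
                continue
        rows.append(
            (site.chrom, site.cpg_start, site.strand, site.context4, site.context6, float(m), y)
        )
        counts["kept"] += 1

    for key in by_pos:
        if key not in focal_positions:
            counts["variants_ignored_not_cpg"] += 1
    if counts["variants_ignored_not_cpg"]:
        logger.warning(
            "%d variant(s) at positions not extracted as CpG cytosines were ignored",
            counts["variants_ignored_not_cpg"],
        )

    table = pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)
    return table, counts


def exclude_sites(
    table: pd.DataFrame,
    exclusion: RegionSet | Iterable[tuple[str, int]],
) -> tuple[pd.DataFrame, int]:
    """Remove sites hit by an exclusion list (e.g. non-zero 5hmC calls).

    ``exclusion`` is either a RegionSet tested against ``cpg_start`` or an
    iterable of (chrom, cpg_start) keys.  Returns the filtered table and
    the number of removed rows.
    """
    if isinstance(exclusion, RegionSet):
        drop = table.apply(lambda r: exclusion.contains(r["chrom"], int(r["cpg_start"])), axis=1)
    else:
        keys = set(exclusion)
        drop = table.apply(lambda r: (r["chrom"], int(r["cpg_start"])) in keys, axis=1)
    if len(table) == 0:
        return table.copy(), 0
    kept = table.loc[~drop].reset_index(drop=True)
    return kept, int(drop.sum())
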