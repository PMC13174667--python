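"""End-to-end stage functions tying I/O, extraction and assembly together.

These are the computations behind the CLI subcommands and the analysis
drivers: genome -> strand-resolved CpG records -> annotated site table.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .contexts import StrandCytosine, find_cpg_sites
from .regions import RegionSet, read_bed, read_fasta, read_vcf_snvs
from .sites import (
    DEFAULT_MIN_COVERAGE,
    assemble_site_table,
    polarize_maf,
    pool_methylation_table,
    read_methylation_tsv,
)

__all__ = ["extract_sites", "annotate_sites"]


def extract_sites(
    fasta_path,
    include_bed=None,
    exclude_bed=None,
    k_list: tuple[int, ...] = (4, 6),
) -> list[StrandCytosine]:
    """Scan a genome for analyzable CpGs within include-minus-exclude regions.

    Without an include BED the whole of every sequence is eligible (masked
    bases are still skipped).
    """
    genome = read_fasta(fasta_path)
    include = read_bed(include_bed) if include_bed else RegionSet(
        (name, 0, len(seq)) for name, seq in genome.items()
    )
    if exclude_bed:
        include = include.subtract(read_bed(exclude_bed))
    records: list[StrandCytosine] = []
    for name in sorted(genome):
        records.extend(find_cpg_sites(genome[name], include, k_list))
    return records


def annotate_sites(
    cytosines: Iterable[StrandCytosine],
    vcf_path,
    methylation_path,
    model_k: int = 4,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    singleton_policy: str = "keep",
    mappability: RegionSet | None = None,
    strand_resolved_methylation: bool = False,
    drop_nonancestral_cpg: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join CpG records with pooled methylation and MAF-polarized variants."""
    variants = read_vcf_snvs(
        vcf_path,
        require_biallelic=True,
        mappability=mappability,
        singleton_policy=singleton_policy,
    )
    polarized = []
    ties = set()
    for v in variants:
        pv = polarize_maf(v)
        if pv is None:
            ties.add((v.chrom, v.pos))
        else:
            polarized.append(pv)
    meth = pool_methylation_table(
        read_methylation_tsv(methylation_path),
        min_coverage=min_coverage,
        strand_resolved=strand_resolved_methylation,
    )
    return assemble_site_table(
        cytosines,
        meth,
        polarized,
        model_k=model_k,
        strand_resolved_methylation=strand_resolved_methylation,
        drop_nonancestral_cpg=drop_nonancestral_cpg,
        unpolarizable_positions=ties,
    )
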