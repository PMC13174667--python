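"""Synthetic data: model-level site tables and byte-level pipeline fixtures.

Two generators live here.

``simulate_site_table`` draws directly from the generative model the
regression inverts: per-context scaled rates alphaT (unmethylated baseline)
and betaT (full-methylation increment), methylation levels from a bimodal
Beta mixture on [0, 1] mimicking the sperm methylome (most CpGs nearly
fully methylated, a minority hypomethylated), and polymorphism indicators
y ~ Bernoulli(1 - exp(-(alphaT + betaT * m))).  Defaults put p roughly in
0.01-0.4, the regime where the recurrent-mutation correction matters.

``generate_fixture_bundle`` writes a small mutually consistent FASTA + BED
+ VCF + methylation TSV, together with the expected annotated site table
produced by an independent straightforward enumeration (the oracle used by
end-to-end tests), not by the pipeline under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import enumerate_contexts, reverse_complement, pair_reverse_complements

__all__ = [
    "MethylationMixture",
    "SyntheticTruth",
    "default_truth",
    "simulate_site_table",
    "additive_flank_truth",
    "generate_fixture_bundle",
    "write_site_table",
]


@dataclass(frozen=True)
class MethylationMixture:
    """Two-component Beta mixture on [0, 1].

    ``w_high`` is the weight of the high-methylation mode.  Defaults mimic
    the bimodal sperm methylation landscape: a sharp near-zero mode and a
    dominant near-one mode.
    """

    w_high: float = 0.55
    a_low: float = 0.6
    b_low: float = 8.0
    a_high: float = 8.0
    b_high: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_high <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        for v in (self.a_low, self.b_low, self.a_high, self.b_high):
            if v <= 0:
                raise ValueError("Beta shape parameters must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        hi = rng.random(n) < self.w_high
        m = np.empty(n)
        m[hi] = rng.beta(self.a_high, self.b_high, int(hi.sum()))
        m[~hi] = rng.beta(self.a_low, self.b_low, int((~hi).sum()))
        return m


@dataclass(frozen=True)
class SyntheticTruth:
    """Known per-context truth for parameter-recovery simulations.

    ``m_kind`` is ``"mixture"`` (Beta mixture) or ``"binary"`` (m in {0,1}
    with P(m=1) = mixture weight), the latter enabling exact stratum
    closed forms.  The single seed fully determines the output.
    """

    k: int
    alphaT: dict[str, float]
    betaT: dict[str, float]
    mixture: MethylationMixture
    n_per_context: int
    seed: int
    m_kind: str = "mixture"

    def __post_init__(self) -> None:
        if self.k not in (4, 6):
            raise ValueError("k must be 4 or 6")
        if self.m_kind not in ("mixture", "binary"):
            raise ValueError("m_kind must be 'mixture' or 'binary'")
        for c in self.alphaT:
            a, b = self.alphaT[c], self.betaT[c]
            if a < 0 or a + b < 0:
                raise ValueError(f"context {c}: need alphaT >= 0 and alphaT + betaT >= 0")

    def muT(self, context: str, x: float) -> float:
        return self.alphaT[context] + self.betaT[context] * x


def default_truth(
    seed: int,
    k: int = 4,
    n_per_context: int = 20_000,
    alpha_range: tuple[float, float] = (0.01, 0.05),
    beta_range: tuple[float, float] = (0.2, 0.6),
    mixture: MethylationMixture | None = None,
    symmetric: bool = False,
    beta_zero: bool = False,
    m_kind: str = "mixture",
) -> SyntheticTruth:
    """Draw per-context truth from the default study conditions.

    ``symmetric`` forces equal rates within every reverse-complement
    context pair (the strand-symmetric null for asymmetry calibration);
    ``beta_zero`` removes any methylation effect.
    """
    rng = np.random.default_rng(seed)
    contexts = enumerate_contexts(k)
    alpha = {c: float(rng.uniform(*alpha_range)) for c in contexts}
    beta = {c: 0.0 if beta_zero else float(rng.uniform(*beta_range)) for c in contexts}
    if symmetric:
        pairs, _ = pair_reverse_complements(contexts)
        for a, b in pairs:
            alpha[b] = alpha[a]
            beta[b] = beta[a]
    return SyntheticTruth(
        k=k,
        alphaT=alpha,
        betaT=beta,
        mixture=mixture or MethylationMixture(),
        n_per_context=n_per_context,
        seed=seed,
        m_kind=m_kind,
    )


def additive_flank_truth(
    seed: int,
    n_per_context: int = 20_000,
    interaction: float = 0.0,
    mixture: MethylationMixture | None = None,
) -> SyntheticTruth:
    """4-mer truth whose flanks act independently (optionally perturbed).

    alphaT(c) and betaT(c) are sums of an overall level plus separate
    upstream- and downstream-base effects, i.e. exactly the generative
    model behind the additive single-flank regression.  A nonzero
    ``interaction`` adds a rate bump to the A_CG_A context only, breaking
    additivity to a controlled degree.
    """
    # flank effect ranges chosen so alphaT spans ~[0.01, 0.05] and betaT
    # ~[0.2, 0.6], the same regime as the default per-context truth
    rng = np.random.default_rng(seed)
    ups = {b: float(rng.uniform(-0.01, 0.01)) for b in "ACGT"}
    downs = {b: float(rng.uniform(-0.01, 0.01)) for b in "ACGT"}
    ups_b = {b: float(rng.uniform(-0.1, 0.1)) for b in "ACGT"}
    downs_b = {b: float(rng.uniform(-0.1, 0.1)) for b in "ACGT"}
    alpha, beta = {}, {}
    for c in enumerate_contexts(4):
        u, d = c[0], c[3]
        alpha[c] = 0.03 + ups[u] + downs[d]
        beta[c] = 0.4 + ups_b[u] + downs_b[d]
        if c == "ACGA":
            alpha[c] += interaction
            beta[c] += interaction * 10
    return SyntheticTruth(
        k=4,
        alphaT=alpha,
        betaT=beta,
        mixture=mixture or MethylationMixture(),
        n_per_context=n_per_context,
        seed=seed,
    )


def simulate_site_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Draw a model-ready site table from known truth.

    Rows carry synthetic coordinates; for k=6 the 4-mer context is the
    central four bases of the 6-mer, so nested models can be fitted on the
    same table.
    """
    rng = np.random.default_rng(truth.seed)
    contexts = sorted(truth.alphaT)
    frames = []
    pos0 = 0
    for c in contexts:
        n = truth.n_per_context
        if truth.m_kind == "binary":
            m = (rng.random(n) < truth.mixture.w_high).astype(float)
        else:
            m = truth.mixture.draw(rng, n)
        mu = truth.alphaT[c] + truth.betaT[c] * m
        p = -np.expm1(-mu)
        y = (rng.random(n) < p).astype(np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "sim",
                    "cpg_start": np.arange(pos0, pos0 + n) * 2,
                    "strand": "+",
                    "context4": c if truth.k == 4 else c[1:5],
                    "context6": c if truth.k == 6 else pd.NA,
                    "m": m,
                    "y": y,
                }
            )
        )
        pos0 += n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Byte-level fixture bundle
# ---------------------------------------------------------------------------

_ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _oracle_revcomp(s: str) -> str:
    return "".join(_ORACLE_COMPLEMENT[b] for b in reversed(s))


def _random_genome(rng: np.random.Generator, length: int) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    # seed extra CG dimers so small genomes carry a useful number of CpGs
    for pos in rng.choice(length - 1, size=max(2, length // 12), replace=False):
        bases[pos], bases[pos + 1] = "C", "G"
    # mask a few positions: N and lowercase both count as unanalyzable
    for pos in rng.choice(length, size=max(1, length // 40), replace=False):
        bases[pos] = "N"
    for pos in rng.choice(length, size=max(1, length // 40), replace=False):
        if bases[pos] != "N":
            bases[pos] = bases[pos].lower()
    return "".join(bases)


def generate_fixture_bundle(
    outdir,
    seed: int,
    genome_length: int = 400,
    n_variants: int = 12,
    min_coverage: int = 5,
) -> dict[str, Path]:
    """Write a consistent FASTA/BED/VCF/methylation fixture plus oracle table.

    Two chromosomes of ``genome_length`` bases each; an include BED
    covering both, an exclude BED removing one internal window per
    chromosome; every VCF record sits on a fixture CpG cytosine with
    AC < AN/2 so MAF polarization keeps the reference ancestral; a
    methylation TSV with two samples per CpG (a few CpGs deliberately
    under-covered).  ``expected_sites.tsv`` is produced by a direct
    character-scan enumeration independent of the pipeline modules.
    """
    if genome_length < 50:
        raise ValueError("genome_length must be >= 50")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = ["chrA", "chrB"]
    genomes = {c: _random_genome(rng, genome_length) for c in chroms}
    exclude = {
        c: (genome_length // 3, genome_length // 3 + genome_length // 10) for c in chroms
    }

    # --- oracle enumeration: per-base analyzable mask, then CG scan -------
    cpgs: dict[str, list[int]] = {}
    for c, seq in genomes.items():
        ex_lo, ex_hi = exclude[c]
        mask = [
            (b in "ACGT") and not (ex_lo <= i < ex_hi) for i, b in enumerate(seq)
        ]
        cpgs[c] = [
            i
            for i in range(len(seq) - 1)
            if seq[i : i + 2] == "CG" and mask[i] and mask[i + 1]
        ]

    # --- methylation: two samples per CpG, CpG-level (forward C position) -
    meth_rows = []
    pooled_m: dict[tuple[str, int], float] = {}
    for c in chroms:
        for i in cpgs[c]:
            undercovered = rng.random() < 0.1
            m_true = float(rng.beta(8.0, 0.6)) if rng.random() < 0.55 else float(rng.beta(0.6, 8.0))
            tot_meth = tot_reads = 0
            for s in ("s1", "s2"):
                total = int(rng.integers(1, 3)) if undercovered else int(rng.integers(5, 30))
                meth = int(rng.binomial(total, m_true))
                meth_rows.append((c, i, "+", meth, total, s))
                tot_meth += meth
                tot_reads += total
            if tot_reads >= min_coverage:
                pooled_m[(c, i)] = tot_meth / tot_reads

    # --- variants: C>T on '+' cytosines, G>A on '-' cytosines -------------
    candidates = [(c, i, "+") for c in chroms for i in cpgs[c]] + [
        (c, i, "-") for c in chroms for i in cpgs[c]
    ]
    rng.shuffle(candidates)
    an = 1000
    variant_rows = []  # (chrom, pos0, ref, alt, ac)
    used_positions = set()
    for c, i, strand in candidates:
        if len(variant_rows) >= n_variants:
            break
        pos = i if strand == "+" else i + 1
        if (c, pos) in used_positions:
            continue
        used_positions.add((c, pos))
        ref, alt = ("C", "T") if strand == "+" else ("G", "A")
        ac = int(rng.integers(1, an // 2))
        variant_rows.append((c, pos, ref, alt, ac))
    variant_rows.sort()

    # --- expected annotated site table (oracle, independent enumeration) --
    variant_at = {(c, pos): (ref, alt) for c, pos, ref, alt, _ in variant_rows}
    expected = []
    for c in chroms:
        seq = genomes[c]
        for i in cpgs[c]:
            ctx4 = seq[i - 1 : i + 3] if i >= 1 else ""
            ctx6 = seq[i - 2 : i + 4] if i >= 2 else ""
            ctx4 = ctx4 if len(ctx4) == 4 and all(b in "ACGT" for b in ctx4) else None
            ctx6 = ctx6 if len(ctx6) == 6 and all(b in "ACGT" for b in ctx6) else None
            if ctx4 is None:  # model_k = 4 downstream: context required
                continue
            m = pooled_m.get((c, i))
            if m is None:
                continue
            for strand in ("+", "-"):
                focal = i if strand == "+" else i + 1
                want = ("C", "T") if strand == "+" else ("G", "A")
                y = 1 if variant_at.get((c, focal)) == want else 0
                expected.append(
                    (
                        c,
                        i,
                        strand,
                        ctx4 if strand == "+" else _oracle_revcomp(ctx4),
                        (ctx6 if strand == "+" else _oracle_revcomp(ctx6)) if ctx6 else ".",
                        m,
                        y,
                    )
                )
    expected_df = pd.DataFrame(
        expected, columns=["chrom", "cpg_start", "strand", "context4", "context6", "m", "y"]
    ).sort_values(["chrom", "cpg_start", "strand"], ignore_index=True)

    # --- write files -------------------------------------------------------
    paths = {
        "fasta": outdir / "genome.fa",
        "include_bed": outdir / "include.bed",
        "exclude_bed": outdir / "exclude.bed",
        "vcf": outdir / "variants.vcf",
        "methylation": outdir / "methylation.tsv",
        "expected_sites": outdir / "expected_sites.tsv",
        "truth": outdir / "fixture_truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = genomes[c]
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    with open(paths["include_bed"], "w") as fh:
        for c in chroms:
            fh.write(f"{c}\t0\t{genome_length}\n")
    with open(paths["exclude_bed"], "w") as fh:
        for c in chroms:
            lo, hi = exclude[c]
            fh.write(f"{c}\t{lo}\t{hi}\n")
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total alleles">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={genome_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c, pos, ref, alt, ac in variant_rows:
            fh.write(f"{c}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAC={ac};AN={an}\n")
    pd.DataFrame(
        meth_rows, columns=["chrom", "pos", "strand", "meth_reads", "total_reads", "sample"]
    ).to_csv(paths["methylation"], sep="\t", index=False)
    write_site_table(expected_df, paths["expected_sites"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": seed,
                "genome_length": genome_length,
                "n_variants_requested": n_variants,
                "n_variants_written": len(variant_rows),
                "n_cpgs": {c: len(v) for c, v in cpgs.items()},
                "exclude_windows": exclude,
                "an": an,
                "min_coverage": min_coverage,
            },
            fh,
            indent=1,
        )
    return paths


def write_site_table(df: pd.DataFrame, path) -> None:
    """Canonical TSV form of a site table ('.' for missing contexts)."""
    out = df.copy()
    for col in ("context4", "context6"):
        out[col] = out[col].fillna(".").replace({None: "."})
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
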