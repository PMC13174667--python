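"""CpG dinucleotide extraction and k-mer context algebra.

Every CG dimer on the forward strand harbours two cytosines: the forward-
strand C and the cytosine paired with the forward-strand G.  Each is emitted
as its own strand-resolved record, with the k-mer context read on that
cytosine's strand, so the minus-strand context is the reverse complement of
the plus-strand window.  Both records share ``cpg_start`` (0-based position
of the forward-strand C), keeping the two halves of one dinucleotide
joinable for asymmetry analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .regions import ANALYZABLE, GenomeSequence, RegionSet

__all__ = [
    "StrandCytosine",
    "reverse_complement",
    "enumerate_contexts",
    "pair_reverse_complements",
    "find_cpg_sites",
    "is_valid_context",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement of an uppercase ACGT string."""
    if not set(s) <= ANALYZABLE:
        bad = sorted(set(s) - ANALYZABLE)
        raise ValueError(f"invalid characters {bad} in {s!r}")
    return s.translate(_COMPLEMENT)[::-1]


def is_valid_context(kmer: str, k: int | None = None) -> bool:
    """True iff ``kmer`` is ACGT-only with a central CG dinucleotide."""
    if k is not None and len(kmer) != k:
        return False
    n = len(kmer)
    if n < 2 or n % 2:
        return False
    half = n // 2
    return set(kmer) <= ANALYZABLE and kmer[half - 1 : half + 1] == "CG"


def enumerate_contexts(k: int) -> list[str]:
    """All 4^(k-2) k-mers with central CG, in lexicographic order."""
    if k not in (4, 6):
        raise ValueError(f"unsupported context length k={k}; expected 4 or 6")
    flank = k // 2 - 1
    out = []
    for left in product("ACGT", repeat=flank):
        for right in product("ACGT", repeat=flank):
            out.append("".join(left) + "CG" + "".join(right))
    return out


def pair_reverse_complements(contexts: list[str]) -> tuple[list[tuple[str, str]], list[str]]:
    """Partition contexts into reverse-complement pairs and palindromes.

    Returns ``(pairs, palindromes)`` where each pair is ordered
    (lexicographically smaller member first) and pairs plus palindromes
    cover the input exactly once.
    """
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    palindromes: list[str] = []
    for c in contexts:
        if c in seen:
            continue
        rc = reverse_complement(c)
        if rc == c:
            palindromes.append(c)
            seen.add(c)
        else:
            if rc not in contexts:
                raise ValueError(f"context set is not closed under reverse complement: {c}/{rc}")
            pairs.append((min(c, rc), max(c, rc)))
            seen.update((c, rc))
    return pairs, palindromes


@dataclass(frozen=True)
class StrandCytosine:
    """One strand-resolved cytosine of a CpG dinucleotide.

    ``cpg_start`` is the 0-based position of the forward-strand C for both
    strands; ``strand`` '+' is the forward C, '-' the cytosine paired with
    the forward G (focal position ``cpg_start + 1`` on the forward strand).
    Contexts are None when the window exits the sequence or contains a
    masked base (N or lowercase).
    """

    chrom: str
    cpg_start: int
    strand: str
    context4: str | None = None
    context6: str | None = None

    @property
    def focal_pos(self) -> int:
        """Forward-strand coordinate of this record's cytosine (C or G)."""
        return self.cpg_start if self.strand == "+" else self.cpg_start + 1

    def context(self, k: int) -> str | None:
        if k == 4:
            return self.context4
        if k == 6:
            return self.context6
        raise ValueError(f"unsupported k={k}")


def find_cpg_sites(
    seq: GenomeSequence,
    included: RegionSet | None = None,
    k_list: tuple[int, ...] = (4, 6),
) -> list[StrandCytosine]:
    """Emit two strand-resolved records for every analyzable CG dimer.

    A dimer qualifies when both bases are uppercase 'CG' and, if
    ``included`` is given, both positions fall inside it.  For each k in
    ``k_list`` the context window (k/2 - 1 flanking bases per side) is
    attached when fully in-bounds and ACGT-only; otherwise that context is
    left missing.  Overlapping CGs (e.g. in "CGCG") each yield their own
    pair of records.
    """
    if not set(k_list) <= {4, 6}:
        raise ValueError(f"k_list {k_list} not a subset of (4, 6)")
    bases = seq.bases
    records: list[StrandCytosine] = []
    start = 0
    while True:
        i = bases.find("CG", start)
        if i < 0:
            break
        start = i + 1
        if included is not None and not (
            included.contains(seq.name, i) and included.contains(seq.name, i + 1)
        ):
            continue
        contexts: dict[int, str | None] = {4: None, 6: None}
        for k in k_list:
            flank = k // 2 - 1
            lo, hi = i - flank, i + 2 + flank
            if lo >= 0 and hi <= len(bases):
                window = bases[lo:hi]
                if set(window) <= ANALYZABLE:
                    contexts[k] = window
        fwd4, fwd6 = contexts[4], contexts[6]
        records.append(StrandCytosine(seq.name, i, "+", fwd4, fwd6))
        records.append(
            StrandCytosine(
                seq.name,
                i,
                "-",
                reverse_complement(fwd4) if fwd4 else None,
                reverse_complement(fwd6) if fwd6 else None,
            )
        )
    return records
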