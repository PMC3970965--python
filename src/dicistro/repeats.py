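"""Exact/near-exact repeat discovery and 5'-terminal similarity scanning.

Internal duplications of the genomic 5' terminus are the signature used to
infer subgenomic RNA (sgRNA) 5' ends in calicivirus-like genomes: the
sgRNA promoter recapitulates the genomic promoter, so the internal copy
marks where the sgRNA starts and implies its length (genome length minus
internal start plus one, excluding the poly(A) tail's variable part).

Genomes here are small (~10 kb), so repeat discovery uses seeded
extension with quadratic worst case rather than suffix structures.
Trailing poly(A) runs are masked by default because homopolymer tails
create spurious repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .seqio import GenomeRecord, Region, UNAMBIGUOUS


@dataclass(frozen=True)
class RepeatHit:
    """A pair of equal-length repeated segments (seq_a.start < seq_b.start)."""

    seq_a: Region
    seq_b: Region
    length: int
    mismatches: int
    identity: float


@dataclass(frozen=True)
class TerminalMatch:
    """An internal window similar to the genomic 5' terminus."""

    internal_start: int  # 1-based
    window: int
    identity: float
    implied_sg_length: int  # genome_length - internal_start + 1


def polya_mask_length(record: GenomeRecord, min_run: int = 10) -> int:
    """Effective length once a trailing run of >= ``min_run`` A's is masked."""
    n = record.length
    run = 0
    while run < n and record.seq[n - 1 - run] == "A":
        run += 1
    return n - run if run >= min_run else n


def _match(a: str, b: str) -> bool:
    """Base equality with ambiguity codes counting as mismatches."""
    return a == b and a in UNAMBIGUOUS


def find_exact_repeats(
    record: GenomeRecord, k_min: int, mask_polya: bool = True, polya_min_run: int = 10
) -> list[RepeatHit]:
    """All maximal repeated substring pairs of length >= ``k_min``.

    Every occurrence pair of a maximal (left- and right-inextensible)
    repeat is reported.  Seeds are exact ``k_min``-mers; each seed pair is
    extended to maximality and deduplicated, which finds every maximal
    pair because any repeat of length >= k contains a seed at its offset.
    """
    if k_min < 8:
        raise ValueError("k_min must be >= 8")
    n = polya_mask_length(record, polya_min_run) if mask_polya else record.length
    seq = record.seq[:n]
    if k_min > n:
        return []

    buckets: dict[str, list[int]] = {}
    for i in range(n - k_min + 1):
        kmer = seq[i : i + k_min]
        if any(b not in UNAMBIGUOUS for b in kmer):
            continue
        buckets.setdefault(kmer, []).append(i)

    seen: set[tuple[int, int, int]] = set()
    hits: list[RepeatHit] = []
    for positions in buckets.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                # extend left
                li, lj = i, j
                while li > 0 and lj > 0 and _match(seq[li - 1], seq[lj - 1]):
                    li -= 1
                    lj -= 1
                # extend right
                length = k_min + (i - li)
                while (
                    lj + length < n and _match(seq[li + length], seq[lj + length])
                ):
                    length += 1
                key = (li, lj, length)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    RepeatHit(
                        seq_a=Region(li + 1, li + length),
                        seq_b=Region(lj + 1, lj + length),
                        length=length,
                        mismatches=0,
                        identity=1.0,
                    )
                )
    hits.sort(key=lambda h: (h.seq_a.start, h.seq_b.start))
    return hits


def repeat_chance_probability(L: int, k: int) -> float:
    """Chance probability of an exact k-mer repeat in an L-nt i.i.d. sequence.

    The expected number of identical unordered k-mer position pairs under a
    uniform 4-letter model, ``C(L-k+1, 2) * 4**-k``, capped at 1 -- a
    Bonferroni-style bound used as the repeat's chance probability.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if L < k:
        raise ValueError(f"L={L} shorter than k={k}")
    pairs = math.comb(L - k + 1, 2)
    return min(1.0, pairs * 4.0 ** (-k))


def compare_regions(record: GenomeRecord, region_a: Region, region_b: Region) -> RepeatHit:
    """Positionwise (Hamming) comparison of two equal-length regions."""
    if region_a.length != region_b.length:
        raise ValueError(
            f"regions have unequal lengths ({region_a.length} vs {region_b.length})"
        )
    region_a.check_within(record)
    region_b.check_within(record)
    a, b = sorted((region_a, region_b), key=lambda r: r.start)
    sa = record.seq[a.start - 1 : a.end]
    sb = record.seq[b.start - 1 : b.end]
    mismatches = sum(0 if _match(x, y) else 1 for x, y in zip(sa, sb))
    length = a.length
    return RepeatHit(
        seq_a=a,
        seq_b=b,
        length=length,
        mismatches=mismatches,
        identity=(length - mismatches) / length,
    )


def terminal_similarity_scan(
    record: GenomeRecord,
    window: int,
    min_identity: float,
    search_region: Optional[Region] = None,
) -> list[TerminalMatch]:
    """Ungapped identity of internal windows against the genomic 5' terminus.

    For each internal start position in ``search_region`` (default: the
    whole genome downstream of position 1), the identity between the
    5'-terminal ``window`` nucleotides and the equal-length window starting
    there is computed; hits at or above ``min_identity`` are returned with
    the sgRNA length they imply.
    """
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    L = record.length
    if window > L:
        raise ValueError("window longer than genome")
    region = search_region or Region(2, L)
    region.check_within(record)
    if window > region.length:
        raise ValueError("window longer than search region")

    arr = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    term = arr[:window]
    term_valid = valid[:window]

    hits: list[TerminalMatch] = []
    last_start = min(region.end, L - window + 1)
    for s in range(region.start, last_start + 1):
        w = arr[s - 1 : s - 1 + window]
        matches = int(np.count_nonzero((w == term) & valid[s - 1 : s - 1 + window] & term_valid))
        identity = matches / window
        if identity >= min_identity:
            hits.append(
                TerminalMatch(
                    internal_start=s,
                    window=window,
                    identity=identity,
                    implied_sg_length=L - s + 1,
                )
            )
    return hits
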