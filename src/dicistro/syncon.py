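"""Windowed synonymous-site conservation statistic over aligned CDSs.

Overlapping functional elements (internal promoters, overlapping genes,
RNA structures) suppress substitutions at positions where substitutions
would otherwise be synonymous and nearly neutral.  The statistic here
slides a window (default 25 codons) along a codon alignment, compares the
observed number of synonymous differences with the number expected under a
uniform neutral synonymous rate estimated from the whole alignment, and
reports a one-tailed Poisson depletion p-value per window.

Synonymous opportunity per codon follows NG86-style counting: each codon
position contributes (number of synonymous single-nucleotide changes)/3,
with changes that create a stop codon classed nonsynonymous.  Codon pairs
that encode different amino acids, or contain gaps or ambiguity codes, are
excluded entirely; this biases the depletion test conservatively and
avoids multi-path counting ambiguity.

The null model is deliberately simple (single global rate, Poisson counts,
pair-summation for multi-sequence alignments without phylogenetic
weighting); it is a faithful-in-spirit depletion screen, not a
phylogeny-aware reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import poisson

from .codons import STOP_CODONS, amino_acid, classify_changes
from .seqio import UNAMBIGUOUS, canonicalize


@lru_cache(maxsize=None)
def syn_site_count(codon: str) -> float:
    """NG86 synonymous-site opportunity of a sense codon.

    Sum over the three positions of (#synonymous single-nt changes at that
    position)/3.  Stop codons and ambiguous codons raise ``ValueError``.
    """
    codon = canonicalize(codon)
    if len(codon) != 3 or any(b not in UNAMBIGUOUS for b in codon):
        raise ValueError(f"ambiguous or malformed codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon: {codon}")
    syn, _ = classify_changes(codon)
    return len(syn) / 3.0


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Aligned coding sequences mapped to codon columns of a reference row.

    ``frame_anchor`` is the 1-based *alignment column* holding the first
    base of the reference's first codon.  Codon columns are formed by
    grouping the reference's non-gap columns into consecutive triplets; a
    terminal reference stop codon is dropped from the analyzed span.
    """

    sequences: list[str]
    ids: list[str] = field(default_factory=list)
    reference_index: int = 0
    frame_anchor: int = 1
    gap_char: str = "-"

    def __post_init__(self) -> None:
        self.sequences = [canonicalize(s) for s in self.sequences]
        if len(self.sequences) < 2:
            raise ValueError("need at least two aligned sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        self.alignment_length = lengths.pop()
        if self.alignment_length < 3:
            raise ValueError("alignment shorter than one codon")
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]
        if not (1 <= self.frame_anchor <= self.alignment_length):
            raise ValueError("frame_anchor outside alignment")
        self._codon_columns = self._build_codon_columns()

    def _build_codon_columns(self) -> list[tuple[int, int, int]]:
        ref = self.sequences[self.reference_index]
        cols = [
            i
            for i in range(self.frame_anchor - 1, self.alignment_length)
            if ref[i] != self.gap_char
        ]
        if len(cols) % 3 != 0:
            raise ValueError(
                "reference coding span (gaps removed) not divisible by 3 "
                f"({len(cols)} columns from anchor)"
            )
        triplets = [tuple(cols[i : i + 3]) for i in range(0, len(cols), 3)]
        # Drop a terminal reference stop; reject internal reference stops.
        ref_codons = ["".join(ref[c] for c in t) for t in triplets]
        if ref_codons and ref_codons[-1] in STOP_CODONS:
            triplets = triplets[:-1]
            ref_codons = ref_codons[:-1]
        for j, codon in enumerate(ref_codons, start=1):
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop codon in reference at codon {j}")
        return triplets

    @property
    def n_codons(self) -> int:
        return len(self._codon_columns)

    def row_codons(self, row: int) -> list[str]:
        """Codon-column triplets of ``row`` (may contain gaps/ambiguity)."""
        s = self.sequences[row]
        return ["".join(s[c] for c in t) for t in self._codon_columns]


def read_alignment_fasta(
    path: str | Path, reference_index: int = 0, frame_anchor: int = 1
) -> CodonAlignment:
    """Load an aligned FASTA (gap character ``-``) as a codon alignment."""
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return CodonAlignment(
        sequences=seqs, ids=ids, reference_index=reference_index, frame_anchor=frame_anchor
    )


# ---------------------------------------------------------------------------
# Per-codon statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonColumnStat:
    """Observed synonymous differences and opportunity at one reference codon."""

    codon_index: int  # 1-based codon number in the reference
    obs_syn: float  # summed over contributing sequence pairs
    syn_sites: float  # summed NG86 opportunity over contributing pairs
    usable: bool  # at least one pair passed the filters
    n_pairs: int = 0


_CODON_OK = None  # lazy lookup tables keyed by codon string


def _codon_tables() -> tuple[dict, dict, dict]:
    """Per-codon lookups: validity, amino acid, synonymous-site count."""
    global _CODON_OK
    if _CODON_OK is None:
        ok: dict[str, bool] = {}
        aa: dict[str, str] = {}
        sites: dict[str, float] = {}
        from .codons import ALL_CODONS

        for codon in ALL_CODONS:
            if codon in STOP_CODONS:
                ok[codon] = False
            else:
                ok[codon] = True
                aa[codon] = amino_acid(codon)
                sites[codon] = syn_site_count(codon)
        _CODON_OK = (ok, aa, sites)
    return _CODON_OK


def column_stats(alignment: CodonAlignment) -> list[CodonColumnStat]:
    """Pairwise synonymous counts per reference codon.

    For each unordered sequence pair whose two codons at a reference codon
    column are gap-free, unambiguous, non-stop and encode the same amino
    acid: ``obs_syn`` accumulates the number of differing nucleotide
    positions and ``syn_sites`` the mean of the two codons' opportunities.
    Pairs failing the filter contribute nothing.
    """
    ok, aa, sites = _codon_tables()
    rows = [alignment.row_codons(r) for r in range(len(alignment.sequences))]
    n_rows = len(rows)
    n_codons = alignment.n_codons

    obs = np.zeros(n_codons)
    opp = np.zeros(n_codons)
    npairs = np.zeros(n_codons, dtype=int)

    for a in range(n_rows):
        for b in range(a + 1, n_rows):
            ra, rb = rows[a], rows[b]
            for j in range(n_codons):
                ca, cb = ra[j], rb[j]
                va = ok.get(ca, False)
                vb = ok.get(cb, False)
                if not (va and vb) or aa[ca] != aa[cb]:
                    continue
                obs[j] += (ca[0] != cb[0]) + (ca[1] != cb[1]) + (ca[2] != cb[2])
                opp[j] += (sites[ca] + sites[cb]) / 2.0
                npairs[j] += 1

    return [
        CodonColumnStat(
            codon_index=j + 1,
            obs_syn=float(obs[j]),
            syn_sites=float(opp[j]),
            usable=bool(npairs[j] > 0),
            n_pairs=int(npairs[j]),
        )
        for j in range(n_codons)
    ]


# ---------------------------------------------------------------------------
# Sliding-window profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowStat:
    center: int  # 1-based reference codon index of the window center
    start: int
    end: int
    obs: float
    exp: float
    ratio: float
    p_value: float


@dataclass(frozen=True)
class ConservationProfile:
    windows: tuple[WindowStat, ...]
    window_size: int
    step: int
    p_hat: float  # global neutral synonymous rate per site

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon_index": [w.center for w in self.windows],
                "window_start": [w.start for w in self.windows],
                "window_end": [w.end for w in self.windows],
                "window_obs": [w.obs for w in self.windows],
                "window_exp": [w.exp for w in self.windows],
                "ratio": [w.ratio for w in self.windows],
                "p_value": [w.p_value for w in self.windows],
            }
        )


def conservation_profile(
    stats: Sequence[CodonColumnStat], window_size: int = 25, step: int = 1
) -> ConservationProfile:
    """Sliding-window depletion profile over per-codon statistics.

    The global neutral rate ``p_hat`` is total observed synonymous changes
    divided by total synonymous opportunity.  Per window, the expected
    count is ``p_hat * sites_w`` and the p-value is the one-tailed Poisson
    probability of observing at most ``obs_w`` changes (depletion test).
    Windows are full-width only (truncated terminal windows are dropped)
    and windows without synonymous opportunity are omitted.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    stats = sorted(stats, key=lambda s: s.codon_index)
    obs = np.array([s.obs_syn for s in stats])
    opp = np.array([s.syn_sites for s in stats])
    n_usable = sum(1 for s in stats if s.usable)
    if n_usable < window_size:
        raise ValueError(
            f"need at least {window_size} usable codons, have {n_usable}"
        )
    total_opp = opp.sum()
    if total_opp == 0:
        raise ValueError("no synonymous opportunity")
    p_hat = float(obs.sum() / total_opp)

    n = len(stats)
    cobs = np.concatenate([[0.0], np.cumsum(obs)])
    copp = np.concatenate([[0.0], np.cumsum(opp)])
    windows: list[WindowStat] = []
    for start0 in range(0, n - window_size + 1, step):
        end0 = start0 + window_size
        obs_w = cobs[end0] - cobs[start0]
        sites_w = copp[end0] - copp[start0]
        if sites_w <= 0:
            continue
        exp_w = p_hat * sites_w
        if exp_w <= 0:
            continue
        p_value = float(poisson.cdf(obs_w, exp_w))
        windows.append(
            WindowStat(
                center=stats[start0].codon_index + window_size // 2,
                start=stats[start0].codon_index,
                end=stats[end0 - 1].codon_index,
                obs=float(obs_w),
                exp=float(exp_w),
                ratio=float(obs_w / exp_w),
                p_value=p_value,
            )
        )
    return ConservationProfile(
        windows=tuple(windows), window_size=window_size, step=step, p_hat=p_hat
    )


def profile_alignment(
    alignment: CodonAlignment, window_size: int = 25, step: int = 1
) -> ConservationProfile:
    """Convenience composition of :func:`column_stats` and :func:`conservation_profile`."""
    return conservation_profile(column_stats(alignment), window_size=window_size, step=step)
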