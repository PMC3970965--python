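"""Seeded generators for testable stand-ins of the study inputs.

Two generators:

* :func:`evolve_pair` -- a pair of homologous CDSs diverged from a common
  ancestor under independent synonymous/nonsynonymous substitution, with
  an optional window in which the synonymous rate is multiplied (planting
  a conserved element, as an overlapping functional element would).  Every
  substitution is logged, so the divergence structure is exactly known.

* :func:`build_toy_genome` -- a miniature dicistronic genome with the
  architecture of an SINV-3-like virus: 5' UTR carrying an exact repeat,
  ORF1 ending in a -1 frameshift cassette (U_GAU_UUA_AAC_UGA), an
  extended ORF2 in the -1 frame, an internal near-duplicate of the 5'
  terminus (the toy sgRNA start), and a poly(A) tail.  The returned truth
  annotation is the oracle for every downstream analysis stage.

Substitutions are applied without back-mutation bookkeeping (rates are
well below one per site) and alignments are generated gap-free; indels
and realistic codon usage are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codons import (
    SENSE_CODONS,
    STOP_CODONS,
    amino_acid,
    classify_changes,
    translate_codons,
)
from .seqio import GenomeRecord, write_fasta
from .syncon import CodonAlignment, syn_site_count

_SENSE = np.array(SENSE_CODONS)


# ---------------------------------------------------------------------------
# Evolved CDS pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvolvedPairSpec:
    """Study conditions for a diverged CDS pair.

    Defaults emulate a full dicistronic polyprotein alignment between two
    viruses at roughly 13% pairwise amino-acid divergence with substantial
    synonymous divergence.  Rates are expected substitutions per site per
    lineage; the conserved window multiplies the synonymous rate inside
    ``(start_codon, end_codon)`` by ``multiplier``.
    """

    n_codons: int = 3000
    syn_rate: float = 0.25
    nonsyn_rate: float = 0.03
    conserved_window: Optional[tuple[int, int, float]] = None  # 1-based, inclusive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if not (0 <= self.syn_rate < 1 and 0 <= self.nonsyn_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.conserved_window is not None:
            a, b, m = self.conserved_window
            if not (1 <= a <= b <= self.n_codons):
                raise ValueError("conserved window outside CDS")
            if not (0 <= m <= 1):
                raise ValueError("multiplier must be in [0, 1]")


@dataclass(frozen=True)
class SubstitutionEvent:
    lineage: int  # 0 or 1
    codon_index: int  # 1-based
    codon_pos: int  # 1-3
    nt_position: int  # 1-based within the CDS
    from_base: str
    to_base: str
    kind: str  # "syn" | "nonsyn"


@dataclass(frozen=True)
class EvolvedPair:
    alignment: CodonAlignment
    events: tuple[SubstitutionEvent, ...]
    ancestor: str


def _evolve_lineage(
    codons: list[str],
    lineage: int,
    spec: EvolvedPairSpec,
    rng: np.random.Generator,
) -> tuple[list[str], list[SubstitutionEvent]]:
    n = len(codons)
    mult = np.ones(n)
    if spec.conserved_window is not None:
        a, b, m = spec.conserved_window
        mult[a - 1 : b] = m
    syn_lam = np.array([syn_site_count(c) for c in codons]) * spec.syn_rate * mult
    nonsyn_lam = np.array([3.0 - syn_site_count(c) for c in codons]) * spec.nonsyn_rate
    n_syn = rng.poisson(syn_lam)
    n_nonsyn = rng.poisson(nonsyn_lam)

    out = list(codons)
    events: list[SubstitutionEvent] = []
    for j in np.nonzero(n_syn + n_nonsyn)[0]:
        # interleave the codon's events in random order
        kinds = ["syn"] * int(n_syn[j]) + ["nonsyn"] * int(n_nonsyn[j])
        rng.shuffle(kinds)
        for kind in kinds:
            syn_targets, nonsyn_targets = classify_changes(out[j])
            if kind == "syn":
                targets = syn_targets
            else:  # stops are never created
                targets = tuple(t for t in nonsyn_targets if t not in STOP_CODONS)
            if not targets:  # e.g. ATG/TGG have no synonymous moves left
                continue
            new = targets[rng.integers(len(targets))]
            old = out[j]
            pos = next(k for k in range(3) if old[k] != new[k])
            events.append(
                SubstitutionEvent(
                    lineage=lineage,
                    codon_index=int(j) + 1,
                    codon_pos=pos + 1,
                    nt_position=3 * int(j) + pos + 1,
                    from_base=old[pos],
                    to_base=new[pos],
                    kind=kind,
                )
            )
            out[j] = new
    return out, events


def evolve_pair(spec: EvolvedPairSpec) -> EvolvedPair:
    """Simulate a diverged CDS pair; every substitution is logged.

    The ancestor is drawn codon-uniform over the 61 sense codons; each
    lineage receives Poisson-distributed synonymous and nonsynonymous
    substitutions per codon with NG86-style opportunities evaluated on the
    ancestral codon.  Stops are never created.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = list(rng.choice(_SENSE, size=spec.n_codons))
    d0, e0 = _evolve_lineage(ancestor, 0, spec, rng)
    d1, e1 = _evolve_lineage(ancestor, 1, spec, rng)
    alignment = CodonAlignment(
        sequences=["".join(d0), "".join(d1)],
        ids=["lineage0", "lineage1"],
        reference_index=0,
        frame_anchor=1,
    )
    return EvolvedPair(
        alignment=alignment, events=tuple(e0 + e1), ancestor="".join(ancestor)
    )


def apply_events(ancestor: str, events: Sequence[SubstitutionEvent], lineage: int) -> str:
    """Replay logged substitutions onto the ancestor (reconciliation check)."""
    seq = list(ancestor)
    for ev in events:
        if ev.lineage != lineage:
            continue
        idx = ev.nt_position - 1
        if seq[idx] != ev.from_base:
            raise ValueError(
                f"event log inconsistent at {ev.nt_position}: "
                f"expected {ev.from_base}, found {seq[idx]}"
            )
        seq[idx] = ev.to_base
    return "".join(seq)


# ---------------------------------------------------------------------------
# Toy dicistronic genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Architecture of a miniature dicistronic genome.

    Defaults mirror the SINV-3 layout: a 91-nt 5' UTR whose first
    ``dup_window`` nucleotides recur internally (with ``dup_mismatches``
    differences) as the toy sgRNA 5' end, a 24-nt exact repeat occupying
    the 3' end of that terminal window, ORF1 terminating in the
    U_GAU_UUA_AAC_UGA cassette, an extended -1-frame ORF2, and a poly(A)
    tail.  ``orf1_len``/``orf2_len`` count sense codons (stops excluded).
    """

    utr5_len: int = 91
    orf1_len: int = 240
    orf2_len: int = 150
    repeat_len: int = 24
    repeat_pos: int = 13  # 1-based start of the repeat inside the terminal window
    dup_window: int = 36
    dup_mismatches: int = 1
    dup_gap: int = 126  # nt between the duplicate's end and the cassette start
    trailer_len: int = 30
    polya_len: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeat_pos < 2:
            raise ValueError("repeat must not be anchored at position 1")
        if self.repeat_pos + self.repeat_len - 1 != self.dup_window:
            raise ValueError("repeat must end exactly at the terminal-window end")
        if self.dup_window > self.utr5_len:
            raise ValueError("terminal window longer than the 5' UTR")
        if self.dup_mismatches > 0 and self.dup_mismatches > self.repeat_pos - 2:
            raise ValueError(
                "not enough window positions upstream of the repeat to place "
                f"{self.dup_mismatches} mismatches"
            )
        if self.orf1_len < 10:
            raise ValueError("orf1_len too short for the cassette")
        if self.polya_len < 10:
            raise ValueError("polya_len must be >= 10 (maskable tail)")


@dataclass(frozen=True)
class ToyGenomeTruth:
    """Planted coordinates and expected analysis outcomes (the oracle)."""

    utr5: tuple[int, int]
    orf1_start: int  # the AUG
    orf1_cds: tuple[int, int]  # start..stop-end (stop included)
    orf1_frame: int
    slippery_pos: int
    heptamer: str
    cassette: tuple[int, int]  # upstream -1-frame stop .. ORF1 stop end
    cassette_rendering: str
    orf2_frame: int
    orf2_extended: tuple[int, int]  # after upstream stop .. ORF2 stop end
    repeat_a: tuple[int, int]
    repeat_b: tuple[int, int]
    repeat_len: int
    expected_maximal_repeat: tuple[tuple[int, int], tuple[int, int]]
    dup_region: tuple[int, int]
    dup_window: int
    dup_mismatch_positions: tuple[int, ...]  # 1-based within the window
    dup_identity: float
    sg_start: int
    sg_length: int
    first_augs_after_sg: tuple[int, ...]
    polya: tuple[int, int]
    genome_length: int
    nonframeshift_peptide: str
    transframe_peptide: str

    def as_dict(self) -> dict:
        return asdict(self)


def _random_sense_codon(rng: np.random.Generator, exclude_atg: bool = False) -> str:
    while True:
        c = str(_SENSE[rng.integers(len(_SENSE))])
        if exclude_atg and c == "ATG":
            continue
        return c


def _random_utr(rng: np.random.Generator, length: int) -> str:
    """Random UTR without any ATG (so planted starts stay first)."""
    bases = list("ACGT")
    utr = [bases[i] for i in rng.integers(4, size=length)]
    s = "".join(utr)
    while "ATG" in s:
        idx = s.index("ATG")
        utr[idx + 2] = "ACT"[rng.integers(3)]
        s = "".join(utr)
    return s


def _scan_phase_ok_slippery(seq: str, frame: int) -> list[int]:
    """Independent naive scan used for generator-side validation."""
    out = []
    for pos in range(1, len(seq) - 5):
        h = seq[pos - 1 : pos + 6]
        if (
            h[0] == h[1] == h[2]
            and h[3] == h[4] == h[5]
            and h[3:6] in ("AAA", "TTT")
            and h[6] != "G"
            and (pos - 1 - frame) % 3 == 2
        ):
            out.append(pos)
    return out


def build_toy_genome(
    spec: ToyGenomeSpec, max_attempts: int = 500
) -> tuple[GenomeRecord, ToyGenomeTruth]:
    """Construct a toy genome; all planted features recorded in the truth.

    Construction is by rejection: a candidate is rebuilt with a fresh
    derived seed until the planted features are exactly recoverable (no
    accidental in-phase slippery sites, no premature stops introduced by
    the spliced duplicate, repeat maximality respected).
    """
    seed_seq = np.random.SeedSequence(spec.seed)
    for attempt, child in enumerate(seed_seq.spawn(max_attempts)):
        rng = np.random.default_rng(child)
        result = _try_build(spec, rng)
        if result is not None:
            return result
    raise ValueError(
        f"could not satisfy ToyGenomeSpec within {max_attempts} attempts; "
        "the planted features may be contradictory"
    )


def _try_build(
    spec: ToyGenomeSpec, rng: np.random.Generator
) -> Optional[tuple[GenomeRecord, ToyGenomeTruth]]:
    utr = _random_utr(rng, spec.utr5_len)

    # ORF1: ATG + body + [codon ending T] GAT TTA AAC + TGA.
    n_body = spec.orf1_len - 5
    body = [_random_sense_codon(rng) for _ in range(n_body)]
    c_pre = None
    while c_pre is None or not c_pre.endswith("T"):
        c_pre = _random_sense_codon(rng)
    orf1_codons = ["ATG", *body, c_pre, "GAT", "TTA", "AAC"]
    assert len(orf1_codons) == spec.orf1_len

    s1 = spec.utr5_len + 1
    e1 = s1 + 3 * spec.orf1_len + 2  # end of the TGA stop
    o1 = e1 - 12  # cassette start: last base of c_pre
    p = o1 + 3  # heptamer start (codon position 3 of GAT)

    # ORF2 tail: -1-frame codons continue across the ORF1 stop.  The codon
    # at e1 starts with the stop's final A; A-initial codons are all sense.
    first_tail = "A" + "".join("ACGT"[i] for i in rng.integers(4, size=2))
    tail_codons = [first_tail] + [
        _random_sense_codon(rng) for _ in range(spec.orf2_len - 1)
    ]
    e2 = e1 + 3 * spec.orf2_len + 2  # end of ORF2's TAA stop

    trailer = "".join("ACGT"[i] for i in rng.integers(4, size=spec.trailer_len))
    if spec.trailer_len:
        trailer = trailer[:-1] + "CGT"[rng.integers(3)]  # keep poly(A) coords exact

    genome = (
        utr
        + "".join(orf1_codons)
        + "TGA"
        + "".join(c[1:] if i == 0 else c for i, c in enumerate(tail_codons))
        + "TAA"
        + trailer
        + "A" * spec.polya_len
    )

    # Splice the near-duplicate of the 5' terminus into ORF1.
    d1 = o1 - spec.dup_gap - spec.dup_window
    if d1 <= s1 + 3:
        raise ValueError("duplicate would not fit inside ORF1; shrink dup_gap or grow orf1_len")
    window_src = genome[: spec.dup_window]
    dup = list(window_src)
    mismatch_wpos: list[int] = []
    if spec.dup_mismatches >= 1:
        # one mismatch immediately left of the repeat blocks left-extension
        slots = [spec.repeat_pos - 1]
        extra = rng.permutation(np.arange(1, spec.repeat_pos - 1))[: spec.dup_mismatches - 1]
        slots += [int(x) for x in extra]
        for wp in sorted(slots):
            orig = dup[wp - 1]
            choices = [b for b in "ACGT" if b != orig]
            dup[wp - 1] = choices[rng.integers(3)]
            mismatch_wpos.append(wp)
    genome = genome[: d1 - 1] + "".join(dup) + genome[d1 - 1 + spec.dup_window :]

    # --- validation (naive, generator-side) ---
    f1 = (s1 - 1) % 3
    orf1_seq = genome[s1 - 1 : e1]
    codons_now = [orf1_seq[i : i + 3] for i in range(0, len(orf1_seq), 3)]
    if any(c in STOP_CODONS for c in codons_now[:-1]) or codons_now[-1] != "TGA":
        return None  # splice created a premature ORF1 stop
    # repeat right-inextensibility: base after each copy must differ
    if genome[spec.dup_window] == genome[d1 - 1 + spec.dup_window]:
        return None
    # exactly one in-phase slippery site upstream of the ORF1 stop (the
    # planted one); hits further 3' (ORF2 tail, poly(A) A-runs) fall outside
    # ORF1 and are filtered by consumers
    if _scan_phase_ok_slippery(genome[:e1], f1) != [p]:
        return None
    # the -1 frame must be open from the YYY codon to the planted ORF2 stop
    f2 = (p + 3 - 1) % 3
    for pos in range(p + 3, e2 - 2, 3):
        codon = genome[pos - 1 : pos + 2]
        if codon in STOP_CODONS and pos != e2 - 2:
            return None

    record = GenomeRecord(id=f"toy_genome_seed{spec.seed}", seq=genome)

    # Expected maximal exact repeat: with mismatches the planted copy pair;
    # without, the two whole terminal windows merge into one longer repeat.
    rep_a = (spec.repeat_pos, spec.repeat_pos + spec.repeat_len - 1)
    rep_b = (d1 + spec.repeat_pos - 1, d1 + spec.dup_window - 1)
    if spec.dup_mismatches == 0:
        expected_max = ((1, spec.dup_window), (d1, d1 + spec.dup_window - 1))
    else:
        expected_max = (rep_a, rep_b)

    # First AUGs downstream of the toy sgRNA start (naive scan).
    augs: list[int] = []
    idx = genome.find("ATG", d1 - 1)
    while idx != -1 and len(augs) < 3:
        augs.append(idx + 1)
        idx = genome.find("ATG", idx + 1)

    # Expected peptides, from the construction itself.
    nonfs_codons = [genome[pos - 1 : pos + 2] for pos in range(s1, e1 - 3, 3)]
    nonfs_peptide = translate_codons(nonfs_codons)
    seg1_codons = [genome[pos - 1 : pos + 2] for pos in range(s1, p + 2, 3)]  # ..XXY
    seg2_codons = [genome[pos - 1 : pos + 2] for pos in range(p + 3, e2 - 3, 3)]  # YYY..
    transframe_peptide = translate_codons(seg1_codons) + translate_codons(seg2_codons)

    truth = ToyGenomeTruth(
        utr5=(1, spec.utr5_len),
        orf1_start=s1,
        orf1_cds=(s1, e1),
        orf1_frame=f1,
        slippery_pos=p,
        heptamer=genome[p - 1 : p + 6],
        cassette=(o1, e1),
        cassette_rendering="U_GAU_UUA_AAC_UGA",
        orf2_frame=f2,
        orf2_extended=(o1 + 3, e2),
        repeat_a=rep_a,
        repeat_b=rep_b,
        repeat_len=spec.repeat_len,
        expected_maximal_repeat=expected_max,
        dup_region=(d1, d1 + spec.dup_window - 1),
        dup_window=spec.dup_window,
        dup_mismatch_positions=tuple(sorted(mismatch_wpos)),
        dup_identity=(spec.dup_window - spec.dup_mismatches) / spec.dup_window,
        sg_start=d1,
        sg_length=len(genome) - d1 + 1,
        first_augs_after_sg=tuple(augs),
        polya=(len(genome) - spec.polya_len + 1, len(genome)),
        genome_length=len(genome),
        nonframeshift_peptide=nonfs_peptide,
        transframe_peptide=transframe_peptide,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Batch fixture writer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BatchSpec:
    """Replicated fixture sets, deterministic given the master seed."""

    n_neutral_pairs: int = 0
    n_planted_pairs: int = 0
    n_toy_genomes: int = 0
    pair_template: EvolvedPairSpec = field(default_factory=EvolvedPairSpec)
    planted_window: tuple[int, int, float] = (276, 325, 0.0)
    toy_template: ToyGenomeSpec = field(default_factory=ToyGenomeSpec)
    master_seed: int = 0


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def batch(outdir: str | Path, run_spec: BatchSpec) -> Path:
    """Write FASTA + truth-JSON fixtures per replicate; returns the directory."""
    import dataclasses

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    total = run_spec.n_neutral_pairs + run_spec.n_planted_pairs + run_spec.n_toy_genomes
    seeds = _derive_seeds(run_spec.master_seed, max(total, 1))
    cursor = 0

    def pair_files(tag: str, spec: EvolvedPairSpec, i: int) -> None:
        pair = evolve_pair(spec)
        recs = [
            GenomeRecord(id=f"{tag}{i:03d}_{name}", seq=seq)
            for name, seq in zip(pair.alignment.ids, pair.alignment.sequences)
        ]
        write_fasta(recs, outdir / f"{tag}{i:03d}.fasta")
        with open(outdir / f"{tag}{i:03d}.truth.json", "w") as fh:
            json.dump(
                {
                    "spec": dataclasses.asdict(spec),
                    "ancestor": pair.ancestor,
                    "events": [dataclasses.asdict(e) for e in pair.events],
                },
                fh,
            )

    for i in range(run_spec.n_neutral_pairs):
        spec = dataclasses.replace(
            run_spec.pair_template, conserved_window=None, seed=seeds[cursor]
        )
        pair_files("neutral", spec, i)
        cursor += 1
    for i in range(run_spec.n_planted_pairs):
        spec = dataclasses.replace(
            run_spec.pair_template,
            conserved_window=run_spec.planted_window,
            seed=seeds[cursor],
        )
        pair_files("planted", spec, i)
        cursor += 1
    for i in range(run_spec.n_toy_genomes):
        spec = dataclasses.replace(run_spec.toy_template, seed=seeds[cursor])
        record, truth = build_toy_genome(spec)
        write_fasta([record], outdir / f"toy{i:03d}.fasta")
        with open(outdir / f"toy{i:03d}.truth.json", "w") as fh:
            json.dump(
                {"spec": dataclasses.asdict(spec), "truth": truth.as_dict()}, fh
            )
        cursor += 1
    return outdir
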