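"""ORF discovery, stop-codon maps, -1 frameshift slippery sites, overlap
cassettes and start-codon (Kozak-like) context calls.

All scanning is forward-strand only (the viruses modelled here are
positive-sense, single-stranded RNA).  Frames are labelled 0/1/2 by the
offset, modulo 3, of the first codon base from genome position 1; a -1
programmed ribosomal frameshift moves the ribosome from frame ``f`` into
frame ``(f + 2) % 3`` (codon starts shift one nucleotide 5'-ward).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .codons import STOP_CODONS
from .seqio import GenomeRecord, Region, canonicalize

#: Default slippery-heptamer class X_XXY_YYZ: homopolymeric XXX,
#: YYY in {AAA, TTT}, Z != G (covers U_UUA_AAC and relatives).
DEFAULT_YYY = ("AAA", "TTT")


@dataclass(frozen=True)
class FrameFeature:
    """An ORF, stop codon, slippery site or ORF-overlap with frame annotation."""

    kind: str  # orf | stop | slippery | overlap | start_codon
    region: Optional[Region]
    frame: int
    phase_ok: Optional[bool] = None
    annotation: str = ""
    offset: Optional[int] = None  # signed relative frame for overlaps


@dataclass(frozen=True)
class StartContext:
    """Kozak-like context of an AUG: bases at -3 and +4 and a strong/weak call.

    ``call`` is ``"strong"`` iff the -3 base is a purine (A/G) or the +4
    base is G; ``"weak"`` otherwise; ``None`` when the AUG sits so close to
    a sequence edge that the context is incomplete (flagged, not an error).
    """

    position: Region
    minus3: Optional[str]
    plus4: Optional[str]
    call: Optional[str]


def _frame_of(position: int) -> int:
    """Frame whose codons start at this 1-based position."""
    return (position - 1) % 3


def codon_phase(position: int, frame: int) -> int:
    """0/1/2 position of a base within the codons of ``frame`` (0 = first)."""
    return (position - 1 - frame) % 3


def render_phased(record: GenomeRecord, start: int, end: int, frame: int) -> str:
    """Underscore-phased RNA rendering of ``start..end`` in codons of ``frame``.

    Partial codons at the edges are rendered as-is, e.g. the 13-nt
    frameshift cassette phased by the upstream ORF reads
    ``U_GAU_UUA_AAC_UGA``.
    """
    Region(start, end).check_within(record)
    tokens: list[str] = []
    current = ""
    for pos in range(start, end + 1):
        if codon_phase(pos, frame) == 0 and current:
            tokens.append(current)
            current = ""
        current += record.seq[pos - 1]
    if current:
        tokens.append(current)
    return "_".join(tokens).replace("T", "U")


# ---------------------------------------------------------------------------
# Stop maps and ORFs
# ---------------------------------------------------------------------------


def stop_map(record: GenomeRecord) -> dict[int, list[int]]:
    """1-based start positions of stop codons in each forward frame."""
    if record.length < 3:
        raise ValueError("record shorter than one codon")
    stops: dict[int, list[int]] = {0: [], 1: [], 2: []}
    seq = record.seq
    for frame in range(3):
        for pos0 in range(frame, record.length - 2, 3):
            if seq[pos0 : pos0 + 3] in STOP_CODONS:
                stops[frame].append(pos0 + 1)
    return stops


def find_orfs(
    record: GenomeRecord,
    mode: str = "stop_to_stop",
    min_len: int = 1,
    frames: Iterable[int] = (0, 1, 2),
) -> list[FrameFeature]:
    """Maximal open reading intervals per forward frame.

    ``stop_to_stop`` returns the runs of sense codons between consecutive
    in-frame stops; coordinates include the terminal stop codon (when one
    exists) while ``min_len`` counts coding codons only.  ``aug_to_stop``
    anchors each run at its first in-frame AUG.  Open 3' runs without a
    terminal stop are reported with annotation ``"open"``.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1 codon")
    if mode not in ("stop_to_stop", "aug_to_stop"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = record.seq
    features: list[FrameFeature] = []
    for frame in frames:
        codon_starts = list(range(frame + 1, record.length - 1, 3))
        run_start_idx = 0
        i = 0
        while i <= len(codon_starts):
            at_end = i == len(codon_starts)
            pos = None if at_end else codon_starts[i]
            is_stop = (not at_end) and seq[pos - 1 : pos + 2] in STOP_CODONS
            if is_stop or at_end:
                run = codon_starts[run_start_idx:i]  # sense codons of the run
                start_pos = None
                if mode == "stop_to_stop":
                    start_pos = run[0] if run else None
                else:  # aug_to_stop
                    for p in run:
                        if seq[p - 1 : p + 2] == "ATG":
                            start_pos = p
                            break
                if start_pos is not None:
                    if is_stop:
                        end_pos = pos + 2  # include terminal stop
                        n_coding = (pos - start_pos) // 3
                        annotation = mode
                    else:
                        end_pos = codon_starts[i - 1] + 2
                        n_coding = (end_pos - start_pos + 1) // 3
                        annotation = "open"
                    if n_coding >= min_len:
                        features.append(
                            FrameFeature(
                                kind="orf",
                                region=Region(start_pos, end_pos, frame_anchor=start_pos),
                                frame=frame,
                                annotation=annotation,
                            )
                        )
                run_start_idx = i + 1
            i += 1
    return features


# ---------------------------------------------------------------------------
# Slippery sites and overlap cassettes
# ---------------------------------------------------------------------------


def is_slippery_heptamer(h: str, yyy_allowed: Sequence[str] = DEFAULT_YYY) -> bool:
    """X XXY YYZ test: homopolymeric XXX, YYY in the allowed set, Z != G."""
    if len(h) != 7:
        return False
    return (
        h[0] == h[1] == h[2]
        and h[3] == h[4] == h[5]
        and h[3:6] in yyy_allowed
        and h[6] in "ACT"
    )


def find_slippery(
    record: GenomeRecord,
    orf_frame: Union[int, FrameFeature],
    yyy_allowed: Sequence[str] = DEFAULT_YYY,
) -> list[FrameFeature]:
    """Scan for canonical -1 frameshift heptamers, checking codon phase.

    ``phase_ok`` is True iff the heptamer's first base is the third base of
    a codon of ``orf_frame``, so the 0-frame reads ``.._XXY_YYZ_..`` --
    the phasing printed for the natural cassette ``U_GAU_UUA_AAC_UGA``.
    The annotation renders the heptamer in context (one codon upstream
    through one codon past YYZ) phased by ``orf_frame``.
    """
    frame = orf_frame.frame if isinstance(orf_frame, FrameFeature) else int(orf_frame)
    hits: list[FrameFeature] = []
    seq = record.seq
    for pos in range(1, record.length - 5):
        h = seq[pos - 1 : pos + 6]
        if not is_slippery_heptamer(h, yyy_allowed):
            continue
        phase_ok = codon_phase(pos, frame) == 2
        ctx_start = max(1, pos - 3)
        ctx_end = min(record.length, pos + 9)
        hits.append(
            FrameFeature(
                kind="slippery",
                region=Region(pos, pos + 6),
                frame=frame,
                phase_ok=phase_ok,
                annotation=render_phased(record, ctx_start, ctx_end, frame),
            )
        )
    return hits


def orf_overlap(orfA: FrameFeature, orfB: FrameFeature, record: GenomeRecord) -> FrameFeature:
    """Intersection of two ORFs in different frames.

    The returned feature carries the signed relative frame offset from
    ``orfA`` to ``orfB`` (-1 means ``orfB`` codons start one nucleotide
    5'-ward) and the overlap sequence rendered with ``orfA`` codon phasing.
    An empty intersection yields ``region=None``.
    """
    if orfA.frame == orfB.frame:
        raise ValueError("ORFs are in the same frame; overlap is not frame-relative")
    diff = (orfB.frame - orfA.frame) % 3
    offset = -1 if diff == 2 else +1
    if orfA.region is None or orfB.region is None:
        raise ValueError("both ORFs need regions")
    start = max(orfA.region.start, orfB.region.start)
    end = min(orfA.region.end, orfB.region.end)
    if start > end:
        return FrameFeature(kind="overlap", region=None, frame=orfA.frame, offset=offset)
    return FrameFeature(
        kind="overlap",
        region=Region(start, end),
        frame=orfA.frame,
        offset=offset,
        annotation=render_phased(record, start, end, orfA.frame),
    )


def extend_orf_upstream(record: GenomeRecord, orf: FrameFeature) -> FrameFeature:
    """Include the immediate upstream in-frame bounding stop codon, if any.

    A maximal "stop-codon-to-stop-codon" reading that counts both bounding
    stops is the convention under which the natural ORF1/ORF2 overlap
    comprises the full 13-nt cassette (upstream -1-frame stop through the
    0-frame ORF1 stop).
    """
    if orf.region is None:
        raise ValueError("ORF needs a region")
    start = orf.region.start
    if start - 3 >= 1 and record.seq[start - 4 : start - 1] in STOP_CODONS:
        start -= 3
    return FrameFeature(
        kind="orf",
        region=Region(start, orf.region.end, frame_anchor=start),
        frame=orf.frame,
        annotation=orf.annotation + "+upstream_stop" if start != orf.region.start else orf.annotation,
    )


# ---------------------------------------------------------------------------
# Start-codon context
# ---------------------------------------------------------------------------


def start_context(record: GenomeRecord, aug_position: int) -> StartContext:
    """Kozak-like -3/+4 context of the AUG starting at ``aug_position``."""
    seq = record.seq
    if seq[aug_position - 1 : aug_position + 2] != "ATG":
        raise ValueError(f"no AUG at position {aug_position}")
    minus3 = seq[aug_position - 4] if aug_position >= 4 else None
    plus4 = seq[aug_position + 2] if aug_position + 3 <= record.length else None
    if minus3 is None or plus4 is None:
        call = None  # edge AUG: flagged, not errored
    else:
        call = "strong" if (minus3 in "AG" or plus4 == "G") else "weak"
    return StartContext(
        position=Region(aug_position, aug_position + 2),
        minus3=minus3,
        plus4=plus4,
        call=call,
    )


def sgrna_aug_survey(
    record: GenomeRecord,
    sg_start: int,
    n: int = 3,
    ref_frame: Optional[int] = None,
) -> list[tuple[StartContext, Optional[str]]]:
    """First ``n`` AUGs at or downstream of a putative sgRNA 5' end.

    Each AUG is reported with its context call and, when ``ref_frame`` is
    given, its frame relative to that ORF (``"ORF"`` for in-frame,
    ``"+1"``/``"+2"`` otherwise).  Fewer than ``n`` downstream AUGs is not
    an error; the survey returns what exists.
    """
    if not (1 <= sg_start <= record.length):
        raise ValueError("sg_start outside record")
    out: list[tuple[StartContext, Optional[str]]] = []
    idx = record.seq.find("ATG", sg_start - 1)
    while idx != -1 and len(out) < n:
        pos = idx + 1
        label = None
        if ref_frame is not None:
            rel = (_frame_of(pos) - ref_frame) % 3
            label = {0: "ORF", 1: "+1", 2: "+2"}[rel]
        out.append((start_context(record, pos), label))
        idx = record.seq.find("ATG", idx + 1)
    return out
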