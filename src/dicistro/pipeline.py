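"""Orchestration: per-genome annotation and per-alignment conservation runs.

``annotate_genome`` composes the stages in order -- ORF/slippery scanning,
repeat discovery and terminal-similarity scanning, then product assembly
-- and cross-links them: the phase-correct slippery site in the longest
ORF defines the frameshift cassette, the best terminal match defines the
putative sgRNA 5' end from which the AUG survey and the designated
structural-protein start are taken.  Reports are deterministic for fixed
input and config; every output records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import orfscan, products, repeats, seqio, syncon
from .orfscan import FrameFeature, StartContext
from .products import CleavageScheme, ProteinProduct
from .repeats import RepeatHit, TerminalMatch
from .seqio import GenomeRecord, Gff3Row, Region


@dataclass(frozen=True)
class AnnotateConfig:
    min_orf: int = 100  # codons
    kmin: int = 20
    window: int = 35
    min_identity: float = 0.70
    mask_polya: bool = True
    polya_min_run: int = 10
    aug_survey_n: int = 3
    cleavage_sites: tuple[int, ...] = ()

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    genome_id: str
    genome_length: int
    config_hash: str
    orfs: list[FrameFeature]
    slippery: list[FrameFeature]
    overlap: Optional[FrameFeature]
    repeat_hits: list[RepeatHit]
    repeat_chance: list[float]
    terminal_matches: list[TerminalMatch]
    sg_start: Optional[int]
    aug_survey: list[tuple[StartContext, Optional[str]]]
    products: list[ProteinProduct]

    # -- serialization ------------------------------------------------------

    def as_dict(self) -> dict:
        def region(r: Optional[Region]) -> Optional[list[int]]:
            return None if r is None else [r.start, r.end]

        return {
            "genome_id": self.genome_id,
            "genome_length": self.genome_length,
            "config_hash": self.config_hash,
            "orfs": [
                {
                    "region": region(f.region),
                    "frame": f.frame,
                    "annotation": f.annotation,
                }
                for f in self.orfs
            ],
            "slippery": [
                {
                    "region": region(f.region),
                    "frame": f.frame,
                    "phase_ok": f.phase_ok,
                    "annotation": f.annotation,
                }
                for f in self.slippery
            ],
            "overlap": None
            if self.overlap is None
            else {
                "region": region(self.overlap.region),
                "offset": self.overlap.offset,
                "annotation": self.overlap.annotation,
            },
            "repeats": [
                {
                    "a": region(h.seq_a),
                    "b": region(h.seq_b),
                    "length": h.length,
                    "chance_probability": p,
                }
                for h, p in zip(self.repeat_hits, self.repeat_chance)
            ],
            "terminal_matches": [
                {
                    "internal_start": m.internal_start,
                    "window": m.window,
                    "identity": m.identity,
                    "implied_sg_length": m.implied_sg_length,
                }
                for m in self.terminal_matches
            ],
            "sg_start": self.sg_start,
            "aug_survey": [
                {
                    "position": region(ctx.position),
                    "minus3": ctx.minus3,
                    "plus4": ctx.plus4,
                    "call": ctx.call,
                    "frame_vs_orf1": label,
                }
                for ctx, label in self.aug_survey
            ],
            "products": [
                {
                    "name": pr.name,
                    "segments": [
                        {"region": region(r), "frame": fr} for r, fr in pr.segments
                    ],
                    "length_aa": pr.length_aa,
                    "mass_kda": round(pr.mass_kda, 1),
                }
                for pr in self.products
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)

    def gff3_rows(self) -> list[Gff3Row]:
        rows: list[Gff3Row] = []
        sid = self.genome_id
        for i, f in enumerate(self.orfs):
            rows.append(
                Gff3Row(
                    seqid=sid, type="ORF", start=f.region.start, end=f.region.end,
                    phase=f.frame, attributes={"ID": f"orf{i}", "mode": f.annotation},
                )
            )
        for i, f in enumerate(self.slippery):
            rows.append(
                Gff3Row(
                    seqid=sid, type="slippery_sequence",
                    start=f.region.start, end=f.region.end, phase=f.frame,
                    attributes={"ID": f"slip{i}", "phase_ok": str(f.phase_ok),
                                "cassette": f.annotation},
                )
            )
        if self.overlap is not None and self.overlap.region is not None:
            rows.append(
                Gff3Row(
                    seqid=sid, type="ORF_overlap",
                    start=self.overlap.region.start, end=self.overlap.region.end,
                    phase=self.overlap.frame,
                    attributes={"offset": str(self.overlap.offset),
                                "rendering": self.overlap.annotation},
                )
            )
        for ctx, label in self.aug_survey:
            rows.append(
                Gff3Row(
                    seqid=sid, type="start_codon",
                    start=ctx.position.start, end=ctx.position.end,
                    attributes={"context": str(ctx.call),
                                "frame_vs_orf1": str(label)},
                )
            )
        return rows

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        note = f"config_hash={self.config_hash}"
        self.to_json(outdir / "report.json")
        seqio.write_gff3(outdir / "features.gff3", self.gff3_rows(), [note])
        seqio.write_tsv(
            outdir / "repeats.tsv",
            [
                (h.seq_a.start, h.seq_a.end, h.seq_b.start, h.seq_b.end,
                 h.length, h.mismatches, f"{h.identity:.4f}", f"{p:.3g}")
                for h, p in zip(self.repeat_hits, self.repeat_chance)
            ],
            ["start_a", "end_a", "start_b", "end_b", "length", "mismatches",
             "identity", "chance_probability"],
            [note],
        )
        seqio.write_tsv(
            outdir / "terminal_matches.tsv",
            [
                (m.internal_start, m.window, f"{m.identity:.4f}", m.implied_sg_length)
                for m in self.terminal_matches
            ],
            ["internal_start", "window", "identity", "implied_sg_length"],
            [note],
        )
        seqio.write_tsv(
            outdir / "products.tsv",
            [
                (pr.name,
                 ";".join(f"{r.start}-{r.end}:{fr}" for r, fr in pr.segments),
                 pr.length_aa, f"{pr.mass_kda:.1f}")
                for pr in self.products
            ],
            ["name", "segments", "length_aa", "mass_kda"],
            [note],
        )
        with open(outdir / "peptides.fasta", "w") as fh:
            for pr in self.products:
                fh.write(f">{pr.name}\n")
                for i in range(0, len(pr.sequence), 60):
                    fh.write(pr.sequence[i : i + 60] + "\n")


def annotate_genome(
    source: Union[GenomeRecord, str, Path],
    config: AnnotateConfig = AnnotateConfig(),
) -> AnalysisReport:
    """Run the full per-genome analysis; see the module docstring."""
    if isinstance(source, (str, Path)):
        recs = seqio.read_fasta(source)
        if len(recs) != 1:
            raise ValueError("annotate_genome expects a single-genome FASTA")
        record = recs[0]
    else:
        record = source

    orfs = orfscan.find_orfs(record, mode="stop_to_stop", min_len=config.min_orf)
    slippery: list[FrameFeature] = []
    overlap: Optional[FrameFeature] = None
    orf1: Optional[FrameFeature] = None
    if orfs:
        orf1 = max(orfs, key=lambda f: f.region.length)
        slippery = [
            s
            for s in orfscan.find_slippery(record, orf1.frame)
            if s.phase_ok
            and orf1.region.start <= s.region.start <= orf1.region.end
        ]
        if slippery:
            # the -1-frame stop-to-stop ORF containing the frameshifted reading
            shift_frame = (orf1.frame + 2) % 3
            q = slippery[0].region.start + 3
            candidates = [
                f
                for f in orfscan.find_orfs(record, mode="stop_to_stop", min_len=1,
                                           frames=(shift_frame,))
                if f.region.start <= q <= f.region.end
            ]
            if candidates:
                orf2 = orfscan.extend_orf_upstream(record, candidates[0])
                overlap = orfscan.orf_overlap(orf1, orf2, record)

    repeat_hits = repeats.find_exact_repeats(
        record, config.kmin, mask_polya=config.mask_polya,
        polya_min_run=config.polya_min_run,
    )
    repeat_chance = [
        repeats.repeat_chance_probability(record.length, h.length)
        for h in repeat_hits
    ]
    terminal_matches = repeats.terminal_similarity_scan(
        record, config.window, config.min_identity
    )
    sg_start = None
    if terminal_matches:
        best = max(terminal_matches, key=lambda m: (m.identity, -m.internal_start))
        sg_start = best.internal_start

    aug_survey: list[tuple[StartContext, Optional[str]]] = []
    if sg_start is not None and orf1 is not None:
        aug_survey = orfscan.sgrna_aug_survey(
            record, sg_start, n=config.aug_survey_n, ref_frame=orf1.frame
        )

    prods: list[ProteinProduct] = []
    if orf1 is not None:
        prods = products.product_catalog(
            record,
            orfs,
            sg_start=sg_start,
            cleavage=CleavageScheme(config.cleavage_sites)
            if config.cleavage_sites
            else None,
        )

    return AnalysisReport(
        genome_id=record.id,
        genome_length=record.length,
        config_hash=config.hash(),
        orfs=orfs,
        slippery=slippery,
        overlap=overlap,
        repeat_hits=repeat_hits,
        repeat_chance=repeat_chance,
        terminal_matches=terminal_matches,
        sg_start=sg_start,
        aug_survey=aug_survey,
        products=prods,
    )


@dataclass(frozen=True)
class SynconConfig:
    window: int = 25
    step: int = 1
    reference_index: int = 0
    frame_anchor: int = 1

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def compare_alignment(
    source: Union[syncon.CodonAlignment, str, Path],
    config: SynconConfig = SynconConfig(),
) -> syncon.ConservationProfile:
    """Synonymous-site conservation profile of an aligned-FASTA CDS set."""
    if isinstance(source, (str, Path)):
        alignment = syncon.read_alignment_fasta(
            source,
            reference_index=config.reference_index,
            frame_anchor=config.frame_anchor,
        )
    else:
        alignment = source
    return syncon.profile_alignment(
        alignment, window_size=config.window, step=config.step
    )


def write_profile(
    profile: syncon.ConservationProfile, path: str | Path, config: SynconConfig
) -> None:
    df = profile.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.hash()} p_hat={profile.p_hat:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)
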