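"""Translation, transframe fusion assembly, average masses and cleavage.

The protein catalog of an APV/SINV-3-like dicistronic genome comprises a
non-frameshift product (leader + capsid, terminating at the ORF1 stop), a
transframe product made when the ribosome slips -1 at a slippery heptamer
and continues into ORF2 (leader + capsid + frameshift domain + VP2-style
precursor), and proteolytic fragments of those precursors.

Frameshift junction convention (tandem-slippage re-pairing): the 0-frame
is translated through the XXY codon of the X_XXY_YYZ heptamer, then
translation resumes in the -1 frame at the YYY codon, re-reading one
nucleotide.  Alternative junction conventions change the fusion by at
most one residue.

Masses are average (not monoisotopic), computed as the sum of residue
masses plus one water, with the N-terminal methionine retained and no
post-translational modifications modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from Bio.Data.IUPACData import protein_weights

from .codons import STOP_CODONS, amino_acid
from .orfscan import FrameFeature, codon_phase, find_slippery
from .seqio import GenomeRecord, Region, subseq

WATER_AVG = 18.0153  # Da, average mass of H2O
STANDARD_AA = frozenset(protein_weights)  # 20 one-letter residues


def average_mass(peptide: str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water.

    The empty peptide returns the mass of water.  Nonstandard residues
    raise ``ValueError``.
    """
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard residues: {sorted(bad)}")
    # protein_weights lists free amino-acid masses; condensation removes
    # one water per peptide bond.
    return sum(protein_weights[a] for a in peptide) - (len(peptide) - 1) * WATER_AVG


def translate(record: GenomeRecord, region: Region, frame: Optional[int] = None) -> str:
    """Standard-code translation of ``region``; terminal stop dropped.

    ``region`` must be codon-aligned (length divisible by 3, starting on a
    codon boundary of ``frame`` when given).  An internal stop raises.
    """
    region.check_within(record)
    if frame is not None and codon_phase(region.start, frame) != 0:
        raise ValueError("region start is not a codon boundary of the given frame")
    s = subseq(record, region)
    if len(s) % 3 != 0:
        raise ValueError(f"region length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for idx, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {idx}")
        aas.append(amino_acid(codon))
    return "".join(aas)


@dataclass(frozen=True)
class ProteinProduct:
    """A (possibly transframe) polypeptide with its coding segments.

    ``segments`` are coding-only regions (stop codons excluded), each with
    its reading frame; their codon counts sum to the sequence length.
    """

    name: str
    segments: tuple[tuple[Region, int], ...]
    sequence: str
    mass_da: float

    @property
    def mass_kda(self) -> float:
        return self.mass_da / 1000.0

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageScheme:
    """Ordered inter-residue cut positions (cut after residue i), with labels."""

    sites: tuple[int, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if list(self.sites) != sorted(set(self.sites)):
            raise ValueError("cleavage sites must be strictly increasing")


def orf_product(
    record: GenomeRecord,
    orf: FrameFeature,
    name: str = "product",
    start: Optional[int] = None,
) -> ProteinProduct:
    """Non-frameshift translation product of an ORF from a designated start."""
    if orf.region is None:
        raise ValueError("ORF needs a region")
    start = start if start is not None else orf.region.start
    if codon_phase(start, orf.frame) != 0:
        raise ValueError("designated start is not a codon boundary of the ORF frame")
    coding_end = orf.region.end
    if subseq(record, Region(coding_end - 2, coding_end)) in STOP_CODONS:
        coding_end -= 3
    region = Region(start, coding_end, frame_anchor=start)
    seq = translate(record, region, frame=orf.frame)
    return ProteinProduct(
        name=name,
        segments=((region, orf.frame),),
        sequence=seq,
        mass_da=average_mass(seq),
    )


def _next_inframe_stop(record: GenomeRecord, start: int) -> Optional[int]:
    """1-based start of the first stop codon at ``start``, ``start+3``, ..."""
    seq = record.seq
    pos = start
    while pos + 2 <= record.length:
        if seq[pos - 1 : pos + 2] in STOP_CODONS:
            return pos
        pos += 3
    return None


def transframe_product(
    record: GenomeRecord,
    orf1: FrameFeature,
    slippery_feature: FrameFeature,
    name: str = "transframe",
    start: Optional[int] = None,
) -> ProteinProduct:
    """Transframe fusion across a -1 frameshift cassette.

    Segment 1: ORF1-frame codons from the designated start through the XXY
    codon of the heptamer.  Segment 2: -1-frame codons from the YYY codon
    to the next -1-frame stop (error when no such stop exists).
    """
    if orf1.region is None or slippery_feature.region is None:
        raise ValueError("features need regions")
    if not slippery_feature.phase_ok:
        raise ValueError("slippery site is not in phase with the ORF")
    start = start if start is not None else orf1.region.start
    p = slippery_feature.region.start  # first heptamer base, codon position 3
    if codon_phase(start, orf1.frame) != 0:
        raise ValueError("designated start is not a codon boundary of ORF1's frame")
    if not (orf1.region.start <= p <= orf1.region.end):
        raise ValueError("slippery site outside ORF1")

    seg1 = Region(start, p + 3, frame_anchor=start)  # ends with the XXY codon
    shift_frame = (orf1.frame + 2) % 3  # -1 frame
    q = p + 3  # YYY codon start in the -1 frame
    stop = _next_inframe_stop(record, q)
    if stop is None:
        raise ValueError("no in-frame stop downstream of the frameshift site")
    if stop == q:
        raise ValueError("frameshift lands directly on a stop codon")
    seg2 = Region(q, stop - 1, frame_anchor=q)

    seq = translate(record, seg1, frame=orf1.frame) + translate(record, seg2, frame=shift_frame)
    return ProteinProduct(
        name=name,
        segments=((seg1, orf1.frame), (seg2, shift_frame)),
        sequence=seq,
        mass_da=average_mass(seq),
    )


def _split_segments(
    segments: Sequence[tuple[Region, int]], res_start: int, res_end: int
) -> tuple[tuple[Region, int], ...]:
    """Sub-segments coding for residues ``res_start..res_end`` (1-based incl.)."""
    out: list[tuple[Region, int]] = []
    offset = 0  # residues before the current segment
    for region, frame in segments:
        n_codons = region.length // 3
        lo = max(res_start, offset + 1)
        hi = min(res_end, offset + n_codons)
        if lo <= hi:
            sub_start = region.start + 3 * (lo - offset - 1)
            sub_end = region.start + 3 * (hi - offset) - 1
            out.append((Region(sub_start, sub_end, frame_anchor=sub_start), frame))
        offset += n_codons
    return tuple(out)


def cleave(
    product: ProteinProduct, scheme: Union[CleavageScheme, Sequence[int]]
) -> list[ProteinProduct]:
    """Cut a precursor at inter-residue sites; fragments partition the sequence.

    Each cut adds one water, so fragment masses sum to the precursor mass
    plus ``n_cuts`` waters.
    """
    if not isinstance(scheme, CleavageScheme):
        scheme = CleavageScheme(sites=tuple(scheme))
    n = len(product.sequence)
    for site in scheme.sites:
        if not (1 <= site <= n - 1):
            raise ValueError(f"cleavage site {site} not interior to 1..{n - 1}")
    bounds = [0, *scheme.sites, n]
    fragments: list[ProteinProduct] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i] + 1, bounds[i + 1]
        frag_seq = product.sequence[a - 1 : b]
        if i < len(scheme.labels):
            label = scheme.labels[i]
        else:
            label = f"{product.name}/frag{i + 1}"
        fragments.append(
            ProteinProduct(
                name=label,
                segments=_split_segments(product.segments, a, b),
                sequence=frag_seq,
                mass_da=average_mass(frag_seq),
            )
        )
    return fragments


def cleavage_motif(product: ProteinProduct, site: int) -> str:
    """Annotation of the residues flanking a cut, e.g. ``Q|M``."""
    return f"{product.sequence[site - 1]}|{product.sequence[site]}"


def product_catalog(
    record: GenomeRecord,
    orf_features: Sequence[FrameFeature],
    sg_start: Optional[int] = None,
    cleavage: Optional[Union[CleavageScheme, Sequence[int]]] = None,
) -> list[ProteinProduct]:
    """Product classes of a dicistronic genome, from annotated features.

    Emits the non-frameshift product (designated start through the ORF1
    stop), the transframe precursor when a phase-correct slippery site
    lies in ORF1, and -- when a cleavage scheme is supplied -- the
    fragments of the transframe precursor.  The designated start is the
    first ORF1-frame AUG at or downstream of ``sg_start`` (or the ORF
    start when no sgRNA start is given).
    """
    orfs = [f for f in orf_features if f.kind == "orf" and f.region is not None]
    if not orfs:
        return []
    orf1 = max(orfs, key=lambda f: f.region.length)

    scan_from = sg_start if sg_start is not None else orf1.region.start
    start = None
    pos = record.seq.find("ATG", scan_from - 1)
    while pos != -1:
        p = pos + 1
        if codon_phase(p, orf1.frame) == 0 and orf1.region.start <= p <= orf1.region.end:
            start = p
            break
        pos = record.seq.find("ATG", pos + 1)
    if start is None:
        return []

    catalog = [orf_product(record, orf1, name="nonframeshift", start=start)]

    slips = [
        s
        for s in find_slippery(record, orf1.frame)
        if s.phase_ok and orf1.region.start <= s.region.start <= orf1.region.end
    ]
    if slips:
        tf = transframe_product(record, orf1, slips[0], name="transframe", start=start)
        catalog.append(tf)
        if cleavage is not None:
            catalog.extend(cleave(tf, cleavage))
    return catalog
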