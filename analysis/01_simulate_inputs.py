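#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under scratch/fixtures/ (regenerable bulk data; the durable
analysis tables live under results/):

* 10 toy dicistronic genomes (FASTA + truth JSON) with the SINV-3-like
  architecture (5' UTR repeat, -1 frameshift cassette, internal 5'-terminal
  duplicate, poly(A) tail);
* 5 neutral diverged CDS pairs and 5 planted-window pairs (aligned FASTA +
  event-log truth JSON) at the divergence used throughout.

The large replicate sets for calibration/power (200 and 50 pairs) are
simulated in memory by 02_syncon_calibration.py rather than written out.
"""

from pathlib import Path

from dicistro import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "scratch" / "fixtures"


def main() -> None:
    run = sd.BatchSpec(
        n_neutral_pairs=5,
        n_planted_pairs=5,
        n_toy_genomes=10,
        pair_template=sd.EvolvedPairSpec(n_codons=600, syn_rate=0.20, nonsyn_rate=0.03),
        planted_window=(276, 325, 0.0),
        toy_template=sd.ToyGenomeSpec(),
        master_seed=1,
    )
    outdir = sd.batch(OUT, run)
    files = sorted(p.name for p in outdir.iterdir())
    print(f"wrote {len(files)} fixture files to {outdir}")
    print("  " + "\n  ".join(files[:6]) + "\n  ...")


if __name__ == "__main__":
    main()
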