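#!/usr/bin/env python
"""Generate the synthetic study inputs every downstream step consumes.

Emits, under results/inputs/ (each with a .truth.json sidecar recording
the planted ground truth):

* ``delta_full.fasta``   — full-length δ-like sequence: 62-residue coiled
  coil, 5 strict bracelet repeats, 43-residue internal spacer, 11 relaxed
  repeats, 97-residue tail (346 aa).
* ``delta_1_101.fasta``  — the crystal-fragment analogue (coiled coil +
  5 strict repeats, 102 aa).
* ``pentamer.pdb``       — idealized C5 pentamer, 5 repeats, rise 15 Å,
  strand tilt 45°, strand radius 6 Å, loop radius 9.5 Å, noise σ=0.2 Å.
* ``mass_peaks.tsv``     — Le Blanc-like pentamer peak plus the two
  minor adduct peaks (−526.9 / +294.0 Da).
* ``gel_intensities.tsv``— three densitometry replicates around a true
  value of 1.1 fibers per capsid, 30% CV.
* ``em_lengths.tsv``     — 200 fiber lengths ~ N(419, 36²) Å.
"""

import argparse
from pathlib import Path

import pandas as pd

from deltafiber import io, synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rec, truth = sd.gen_repeat_sequence(
        5, 11, {"cc": 62, "spacer": 43, "tail": 97}, seed=seed)
    io.write_fasta([rec], OUT / "delta_full.fasta")
    io.write_json(truth, OUT / "delta_full.fasta.truth.json")
    print(f"delta_full.fasta: {truth['length']} aa, "
          f"{len(truth['strict_starts'])} strict + "
          f"{len(truth['relaxed_starts'])} relaxed repeats planted")

    rec, truth = sd.gen_repeat_sequence(5, 0, {"cc": 62, "tail": 0}, seed=seed)
    io.write_fasta([rec], OUT / "delta_1_101.fasta")
    io.write_json(truth, OUT / "delta_1_101.fasta.truth.json")
    print(f"delta_1_101.fasta: {truth['length']} aa, strict repeats at "
          f"{truth['strict_starts']}")

    model, truth = sd.gen_pentamer_coords(
        5, rise=15, tilt=45, strand_radius=6, loop_radius=9.5,
        noise_sd=0.2, seed=seed)
    sd.write_pentamer_pdb(model, OUT / "pentamer.pdb")
    io.write_json(truth, OUT / "pentamer.pdb.truth.json")
    print("pentamer.pdb: 5 chains x 40 residues, planted rise 15 A, tilt 45 deg")

    peaks, truth = sd.gen_mass_peaks(43512.2, 5, adduct_offsets=(-526.9, 294.0),
                                     seed=seed)
    pd.DataFrame({"mass_da": peaks}).to_csv(OUT / "mass_peaks.tsv", sep="\t",
                                            index=False)
    io.write_json(truth, OUT / "mass_peaks.tsv.truth.json")
    print(f"mass_peaks.tsv: main peak {peaks[0]:.1f} Da + 2 minor peaks")

    reps, truth = sd.gen_gel_intensities(1.1, 0.3, 3, mw_cp=36, mw_cpdelta=72,
                                         seed=seed)
    rows = [(i, band, val) for i, (cp, cpd) in enumerate(reps, 1)
            for band, val in (("cp", cp), ("cpdelta", cpd))]
    pd.DataFrame(rows, columns=["replicate", "band", "intensity"]).to_csv(
        OUT / "gel_intensities.tsv", sep="\t", index=False)
    io.write_json(truth, OUT / "gel_intensities.tsv.truth.json")
    print("gel_intensities.tsv: 3 replicates, true value 1.1 fibers/capsid")

    lengths, truth = sd.gen_em_lengths(419, 36, 200, seed=seed)
    pd.DataFrame({"length_A": lengths}).to_csv(OUT / "em_lengths.tsv",
                                               sep="\t", index=False)
    io.write_json(truth, OUT / "em_lengths.tsv.truth.json")
    print(f"em_lengths.tsv: {len(lengths)} lengths, sample mean "
          f"{lengths.mean():.1f} A")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
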