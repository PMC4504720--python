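"""Generate the synthetic study datasets.

Writes to results/data/:
  - FTL tetrad tables for two genotype scenarios on the I5c/I5d-like
    geometry (6.1 + 5.5 cM): a strongly interfering "wild-type-like"
    bivalent (shape 7) and a weakly interfering "mutant-like" one
    (shape 1.2);
  - matching per-cell chiasma-count samples (obligate crossover for the
    wild-type-like scenario, not for the mutant-like one, whose
    crossover-less bivalents yield univalent pairs);
  - paired synapsed/unsynapsed intensity tables with bead calibration
    (67% true reduction vs no reduction).

All downstream drivers read these files, so the whole analysis is
reproducible from this script's seed.
"""

import pathlib

import numpy as np

from tetracross.io import write_chiasma_table, write_tetrad_table
from tetracross.simulate import (
    SimConfig,
    simulate_chiasma_counts,
    simulate_ftl_tetrads,
    simulate_intensity_dataset,
)

SEED = 20_260_919
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"

SCENARIOS = {
    # obligate_co None = context default: off for FTL tetrads, on for
    # whole-genome chiasma counts
    "wildtype_like": dict(shape=2.0, obligate=None, lengths=(120.0, 85.0, 95.0, 90.0, 90.0)),
    # reduced interference, no obligate CO, and ~30% fewer crossovers
    # (chiasma mean ~6.9); crossover-less bivalents become univalent pairs
    "mutant_like": dict(shape=1.2, obligate=False, lengths=(86.0, 61.0, 68.0, 65.0, 65.0)),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (name, pars) in enumerate(SCENARIOS.items()):
        cfg = SimConfig(
            marker_positions_cM=(0.0, 6.1, 11.6),
            interference_shape=pars["shape"],
            n_tetrads=5000,
            n_cells=50,
            obligate_co=pars["obligate"],
            bivalent_lengths_cM=pars["lengths"],
            seed=SEED + i,
        )
        tet = simulate_ftl_tetrads(cfg)
        write_tetrad_table(tet, OUT / f"tetrads_{name}.csv")
        chi = simulate_chiasma_counts(cfg)
        chi.genotype = name
        write_chiasma_table(chi, OUT / f"chiasma_{name}.csv")
        print(f"{name}: {cfg.n_tetrads} tetrads, {cfg.n_cells} cells "
              f"(shape {pars['shape']}, mean chiasmata {chi.counts.mean():.2f})")

    rng = np.random.default_rng(SEED + 10)
    simulate_intensity_dataset(23, 0.67, noise=0.1, rng=rng).to_csv(
        OUT / "intensity_wildtype_like.csv", index=False
    )
    simulate_intensity_dataset(22, 0.0, noise=0.1, rng=rng).to_csv(
        OUT / "intensity_mutant_like.csv", index=False
    )
    print(f"intensity tables written (23 pairs at 67% reduction; 22 pairs at 0%)")
    print(f"datasets under {OUT}")


if __name__ == "__main__":
    main()
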