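"""Replicated calibration and recovery studies.

Runs the package's evidence base: Perkins map-distance recovery at the
I5c/I5d-like geometry, the interference-ratio/CoC no-interference null
and monotone response to interference strength, Poisson GOF type-I
error and power, and intensity-reduction recovery. Writes
results/calibration.json. Expect a few minutes of runtime.
"""

import json
import pathlib

from tetracross.experiments import (
    gof_calibration_and_power,
    intensity_recovery,
    interference_calibration,
    perkins_recovery,
)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 20_260_919


def main() -> None:
    out = {}
    out["perkins_recovery"] = r = perkins_recovery(seed=SEED)
    print(f"Perkins recovery: {r['percent_within_3se']:.0f}% of replicates within 3 SE "
          f"(means {r['mean_interval1_cM']:.2f}/{r['mean_interval2_cM']:.2f} cM "
          f"vs truth {r['true_interval1_cM']}/{r['true_interval2_cM']})")
    out["interference"] = r = interference_calibration(seed=SEED + 1)
    print(f"IR null {r['ir_null']:.3f}, CoC null {r['coc_null']:.3f}; strong interference "
          f"IR {r['ir_strong_mean']:.3f}, CoC {r['coc_strong_mean']:.3f} "
          f"({r['n_strong_below_null_ir']}/{r['n_reps_strong']} IR and "
          f"{r['n_strong_below_null_coc']}/{r['n_reps_strong']} CoC replicates below the null)")
    out["gof"] = r = gof_calibration_and_power(seed=SEED + 2)
    print(f"GOF type-I error {r['type1_error_rate']:.3f} at alpha {r['alpha']}; "
          f"power vs obligate strongly interfering counts {r['power_strong_interference']:.2f}")
    out["intensity"] = r = intensity_recovery(seed=SEED + 3)
    print(f"intensity recovery: mean {r['mean_reduction_pct']:.1f}% (truth "
          f"{r['true_reduction_pct']:.0f}%), P<0.001 in {100 * r['frac_p_below_0.001']:.0f}% "
          f"of replicates; null rejection rate {r['null_rejection_rate']:.3f}")
    ROOT.mkdir(exist_ok=True)
    (ROOT / "calibration.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {ROOT / 'calibration.json'}")


if __name__ == "__main__":
    main()
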