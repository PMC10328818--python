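"""Regenerate the frozen Monte-Carlo reference for planted-tier recovery.

Runs expected_r2 on the canonical tier experiment (four balanced binary
covariates at tiers none/small/medium/large on the same stable taxa) at
n=300 families over a fixed seed grid, and freezes the per-(variable,
timepoint) mean R-squared together with a 4-standard-deviation Monte-Carlo
tolerance band into tests/data/expected_r2_reference.json.

Usage:  python scripts/make_fixtures.py
"""

import json
from pathlib import Path

from permapart.simulate import GeneratorConfig, expected_r2, tier_truth

SEED = 101
REPLICATES = 5
N_FAMILIES = 300
TIMEPOINTS = ("3w", "3m", "12m")


def main() -> None:
    truth, names = tier_truth()
    cfg = GeneratorConfig(seed=SEED, timepoints=TIMEPOINTS, extra_binary_vars=names)
    df = expected_r2(truth, cfg, n_mc=N_FAMILIES, replicates=REPLICATES)
    records = {}
    for _, row in df.iterrows():
        key = f"{row['variable']}@{row['timepoint']}"
        sd = float(row["R2_sd"])
        records[key] = {
            "R2": float(row["R2"]),
            "R2_sd": sd,
            "tolerance": max(4.0 * sd, 0.004),
            "n_samples": float(row["n"]),
        }
    out = {
        "seed": SEED,
        "replicates": REPLICATES,
        "n_families": N_FAMILIES,
        "timepoints": list(TIMEPOINTS),
        "values": records,
    }
    path = Path(__file__).resolve().parent.parent / "tests" / "data" / "expected_r2_reference.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=1))
    print(f"wrote {path}")
    for k, v in records.items():
        print(f"  {k}: R2={v['R2']:.4f} +- {v['tolerance']:.4f}")


if __name__ == "__main__":
    main()
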