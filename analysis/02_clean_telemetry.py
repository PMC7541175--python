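"""Apply the three GPS cleaning filters to the simulated telemetry and
report what each removed.

Filters (all strict inequalities): elevation residual vs the DEM above
25 m; movement speed above 300 m/hr (with a mislocated-point rule that
never drags innocent neighbours out); fast (>100 m/hr both legs) sharp-turn
(>300 deg on the mod-360 metric) spikes; and the full-season gate.

Run after 01:  python analysis/02_clean_telemetry.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from pathsel.cleaning import CleaningConfig, clean_telemetry
from pathsel.grid import read_ascii_grid
from pathsel.io import read_telemetry_csv, write_telemetry_csv

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    fixes = read_telemetry_csv(SCRATCH / "telemetry.csv")
    dem = read_ascii_grid(SCRATCH / "dem.asc")
    cfg = CleaningConfig(season=(5, 6))  # simulated season is May-June
    kept, report = clean_telemetry(fixes, dem, cfg)
    write_telemetry_csv(kept, SCRATCH / "telemetry_clean.csv")
    counts = report["reason"].value_counts() if len(report) else pd.Series(dtype=int)
    tab = pd.DataFrame(
        {
            "stage": ["input fixes", "kept"] + [f"removed: {r}" for r in counts.index],
            "n": [len(fixes), len(kept)] + counts.tolist(),
        }
    )
    tab.to_csv(RESULTS / "02_cleaning_summary.csv", index=False)
    print(tab.to_string(index=False))
    print("cleaned telemetry written to scratch/analysis/telemetry_clean.csv")


if __name__ == "__main__":
    main()
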