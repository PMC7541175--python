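"""Predict the landscape movement-quality surface from the fitted model,
classify it into the 10-quantile Movement Quality Index and Fisher-break
display classes, and extract contiguous high-quality corridor patches.

Barrier distance covariates (fence, flood control, rail) are held at the
far log-flatten plateau so barrier-following does not masquerade as good
movement habitat.

Run after 04:  python analysis/05_predict_movement_quality.py [seed]
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from pathsel.grid import read_ascii_grid, write_ascii_grid
from pathsel.model import FittedModel
from pathsel.pipeline import COVARIATE_NAMES
from pathsel.surface import PredictionConfig, corridor_patches, predict_surface

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    d = json.loads((SCRATCH / "fit.json").read_text())
    fm = FittedModel(
        terms=d["terms"], beta=np.array(d["beta"]), se=np.array(d["se"]),
        vcov=np.zeros((len(d["beta"]),) * 2), loglik=d["loglik"], converged=d["converged"],
        n_strata_used=d["n_strata_used"], n_strata_total=d["n_strata_total"],
    )
    transform = {k: tuple(v) for k, v in d["standardization"].items()}
    grids = {
        n: read_ascii_grid(SCRATCH / f"{n}.asc")
        for n in COVARIATE_NAMES
        if (SCRATCH / f"{n}.asc").exists()
    }
    cfg = PredictionConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surf = predict_surface(fm, grids, transform, cfg)
    write_ascii_grid(surf.mqi, SCRATCH / "mqi.asc")
    write_ascii_grid(surf.linear_predictor, SCRATCH / "linear_predictor.asc")
    patches = corridor_patches(surf.mqi, min_class=9)
    patches.sort_values("area_ha", ascending=False).to_csv(
        RESULTS / "05_corridor_patches.csv", index=False
    )
    print(f"MQI surface: classes 1..{cfg.n_quantiles}; "
          f"{int(np.nansum(surf.mqi.values >= 9))} cells in the top two classes")
    if len(patches):
        top = patches.sort_values("area_ha", ascending=False).iloc[0]
        print(
            "largest top-quality patch: "
            f"{top['area_ha']:.1f} ha, bbox {top['bbox_length_m']:.0f} m long, "
            f"min width {top['min_width_m']:.0f} m"
        )
    print("surfaces in scratch/analysis/, patch table in results/05_corridor_patches.csv")


if __name__ == "__main__":
    main()
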