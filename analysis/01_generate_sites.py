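"""Generate the three synthetic study areas and their sparse observations.

Writes each template's site configuration (YAML), the fine-resolution
truth series, and noisy head/concentration observations under
results/sites/.
"""

import sys
from pathlib import Path

import pandas as pd

from aquarecon.config import save_config
from aquarecon.synthetic import TEMPLATES, make_truth, sample_observations

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11
OUT = Path("results/sites")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for template in TEMPLATES:
        truth = make_truth(template, "small", seed=SEED)
        tdir = OUT / template
        tdir.mkdir(exist_ok=True)
        save_config(truth.site, tdir / "site.yaml", truth.run)
        for name, series in truth.true_wtp_series.items():
            pd.DataFrame(
                {"month": [str(m) for m in series.months()], "conc_ugL": series.values}
            ).to_csv(tdir / f"truth_wtp_{name}.csv", index=False)
        obs = sample_observations(truth, n_head=120, seed=SEED)
        pd.DataFrame(
            [(l, r, c, str(m), h) for (l, r, c, m, h) in obs.head_obs],
            columns=["layer", "row", "col", "month", "head_m"],
        ).to_csv(tdir / "head_obs.csv", index=False)
        pd.DataFrame(
            [(w, str(m), v) for (w, m, v) in obs.conc_obs],
            columns=["well", "month", "conc_ugL"],
        ).to_csv(tdir / "conc_obs.csv", index=False)
        print(
            f"{template}: {truth.site.grid.shape} grid, {len(truth.site.wells)} wells, "
            f"{len(obs.head_obs)} head obs, {len(obs.conc_obs)} water-quality samples"
        )


if __name__ == "__main__":
    main()
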