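#!/usr/bin/env python
"""Compare the d' model against the heuristic difficulty models.

The absolute-difference and negative-ratio heuristics are fitted to the
same normalized playtimes; the table reports condition-mean correlation,
trial-level R^2, AIC, and rank agreement with d'.  The negative ratio is a
monotone transform of d' (rank agreement 1 by construction); the absolute
difference genuinely reorders some contrasts.
"""

from pathlib import Path

import pandas as pd

from shakebox.pipeline import run_compare

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    out = run_compare(ROOT / "synthetic" / "trials.csv", ROOT / "analysis")
    table = pd.read_csv(out["comparison"])
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    best = table.loc[table["aic_trial_level"].idxmin(), "model_name"]
    print(f"lowest AIC: {best}")
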