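#!/usr/bin/env python
"""Assemble the final markdown report from the completed stages."""

from pathlib import Path

from shakebox.pipeline import run_report

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    path = run_report(ROOT / "analysis")
    print(f"wrote {path}")
    print(path.read_text())
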