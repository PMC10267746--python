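#!/usr/bin/env python
"""Materialize the synthetic study dataset (4 seat conditions x Exp/Sim).

Writes force CSVs (bundled reference global values), synthetic pressure
maps with condition-matched normal forces and calibration errors, and
pre/post-loading tissue mesh pairs, under results/fixtures/.
"""

from pathlib import Path

from sitpress import pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    study = pipeline.write_fixtures(OUT, seed=0)
    n_files = len(list(OUT.iterdir()))
    print(f"wrote {n_files} fixture files for {len(study.conditions)} conditions -> {OUT}")
    print("study config:", OUT / "study.yaml")


if __name__ == "__main__":
    main()
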