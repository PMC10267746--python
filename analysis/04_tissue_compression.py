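#!/usr/bin/env python
"""Under-ischium tissue compression: ROI thickness and volume reduction.

Runs the ray-cast ROI metrics over the synthetic pre/post mesh pairs (run
01 first).  The finding mirrored here: enabling the tissue-sliding mode
increases the volume reduction R in both the 20 mm and 50 mm cylinders for
every seat condition.
"""

from pathlib import Path

from sitpress import pipeline

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fixtures = BASE / "fixtures"
    if not (fixtures / "study.yaml").exists():
        raise SystemExit("no fixture set found; run analysis/01_generate_fixtures.py first")
    study = pipeline.StudyConfig.from_yaml(fixtures / "study.yaml")
    rep = pipeline.run_tissue(study)
    pipeline.write_report(rep, BASE / "tissue_synthetic.csv", study)
    print("tissue report -> results/tissue_synthetic.csv")
    for tag in ("20", "50"):
        y = rep.loc[("All", "Y"), f"R_{tag}"]
        n = rep.loc[("All", "N"), f"R_{tag}"]
        print(f"  ROI {tag} mm: mean R with sliding {y:.1f} % vs without {n:.1f} %")


if __name__ == "__main__":
    main()
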