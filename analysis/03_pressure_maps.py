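#!/usr/bin/env python
"""Pressure-map validation report: fcorr, CA/PP/MP, fore-aft regions.

The printed-value route recomputes mean pressures as normal force over
contact area (reproducing the campaign's 4.1/4.2/3.9/3.8 kPa seat-pan
values); the synthetic route runs the full map analysis on generated mats,
recovering the injected calibration errors.
"""

from pathlib import Path

from sitpress import pipeline, reference

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    BASE.mkdir(exist_ok=True)
    printed = pipeline.printed_pressure_report()
    pipeline.write_report(printed, BASE / "pressure_printed.csv")
    mp = [printed.loc[(c, "Exp"), "MP_SP"] for c in reference.CONDITIONS]
    print("printed-value pressure report -> results/pressure_printed.csv")
    print("  recomputed Exp seat-pan MP (kPa):", ", ".join(f"{v:.1f}" for v in mp))
    print(f"  backrest contact-area mean error: {printed.loc[('All', 'D%'), 'CA_SB']:.1f} %")

    fixtures = BASE / "fixtures"
    if (fixtures / "study.yaml").exists():
        study = pipeline.StudyConfig.from_yaml(fixtures / "study.yaml")
        rep = pipeline.run_pressure(study)
        pipeline.write_report(rep, BASE / "pressure_synthetic.csv", study)
        print("synthetic-fixture pressure report -> results/pressure_synthetic.csv")
        fc = [rep.loc[(c, "Exp"), "fcorr_SP"] for c in reference.CONDITIONS]
        print("  recovered seat-pan calibration factors:", ", ".join(f"{v:.2f}" for v in fc))
    else:
        print("no fixture set found; run analysis/01_generate_fixtures.py first")


if __name__ == "__main__":
    main()
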