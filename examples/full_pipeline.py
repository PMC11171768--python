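"""The whole screening battery end to end, from CSVs to a report.

Simulates every assay, writes the CSVs through the package's writers,
runs the consolidated pipeline and prints the human-readable report —
the same flow as `ecotoxscreen report` on the command line.
"""

import tempfile
from pathlib import Path

from ecotoxscreen import io as eio
from ecotoxscreen.pipeline import PipelineConfig, render_text_report, run_pipeline
from ecotoxscreen.simulate import (
    GerminationSimConfig,
    HemolysisSimConfig,
    LeakageSimConfig,
    MortalitySimConfig,
    ViabilitySimConfig,
    simulate_germination,
    simulate_hemolysis,
    simulate_leakage,
    simulate_mortality,
    simulate_viability,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    eio.write_germination_csv(simulate_germination(GerminationSimConfig(seed=1)), tmp / "germ.csv")
    eio.write_mortality_csv(simulate_mortality(MortalitySimConfig(seed=1)), tmp / "mort.csv")
    eio.write_hemolysis_csv(simulate_hemolysis(HemolysisSimConfig(seed=1)), tmp / "hemo.csv")
    eio.write_viability_csv(simulate_viability(ViabilitySimConfig(seed=1)), tmp / "viab.csv")
    eio.write_leakage_csv([simulate_leakage(LeakageSimConfig(seed=1))], tmp / "leak.csv")

    config = PipelineConfig(
        germination_csv=str(tmp / "germ.csv"),
        mortality_csv=str(tmp / "mort.csv"),
        hemolysis_csv=str(tmp / "hemo.csv"),
        viability_csv=str(tmp / "viab.csv"),
        leakage_csv=str(tmp / "leak.csv"),
    )
    report = run_pipeline(config, out_dir=tmp / "out")
    print(render_text_report(report))
    print(f"(JSON report also written under {tmp / 'out'})")
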