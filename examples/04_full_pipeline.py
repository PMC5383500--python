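"""Run the complete pipeline and validate predicted establishment.

Simulates an assembly, scans neighborhood sizes for both filters,
predicts each colonist's probability of passing both filters, multiplies
them into an overall establishment probability, and regresses the
observed proportion of established seeds on that prediction.
"""

from pathlib import Path

import darkneighbors as dn

config = dn.RunConfig(
    seed=1,
    outdir="scratch/example_run",
    simulation=dn.SimulationConfig(),
    sizes=("nn", 0.1, 0.3, 0.5, 0.7, 1.0),
    schemes=("none", "all_pairwise"),
)
rundir = dn.run(config)
print((Path(rundir) / "report.txt").read_text())
print("Outputs written to", rundir)
print("predictions.csv has one row per colonist: P(env), P(biotic),")
print("and their product, the predicted establishment probability.")
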