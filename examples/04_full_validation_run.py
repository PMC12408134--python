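"""Run the complete synthetic validation campaign and print its summary.

Simulates three acquisition runs with dual calibration curves, QCs at four
levels, matrix-effect and stability panels, a reinjection replay, the A/B/C
recovery design, and the whole-workflow RED repeatability specimens; then
quantifies, fractionates, and applies every acceptance rule.
"""

from pathlib import Path

from redquant import RunConfig, run_pipeline

config = RunConfig(seed=42, outdir="scratch/example-validation")
result = run_pipeline(config)

print(Path(config.outdir, "summary.txt").read_text())
print("report files:", ", ".join(sorted(p.name for p in result.outputs.values())))
# Inter-run QC accuracies near 100% with CVs of a few percent, workflow
# totals within +/-15% of the 88 / 1742.5 ng/mL spikes, and clean
# carry-over/selectivity checks mean the simulated method passes validation.
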