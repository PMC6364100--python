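"""End-to-end content survey of four simulated *D. chrysotoxum* samples.

The packaged per-sample contents parameterise the simulator; the pipeline
then re-measures every compound from the raw runs (screen -> calibrate ->
quantify) and reports the content table with its Average row, using the
survey's display conventions: truncation to three significant digits and
an em dash for compounds below quantification (coumarin is absent from
every sample).
"""

import math
import warnings
from pathlib import Path

import phenoscreen as ps

df = ps.load_sample_contents()
samples = {str(i): {c: float(v) for c, v in row.items() if not math.isnan(v)}
           for i, row in df.iterrows()}

out = Path("scratch/example_report")
cfg = ps.PipelineConfig(samples=samples, noise_level=0.0, seed=1, out_dir=out)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = ps.run_pipeline(cfg)

print(result.content_table.render())
print(f"\nreport tables written to {out}/")
# The Average row matches the published survey: erianin dominates at
# ~425 mg/kg, the four major phenols (erianin, chrysotobibenzyl,
# confusarin, moscatilin) all average above 200 mg/kg, and coumarin was
# not found in any sample.
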