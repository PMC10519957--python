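"""One-command end-to-end study: screening table, formulation arithmetic,
toy trajectory and full analysis, written to results/demo/.

The report is a pure function of the seed: rerunning with the same seed
reproduces report.json byte for byte.
"""

from assdkit.pipeline import demo_end_to_end

report = demo_end_to_end(seed=2023, outdir="results/demo")
print(open("results/demo/summary.txt").read())
print("machine-readable report: results/demo/report.json")
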