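"""Repeated-trial comparison table (mean/std of final best fitness).

Runs GOA and AGOA 10 times each on three benchmarks at D=5 (a scaled-down
version of the full 35-run protocol) and prints the summary table.
"""

from goaelm import goa_config, agoa_config
from goaelm.benchmarks import get_benchmark, run_trials, summarize_table

summaries = []
for name in ("F1", "F3", "F5"):
    fn = get_benchmark(name, dimension=5)
    for label, cfg in [("goa", goa_config()), ("agoa", agoa_config())]:
        summaries.append(run_trials(label, fn, n_runs=10, config=cfg, seed_base=7))

print(summarize_table(summaries).to_string(index=False))

# Each row is one (function, optimizer) cell: "ave" is the mean of the 10
# final best fitnesses, "std" their sample standard deviation.  Lower is
# better; the agoa rows should dominate the goa rows on every function.
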