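"""Generate a synthetic four-table spontaneous-report dump.

Writes DEMO/DRUG/REAC/HIST as delimited text plus a ground-truth file, then
prints the flow counts the generator planted. Because the truth is known
exactly, the same dump doubles as an oracle for every downstream stage.
"""

import sys

import pvonset as pv

out = sys.argv[1] if len(sys.argv) > 1 else "scratch/example_dump"

cfg = pv.SimConfig(n_cases=2000, seed=42)
res = pv.simulate(cfg)
paths = pv.write_tables(res, out)

print(f"wrote {len(paths)} tables to {out}/")
print(f"reports simulated:          {cfg.n_cases}")
print(f"study-drug (clozapine):     {res.truth.n_clozapine}")
print(f"retainable for the cohort:  {res.truth.ledger.n_retained}")
print(f"planted exclusions:         {res.truth.ledger.to_dict()['excluded']}")
print(f"seizure onsets in window:   {len(res.truth.onset_days)}")
# The exclusion counts come from the planted missing-completely-at-random
# missingness; the pipeline must reproduce them exactly from the tables.
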