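"""Find the extraction conditions jointly maximizing both responses via
Derringer desirability, then validate the prediction against the
confirmatory experiment.

Each response is ramped to a desirability d in [0,1] between its
observed minimum and maximum; the optimizer maximizes the geometric mean
D over the design region.  RSD% < 10 between predicted and confirmed
values indicates the model's optimum holds up at the bench.
"""

from rsmextract import DesirabilityGoal, fit_quadratic, optimize, validate
from rsmextract.datasets import load_extraction_runs, load_validation_pairs

table = load_extraction_runs()
fits = [fit_quadratic(table, r) for r in ("TPC", "TFC")]
goals = [
    DesirabilityGoal(r, "maximize", float(table.response(r).min()), float(table.response(r).max()))
    for r in ("TPC", "TFC")
]
opt = optimize(fits, goals)
eth, t, temp = opt.natural
print(f"optimum: {eth:.1f}% ethanol, {t:.1f} min, {temp:.1f} degC")
print(f"predicted responses: { {k: round(v, 2) for k, v in opt.predicted.items()} }")
print(f"individual desirabilities: { {k: round(v, 4) for k, v in opt.individual.items()} }")
print(f"composite D = {opt.D:.4f}  (1.0 would mean both responses at their observed maxima)")

pairs = load_validation_pairs()
records = validate(opt, pairs["experimental"].to_dict())
for r in records:
    print(
        f"{r.response_name}: experimental {r.experimental} vs model {r.predicted:.2f} "
        f"-> RSD {r.rsd_percent:.2f}% ({'pass' if r.passed else 'FAIL'} at the 10% criterion)"
    )
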