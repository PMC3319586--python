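"""Uncertainty propagation and the surgical recommendation.

Runs a small Latin-Hypercube Monte-Carlo per configuration (diameters,
lengths, stiffness, windkessels, anastomosis angle and venous pressure all
perturbed within their uncertainty bands), summarizes each flow
distribution by its median and 25th-75th percentile interval, and applies
the 400-1500 ml/min rule with the RC > BC > BB preference.
"""

from avfplan.decision import FLOW_WINDOW_ML_MIN, assess_configuration, recommend
from avfplan.synthesis import DEFAULT_COHORT_SPEC, generate_patient
from avfplan.uncertainty import default_uncertainty_spec, run_monte_carlo

N_RUNS = 8  # increase (default 256) for stable percentiles
record = generate_patient(DEFAULT_COHORT_SPEC, 0)
spec = default_uncertainty_spec()

assessments = []
for i, cfg in enumerate(("RC-AVF", "BC-AVF", "BB-AVF")):
    dist = run_monte_carlo(record, cfg, spec, n_runs=N_RUNS, seed=100 + i)
    a = assess_configuration(dist, configuration=cfg,
                             cardiac_output_ml_min=record.cardiac_output_ml_min)
    assessments.append(a)
    status = "eligible" if a.eligible else "; ".join(a.reasons)
    print(f"{cfg}: median {dist.median:7.0f} ml/min, "
          f"IQR [{dist.p25:.0f}, {dist.p75:.0f}], "
          f"{dist.n_converged}/{dist.n_requested} runs converged -> {status}")

plan = recommend(assessments)
lo, hi = FLOW_WINDOW_ML_MIN
print(f"\nflow window {lo:.0f}-{hi:.0f} ml/min, preference RC > BC > BB")
print(f"recommended configuration: {plan.selected or 'none eligible'}")
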