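"""Compare longitudinal visit schedules for a surrogate biomarker.

Generates a synthetic two-arm trial shaped like a phase II multiple sclerosis
study (continuous imaging marker at weeks 0..96, binary clinical endpoint at
~48% vs ~71%), then sweeps eight candidate visit subsets, reporting the
trial-level I_alpha(T, S | Z) and its ITMA per entropy order.  Designs whose
ITMA matches the full schedule's deliver the same surrogacy information with
fewer (or earlier) scans.
"""

from hcsurrogacy import DesignSubset, TrialGeneratorConfig, design_sweep, generate_trial

DESIGNS = [
    (0, 24), (0, 24, 48), (0, 24, 48, 72), (0, 24, 48, 72, 96),
    (0, 48), (0, 72), (0, 24, 72), (0, 48, 72),
]

data = generate_trial(TrialGeneratorConfig())
n0, n1 = data.arm_sizes()
print(f"simulated trial: {n0} control / {n1} treated subjects, "
      f"endpoint rates {data.endpoints[:n0].mean():.2f} / {data.endpoints[n0:].mean():.2f}")

report = design_sweep(data, [DesignSubset(d) for d in DESIGNS], [0.5, 1.0, 2.0])
print("\ntrial-level I_a(T, S | Z) and ITMA by design:")
print(report.wide_frame(measure="ts").to_string(float_format=lambda v: f"{v:.4f}"))

print("\nHigher ITMA = more endpoint uncertainty removed by the surrogate under")
print("that visit schedule; order 2 spreads the designs, order 0.5 saturates.")
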