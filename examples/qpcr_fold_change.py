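"""qPCR quantification arithmetic: 2^-ddCq relative expression for a
simulated knockdown, ChIP percent input, and fold over a negative
control locus.

Run:  python examples/qpcr_fold_change.py
"""

from g4enrich import (
    ChipMeasurement,
    fold_over_reference,
    generate_qpcr_dataset,
    percent_input,
    relative_expression_ddcq,
    t_test_delta_cq,
)

# RT-qPCR: simulate a knockdown that reduces the target to 0.37-fold
# (a 63% reduction) with triplicate Cq noise of 0.1 cycles.
ms = {(m.sample, m.gene): m
      for m in generate_qpcr_dataset(3, true_fold_change=0.37,
                                     cq_noise_sd=0.1, seed=4)}
fold = relative_expression_ddcq(
    ms[("treated", "target")], ms[("treated", "housekeeping")],
    ms[("calibrator", "target")], ms[("calibrator", "housekeeping")],
)
print(f"recovered fold change (2^-ddCq): {fold:.3f} "
      f"= {100 * (1 - fold):.0f}% reduction (truth: 0.37)")

dcq_treated = [t - h for t, h in zip(ms[("treated", "target")].cq_values,
                                     ms[("treated", "housekeeping")].cq_values)]
dcq_cal = [t - h for t, h in zip(ms[("calibrator", "target")].cq_values,
                                 ms[("calibrator", "housekeeping")].cq_values)]
t_stat, p = t_test_delta_cq(dcq_treated, dcq_cal)
print(f"Student t-test on dCq values: t = {t_stat:.2f}, p = {p:.4g}")

# ChIP-qPCR: 2% input aliquot; the IP amplifies 3.3 cycles after the
# input at the target locus and 4.7 cycles after at the control locus.
target = ChipMeasurement("anti-X", "target_promoter",
                         cq_ip=27.3, cq_input=24.0, input_fraction=0.02)
control = ChipMeasurement("anti-X", "control_locus",
                          cq_ip=28.7, cq_input=24.0, input_fraction=0.02)
pt, pc = percent_input(target), percent_input(control)
print(f"percent input: target {pt:.3f}%, negative control {pc:.3f}%")
print(f"fold enrichment over control (control set to 1): "
      f"{fold_over_reference(pt, pc):.1f}-fold")
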