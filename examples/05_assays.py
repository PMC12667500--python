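"""Quantify the validation assays: qPCR relative expression, cell viability,
and ABR thresholds with post-noise shifts."""

from crossdeg import SynthConfig, simulate_assays
from crossdeg.assays import abr_thresholds, ddct_quantify, relative_viability, threshold_shift

cfg = SynthConfig(seed=1)  # true ddCt = -1 (2-fold up), viability 55%
ct, plate, abr = simulate_assays(cfg)

per_sample, summary = ddct_quantify(ct, calibrator_group="control")
print("qPCR relative quantity (2^-ddCt), mean +- SD per group:")
print(summary.to_string(index=False))

viab = relative_viability(plate)
print(f"\nmean viability: {viab['viability_pct'].mean():.1f}% "
      "(negative controls define 100%, no-cell positives 0%)")

thr = abr_thresholds(abr)
pre = thr[thr["timepoint"] == "Pre-NE"]
post = thr[thr["timepoint"] == "2DPN"]
shifts = threshold_shift(pre, post)
print("\nABR threshold shifts at 2 days post noise exposure:")
print(shifts.to_string(index=False))
print("A 90 dB post threshold means no detectable waveform (ceiling, censored).")
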