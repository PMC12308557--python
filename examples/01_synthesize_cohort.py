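"""Generate a labeled synthetic VF cohort and inspect its ground truth.

Builds 20 records per outcome class (successful ROEA vs. unsuccessful
NoROEA shocks) from the class-conditional feature summaries, then prints
the injected heart-rate and amplitude means per class.  These injected
values are what the downstream feature extractors must recover.
"""

import numpy as np

import preshock as ps

records, labels, truths = ps.synth_cohort(n_per_class=20, seed=0)

for spec in (ps.ROEA_SPEC, ps.NOROEA_SPEC):
    idx = [i for i, r in enumerate(records) if r.label == spec.label]
    hr = np.mean([60 / np.mean(np.diff(truths[i].r_peak_times)) for i in idx])
    amp = np.mean([truths[i].beat_amplitudes[0] for i in idx])
    print(
        f"{spec.label:>7}: {len(idx)} records, injected mean HR {hr:6.1f} bpm "
        f"(target {spec.means['heart_rate']:.0f}), "
        f"amplitude {amp:.2f} mV (target {spec.means['amplitude_qrs']:.1f})"
    )

record = records[0]
print(
    f"\nfirst record: {record.record_id}, {record.n_samples} samples at "
    f"{record.fs:.0f} Hz ({record.duration:.0f} s), {truths[0].n_beats} beats"
)
# Small per-class deviations from the targets are sampling noise: each
# record's rate/amplitude is an independent Gaussian draw.
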