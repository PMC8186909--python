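"""Estimate how fast a force signal travels along the ankyrin spring.

Five replica pairs of reaction-force traces (free vs pushed) are generated
with an imposed signal speed of 1.8 nm/ps over a 15 nm spring; the onset
detector finds where the traces start to deviate and v = L / mean(onset).
"""

from mechanotraj import mechanics as mech
from mechanotraj import synthetic as syn

v_true, length_nm = 1.8, 15.0
onsets = []
for replica in range(5):
    times, free, pushed = syn.make_delayed_force_traces(
        delay_ps=length_nm / v_true, seed=replica
    )
    onset = mech.arrival_onset(
        times, free, pushed, baseline_window_ps=2.0, threshold_sd=3.0
    )
    onsets.append(onset)
    print(f"replica {replica}: onset at {onset:.2f} ps")

est = mech.transfer_speed(onsets, length_nm)
print(f"\ntransfer speed v = L / mean(onset) = "
      f"{est.speed_nm_per_ps:.2f} +/- {est.speed_sd_nm_per_ps:.2f} nm/ps")
print("An onset near 8.3 ps over 15 nm recovers the imposed 1.8 nm/ps: the")
print("force reaches the far end of the spring within picoseconds.")
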