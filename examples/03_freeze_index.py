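"""The frequency-ratio (FR) freeze index on paired trials with/without FOG.

FR divides the squared 3-8 Hz (freeze band) power of the anteroposterior
acceleration by the squared 0.5-3 Hz (locomotor band) power.  Values near
zero mean purely rhythmic gait; trembling-in-place episodes push power into
the freeze band and raise FR.  The same random seed is used for both trials
so the only difference is the injected freeze burst.
"""

from itug import frequency_ratio
from itug.synthetic import FreezeEpisode, pd_profile, simulate_trial

base = pd_profile(0.6, subject_id="P01")
freezing = pd_profile(
    0.6,
    subject_id="P01",
    freeze_episodes=(
        FreezeEpisode("turn", start_offset_s=0.4, duration_s=1.5, intensity_g=0.35),
        FreezeEpisode("turn_stand_to_sit", 0.3, 1.0, intensity_g=0.30),
    ),
)

for label, profile in [("PD, no freeze episodes", base), ("PD, freezing", freezing)]:
    rec, truth = simulate_trial(profile, trial_index=2, seed=7)
    s, e = truth.full
    fr = frequency_ratio(rec.acc_axis("AP")[s:e], rec.sample_rate)
    print(f"{label:<28} FR = {fr:.3f}")

print("\nHigher FR with the bursts: freeze-band power grew relative to the")
print("locomotor band. Near 0 indicates healthy gait; freezing pushes FR up.")
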