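"""Generate a small synthetic music-EEG dataset and inspect it.

Builds 4 emotion classes x 4 trials of 8-channel EEG-like signal (1/f
background + class-dependent alpha power) with SAM-style ratings, and
prints the per-class rating statistics.  The printed means should sit
near the generator's class parameters (e.g. fear valence 3.03, arousal
7.12) — these are the stimulus statistics the generator emulates.
"""

from musemo.synth import SyntheticDatasetSpec, default_profiles, make_dataset

spec = SyntheticDatasetSpec(
    profiles=default_profiles(),
    n_trials_per_class=4,
    n_channels=8,
    trial_seconds=10.0,
    fs=128.0,
    seed=0,
)
recordings, ratings = make_dataset(spec)

print(f"{len(recordings)} recordings of shape {recordings[0].data.shape} "
      f"at {recordings[0].fs:g} Hz")
print("\nPer-class SAM rating means (1-9 scale):")
print(ratings.groupby("class")[["valence", "arousal"]]
      .agg(["mean", "std"]).round(2))
print("\nA valence/arousal mean on either side of 5 determines the binary "
      "label of every trial in that class.")
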