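"""Extract the six kinematic features from one synthetic act.

Builds a 9-second recording in which the right hand makes four ballistic
(minimum-jerk) strokes up to chest height and everything freezes for
0.4 s, then runs the full pipeline (Savitzky-Golay smoothing, speed,
feature extraction) and compares the result with the generator's ground
truth.
"""
from gesturekin import ActSpec, Stroke, extract_features, generate_act

spec = ActSpec(
    duration_s=9.0,
    strokes=[
        Stroke("R", 1.0, 0.6, (0.45, 1.15, 0.35)),  # up to between torso midline and neck
        Stroke("R", 2.0, 0.6, (0.30, 0.85, 0.25)),  # back to rest
        Stroke("R", 3.0, 0.6, (0.45, 1.15, 0.35)),
        Stroke("R", 4.2, 0.8, (0.30, 0.85, 0.25)),
    ],
    holds=[(6.0, 0.4)],
)
seq, truth = generate_act(spec)
row = extract_features(seq).rows[0]

print(f"submovements (right hand): {row.submovements_right}  [truth {truth.submovements['R']}]")
print(f"hold count:                {row.hold_count}  [truth {truth.hold_count}]")
print(f"hold time:                 {row.hold_time_s:.3f} s  [truth {truth.hold_time_s:.3f} s]")
print(f"vertical amplitude:        {row.vertical_amplitude}  [truth {truth.vertical_amplitude}]")
print(f"peak velocity:             {row.peak_velocity_mps:.3f} m/s  [truth {truth.peak_speed_mps:.3f}]")
print(f"hand distance:             {row.distance_m:.3f} m  [truth {truth.distance_m:.3f}]")
print()
print(
    "Each counted submovement is a velocity peak of at least 0.2 m/s at\n"
    "least 8 frames from its neighbours; the hold is an interval where\n"
    "hands, thumbs, elbows and shoulders all move < 0.01 m per frame for\n"
    ">= 300 ms; amplitude 2 means the hand topped out between the torso\n"
    "midline and the neck."
)
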