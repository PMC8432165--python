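"""Inserting a barrier duplicates place fields immediately; relearning with
the barrier in place then prunes some of the duplicates.

The duplication needs no change to the successor matrix: BVCs respond to
the nearest boundary, so a new wall creates a second location with the
feature profile that drove the original field.
"""

import bvcsr

env = bvcsr.build_environment("square")
pop = bvcsr.make_population()
fmap = bvcsr.feature_map(pop, env)
traj = bvcsr.simulate_trajectory(env, duration=600.0, seed=3)
sm = bvcsr.learn_sr(fmap, traj)

barrier = bvcsr.default_barrier(env)  # from the south wall midpoint, halfway up
env_b = bvcsr.insert_barrier(env, barrier)
fmap_b = bvcsr.feature_map(pop, env_b, gain=fmap.gain)

before = bvcsr.place_maps(sm, fmap)
after = bvcsr.place_maps(sm, fmap_b)   # same M - purely geometric response
records = [bvcsr.barrier_duplication(b, a, barrier, cell=i)
           for i, (b, a) in enumerate(zip(before, after))]
dup = [r for r in records if r.duplicated]
print(f"immediate field duplication: {len(dup)}/{len(records)} cells "
      f"({100 * len(dup) / len(records):.0f}%)")

traj2 = bvcsr.simulate_trajectory(env_b, duration=600.0, seed=4)
sm2 = bvcsr.learn_sr(fmap_b, traj2, M0=sm)  # continual learning
relearned = bvcsr.place_maps(sm2, fmap_b)
lost = sum(
    len(bvcsr.detect_fields(relearned[r.cell])) <= r.fields_before for r in dup
)
print(f"duplicates lost after relearning: {lost}/{len(dup)}")

# The first number is the purely geometric response (no learning); the
# second reflects the SR adapting to the changed transition structure as
# the barrier reshapes behavior.
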