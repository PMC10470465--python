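"""Counterbalanced 2AFC session designs for both experiments."""

from collections import Counter

from hyperrigid import build_session

for experiment in (1, 2):
    session = build_session(experiment, seed=0)
    cells = Counter(
        (t.condition.dimension, t.condition.displacement_axis,
         t.condition.irregularity)
        for t in session.trials
    )
    reps = set(cells.values())
    print(f"experiment {experiment}: {session.n_trials} trials, "
          f"{len(cells)} condition cells x {reps} repetitions, "
          f"block order {session.block_order}")
# Experiment 1 crosses 2 dimensionalities x 3 displacement axes x 3
# irregularity levels x 3 repetitions = 54 trials; Experiment 2 drops the
# x axis and repeats each of the 12 cells 7 times = 84 trials.  3D and 4D
# trials sit in separate blocks; the rigid stimulus's top/bottom position
# is balanced within each cell.
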