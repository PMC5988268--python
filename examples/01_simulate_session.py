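"""Generate a synthetic foraging session and write it to disk.

The generator emulates a recording day: three scene contexts (D/R
dangerous+rich, S/R safe+rich, S/P safe+poor), LATER-distributed saccade
reaction times that are fastest in dangerous scenes, excited/inhibited
Poisson units whose fixation-period gain follows the same context ordering,
and context-modulated pupil and heart-rate signals.
"""

from contextsacc import SessionConfig, generate_session, write_session
from contextsacc.behavior import success_rate

cfg = SessionConfig(n_per_context=5, n_trials_per_scene=10, n_units=8)
session = generate_session(cfg, seed=7)
write_session(session, "scratch/example_session")

print(f"scenes: {len(session.scenes)}  trials: {len(session.trials)} "
      f"(incl. {sum(t.is_repeat for t in session.trials)} repeats after "
      "robber wins)")
print(f"units: {len(session.units)}  spike trains: "
      f"{len(session.spike_trains)}")
for ctx in ("D/R", "S/R", "S/P"):
    trials = [t for t in session.trials
              if session.context_of_trial(t) == ctx and not t.is_repeat]
    print(f"{ctx}: {len(trials)} trials, success rate "
          f"{success_rate(trials):.2f}")
# The D/R success rate is lower: the robber object races the saccade and
# steals the reward on slow trials, which is what gives the dangerous
# context its reduced predicted reward value.
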