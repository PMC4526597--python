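"""Simulate one subject through the two-game devaluation experiment.

A mid-weight hybrid agent (w = 0.5) plays 200 training trials of the two
interleaved games, four no-feedback trials, the devaluation of one coin
type, 20 respond/withhold test trials and the consumption display.
"""

import habitlearn as hl

config = hl.TaskConfig.exp1()
params = hl.AgentParams(alpha=0.5, beta=5.0, w=0.5, pi=0.2)
log = hl.simulate_subject(params, config, seed=1)

print(log["phase"].value_counts().to_string())
print("\nfirst training trials:")
print(log.head(5).to_string(index=False))

test = log[log["phase"] == "test"]
responded = test[test["action"] != "none"]
print(f"\ntest-phase responses: {len(responded)}/20 "
      f"({int(responded['devalued_game'].sum())} toward the devalued coin)")
score = hl.devaluation_sensitivity(log, "exp1")
print(f"devaluation sensitivity: {score:+.0f}  "
      "(valued-state minus devalued-state responses; 10 = fully "
      "goal-directed, 0 = habitual)")
print(f"consumption sensitivity: {hl.consumption_sensitivity(log):+.0f}  "
      "(valued minus devalued coins collected, of 10 each)")
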