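"""Simulate one participant's session and check the contingency they
actually experienced.

The programmed contingency is zero — pressing never changes the outcome
probability — but a participant who presses on some trials and not others
experiences a *sample* ΔP that fluctuates around zero.
"""

from contingencylab import (
    ExperimentConfig,
    ParticipantProfile,
    generate_schedule,
    simulate_session,
    tabulate_events,
)

config = ExperimentConfig.for_density_arm("high")
profile = ParticipantProfile(
    participant_id="P001",
    bdi_group="low",
    density_arm="high",
    instruction_arm="discrete",
)
schedule = generate_schedule(config, seed=21)
log = simulate_session(profile, schedule, seed=42)

summary = tabulate_events(log)
print(f"engaged trials:   {summary.n_engaged}  (missed {summary.n_missed})")
print(f"2x2 counts:       a={summary.a} b={summary.b} c={summary.c} d={summary.d}")
print(f"P(O|A):           {summary.p_o_given_a:.3f}")
print(f"P(O|~A):          {summary.p_o_given_not_a:.3f}")
print(f"experienced dP:   {summary.delta_p:+.3f}   (programmed: 0)")
print(f"outcome density:  {summary.outcome_density:.3f}  (programmed: 0.75)")
print(f"block ratings:    {log.judgments}")

# A small nonzero experienced ΔP is pure sampling noise; it is exactly the
# quantity entered as the covariate in the downstream ANCOVA so that
# judgment effects are not confounded by accidental experienced control.
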