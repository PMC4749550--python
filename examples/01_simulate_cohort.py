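"""Generate a synthetic Go/No-Go cohort and summarize its behavior.

The generator produces blocked trial streams (200 Go : 24 No-Go per
224-trial block, >= 3 Go trials between No-Go stimuli) and lets the
one-choice diffusion model decide which commission errors are detected
and when.
"""

from postdecision import CohortConfig, behavioral_summary, generate_behavior

config = CohortConfig(n_subjects=12, n_blocks=4, seed=1)
trials = generate_behavior(config)
summary = behavioral_summary(trials)

print(f"{len(trials)} trials from {config.n_subjects} subjects")
for key, value in summary.items():
    print(f"  {key:>22}: {value:.3f}" if isinstance(value, float)
          else f"  {key:>22}: {value}")

# What to look for: roughly 57% of No-Go trials withheld, roughly 68% of
# errors detected, and the primary-RT ordering detected < Go < undetected
# (salient lapses are pressed faster *and* generate stronger error
# evidence, so they are caught more often).
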