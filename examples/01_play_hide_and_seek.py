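"""Simulate the experimental protocol and score performance patterns.

A competitive 1-ToM seeker plays the 12-session protocol (4 sessions
against each of the biased-random, 0-ToM and 1-ToM hiders) several times;
we report the average per-condition win rate, raw and net of the 0.5
chance level.
"""
import numpy as np

from ktom.agents import AgentSpec
from ktom.arena import CONDITIONS, ProtocolDesign, run_protocol, score_performance

subject = AgentSpec("1ToM-comp", {"sigma": 0.5, "beta": 0.05})
raw = {c: [] for c in CONDITIONS}
for rep in range(10):
    sessions = run_protocol(subject, ProtocolDesign(), seed=rep, individual_index=rep)
    perf = score_performance(sessions)
    for c in CONDITIONS:
        raw[c].append(perf[c]["raw"])

print("condition  raw    net   (mean of 10 protocol runs)")
for c in CONDITIONS:
    m = float(np.mean(raw[c]))
    print(f"{c:9s}  {m:.3f}  {m - 0.5:+.3f}")
print(
    "\nA mentalizing seeker exploits the predictable 0-ToM hider (net > 0 vs"
    " OTOM),\nwhile RB and the more sophisticated 1-ToM hider hold it near"
    " chance."
)
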