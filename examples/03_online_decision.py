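"""The agreement vote and transition-legality rules on a raw label stream.

Feeds a noisy hand-made classifier stream through the decision layer and
shows how the 100-window vote suppresses flicker and how the rule table
blocks a physically implausible sit -> level-walk jump.
"""

import numpy as np

from gaitfusion import DecisionConfig, decide_stream, default_rules, update_latency_ms
from gaitfusion.modes import LocomotionMode as M

rules = default_rules()
print("legal successors of each mode:")
for m in M:
    nxt = [n.name for n in M if rules.is_allowed(m, n) and n != m]
    print(f"  {m.name:>2} -> {', '.join(nxt)}")

fs = 2000.0
print(f"\nvote latency: {update_latency_ms(100, fs):.1f} ms "
      f"(100 agreeing one-sample steps at {fs:.0f} Hz)")

rng = np.random.default_rng(0)
raw = np.concatenate([
    np.full(400, int(M.ST)),
    rng.choice([int(M.ST), int(M.LW)], size=80),   # noisy boundary
    np.full(600, int(M.LW)),
])
trace = decide_stream(raw, DecisionConfig(100, M.ST), rules,
                      times=np.arange(raw.size) / fs)
print("\nupdates on a noisy stand->walk stream:")
for t, a, b in trace.updates:
    print(f"  {t*1000:7.1f} ms  {M(a).name} -> {M(b).name}")

# An illegal candidate never takes effect, however long it persists:
blocked = decide_stream(np.full(2000, int(M.LW)), DecisionConfig(100, M.S), rules)
print(f"\nsit + 2000 samples of 'level walk': output stays "
      f"{M(int(blocked.output[-1])).name} (S->LW is not a legal transition)")
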