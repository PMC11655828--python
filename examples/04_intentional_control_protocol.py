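"""The twelve-iteration intentional-control protocol, end to end.

Step I gates the external/endogenous streams in BA9 (correlated
streams open the deliberate pathway); then twelve feedback iterations
of goal competition (BA10) and expectancy-weighted action competition
(BA46) run with rising salience for the winning assembly and rising
feed-forward inhibition. Per iteration the tracked BA46 assembly's
attractor is measured (correlation dimension, Lyapunov exponent,
sample entropy, dominant frequency, theta-gamma coupling); the
accumulated BA10/BA9 output forms the negative-going early readiness
potential.

Takes about a minute. Watch the correlation dimension fall from ~4 to
~2.5 while the dominant frequency jumps from theta to ~45 Hz gamma.
"""

from avol.brain import BrainConfig, build_brain
from avol.protocol import ProtocolConfig, run_protocol

brain = build_brain(BrainConfig(seed=0))
trace, rp = run_protocol(brain, ProtocolConfig(seed=0))

print(f"gate: r = {trace.gate.correlation:+.2f} -> {trace.mode} pathway")
print(" it |   D2  | lambda1 | SampEn | f_BA10 | f_BA46 |  PAC  | salience(A0)")
for r in trace.records:
    m = r.metrics
    print(f" {r.index:2d} | {m.d2:5.2f} | {m.lyap1:7.1f} | {m.entropy:6.2f} |"
          f" {r.dominant_freq_ba10:6.1f} | {r.dominant_freq_ba46:6.1f} |"
          f" {r.pac_mvl:5.3f} | {r.salience['A0']:.2f}")
print(f"readiness potential: |RP| trend rho = {rp.spearman_rho:.2f}, "
      f"final amplitude = {rp.amplitude[-1]:+.2f}, "
      f"awareness threshold crossed at t = {rp.threshold_crossing} ms")
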