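"""Phase-amplitude coupling: detection and significance.

A gamma rhythm whose bursts ride the peaks of a drifting theta carrier
shows strong coupling (mean vector length well above the time-shift
surrogate null); independent noise does not. The same measure drives
the salience competition between goal assemblies inside the model.
"""

from avol.analysis import pac_mvl
from avol.fixtures import FixtureSpec, generate_fixture

coupled = generate_fixture(FixtureSpec("theta_modulated_gamma", n=5000,
                                       fs=1000.0, seed=1,
                                       params={"mod": "burst"}))
res = pac_mvl(coupled["pac"], 1000.0, (4, 8), (30, 80), seed=1)
print(f"theta-burst gamma: mvl = {res.mvl:.3f}, "
      f"surrogate p = {res.surrogate_p:.4f}  (significant coupling)")

noise = generate_fixture(FixtureSpec("white_noise", n=5000, seed=7))
null = pac_mvl(noise["noise"], 1000.0, (4, 8), (30, 80), seed=7)
print(f"white noise:       mvl = {null.mvl:.3f}, "
      f"surrogate p = {null.surrogate_p:.4f}  (no coupling)")
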