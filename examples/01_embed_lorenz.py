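"""Delay-embed a Lorenz time series and inspect the eigen modes.

Simulates x(t) of the Lorenz system, stacks it into a Hankel matrix with
a q*dt = 0.1 time-unit window, and computes the eigen-time-delay
coordinates by SVD.  The singular values decay fast (the window of a
smooth signal is nearly polynomial), and the delay modes in U oscillate
like polynomials of increasing order — the zero-crossing count of mode k
grows with k, which is the practical criterion for a good (q, dt) choice.
"""

import numpy as np

from havok import build_hankel, compute_embedding, simulate_system

traj = simulate_system("lorenz", dt=0.001, duration=50.0, transient=10.0)
series = traj.observed
print(f"simulated {len(series)} samples of Lorenz x(t), dt = {series.dt}")

H = build_hankel(series, q=100)
print(f"Hankel matrix: {H.shape[0]} x {H.shape[1]}")

emb = compute_embedding(H, r=15)
ratios = emb.S / emb.S[0]
print("normalized singular values (r = 15):")
print("  " + "  ".join(f"{v:.2e}" for v in ratios))

print("zero crossings of delay modes u_1 .. u_6 (polynomial-like ordering):")
for k in range(6):
    s = np.sign(emb.U[:, k])
    n = int(np.sum(s[1:] * s[:-1] < 0))
    print(f"  mode {k + 1}: {n} crossings")
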