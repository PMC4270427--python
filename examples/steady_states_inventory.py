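"""Equilibria of the two-option model at the Japanese-strain rates.

Prints every steady state at a mass past the symmetry-restoring
pitchfork, with stability flags, and the three critical masses.  The
nine states (tristability: none / one / both options, plus their
unstable separators) are the model's explanation of why a large
plasmodium can settle on either one or two food sources.
"""

from slimechoice import ModelParams, all_steady_states, critical_masses

params = ModelParams(k=2.5, d=1.0, T=1.5, n=2, M=5.0)

cm = critical_masses(params)
print(f"critical masses: M1={cm.M1:.4f}  M2={cm.M2:.4f}  M3={cm.M3:.4f}")
print(f"steady states at M={params.M} (past the pitchfork):")
for s in sorted(all_steady_states(params), key=lambda s: (s.branch, -s.X1)):
    flag = "stable  " if s.stable else "unstable"
    print(f"  {s.branch:22s} ({s.X1:7.4f}, {s.X2:7.4f})  {flag}  "
          f"Re(lambda) = {s.eigenvalues[0].real:+.4f}, {s.eigenvalues[1].real:+.4f}")
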