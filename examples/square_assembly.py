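"""Square assembly: the catastrophe without a sequential assembly path.

S = L species sit on a sqrt(S) x sqrt(S) grid; a monomer binds a cluster
with b matching neighbours at rate b*nu.  Structures can grow in two
dimensions along many different paths, yet the small-alpha saturation yield
still sits below 1 and still falls with N -- kinetic trapping by structural
mismatch does not require a linear assembly order.
"""

from selfassembly import AssemblyConfig, run_ensemble
from selfassembly.variant_models import run_ssa_square

G = 6
S = G * G
alpha = 1e-7
print(f"{G}x{G} squares ({S} species), alpha = {alpha:g}")
for N in (10, 30, 100):
    cfg = AssemblyConfig(S=S, L=S, N=N, alpha=alpha, variant="square")
    s = run_ensemble(cfg, 64, N, runner=run_ssa_square)
    print(f"  N = {N:4d}: mean yield {s.mean_yield:.3f} +- {s.stderr:.3f}")
# The saturation value decreases with N, mirroring the ring results: the
# catastrophe is generic for heterogeneous, (partially) irreversible
# assembly with limited resources.
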