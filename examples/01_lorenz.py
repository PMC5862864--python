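"""Any ODE system can be simulated from a bare equation string.

The Lorenz system is written in conventional notation, flattened into a
single-population model ('pop1'), and integrated with 4th-order
Runge-Kutta. We print the final state and the attractor's bounding box.
"""

import numpy as np

import neusim as ns

eqns = ("s=10; r=27; b=2.666\n"
        "dx/dt=s*(y-x); x(0)=1\n"
        "dy/dt=r*x-y-x*z; y(0)=1\n"
        "dz/dt=-b*z+x*y; z(0)=1")

model = ns.build(eqns)
data = ns.integrate(model, ns.SolverOptions(method="rk4", dt=0.001,
                                            tspan=(0, 20)))

x, z = data["pop1_x"][:, 0], data["pop1_z"][:, 0]
print(f"states: {data.names()}")
print(f"final (x, z) = ({x[-1]:.3f}, {z[-1]:.3f})")
print(f"x range [{x.min():.1f}, {x.max():.1f}], "
      f"z range [{z.min():.1f}, {z.max():.1f}]")
# The (x, z) phase plane traces the familiar two-lobed butterfly; the
# ranges above are the attractor's extent for these classic parameters.
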