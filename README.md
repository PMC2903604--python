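# bonesim

Simulation of trabecular bone adaptation at different mechanical levels:
a 2D plane-stress voxel finite-element model coupled to an osteocyte
mechanosensing field and a mechanostat remodeling rule set with stochastic
osteoclast activation.

## Who this is for

Researchers in bone mechanobiology and computational biomechanics who want
a small, fully reproducible implementation of mechanostat-style surface
remodeling: how disuse, overload, small physiological load changes, strut
disconnection, load rotation and raised remodeling set points (menopause)
reshape a trabecular patch.

## The model

A 2 mm x 2 mm bone patch (80 x 80 bilinear elements, 0.02 mm thick, framed
by non-remodeling side plates) carries a relative density field
m(x) in [0.01, 1] with a power-law tissue modulus

    E(m) = E_max m^3,  E_max = 500 MPa,

loaded by a biaxial far field with principal stresses (+sigma, -sigma) at
phi = 30 deg.  Osteocytes (one per bone-filled element, 1600/mm^2) sense the
local strain-energy density R_i and relay it to the trabecular surface with
exponential spatial decay (D = 100 um):

    P(x,t) = sum_i mu_i R_i(t) exp(-d_i(x)/D).

At each surface site and iteration, osteoclasts activate with a
zone-dependent probability p(P) — sigmoidal in disuse, constant c = 0.0275
in the adaptive (lazy) zone [K_AD1, K_AD2] = [0.0918, 0.1122] MPa, quadratic
(clamped at 1) in overload — resorbing a fixed quantum r_oc = 0.38 of
relative density; osteoblasts refill r_ob(P), a continuous piecewise-linear
law that exactly balances resorption inside the lazy zone and
over-compensates above it.  Iterating FE solve -> stimulus -> stochastic
activation -> density update produces the adaptation dynamics; see
`docs/methods.md` for the full rule set, calibration and limitations.

## Worked example

```python
from bonesim import MeshSpec, ScenarioConfig, Simulation, build_mesh
from bonesim.engine import bootstrap_homeostasis, run_scenario

sim = Simulation(mesh=build_mesh(MeshSpec()))      # defaults: 80x80, phi=30
boot = bootstrap_homeostasis(sim, seed=1)           # homeostatic start
row = boot.state.history[-1]
print(f"homeostasis: VF={row['volume_fraction']:.3f}, "
      f"avg strain={row['avg_strain_ue']:.0f} ue")

state = run_scenario(
    ScenarioConfig(scenario="overload", iterations=500, seed=11),
    sim, boot.density,
)
print(f"overload x1.2: bone mass {state.history[-1]['bone_mass_pct']:+.2f}%")
```

prints

```
homeostasis: VF=0.666, avg strain=3091 ue
overload x1.2: bone mass +7.35%
```

i.e. the equilibrated patch has a bone volume fraction of 0.666, and a 20%
load increase drives net formation (+7.35% bone mass over 500 iterations)
until the surface stimulus re-enters the lazy zone — the mechanostat
correcting the strain error.  The same API runs `disuse`, `phys_up`,
`phys_down`, `menopause`, `rotate` and `disconnect`.

The CLI mirrors this: `bonesim bootstrap`, `bonesim run --scenario overload
--start-field density.csv`, `bonesim validate` (analytic anchor table),
`bonesim fixtures` (toy architectures).  Runs write `history.csv`,
`density_final.csv` and `manifest.json` (resolved config, seed, derived
constants).

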