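# flowbond

Kinetics of single and divalent receptor–ligand attachments under flow.

When a microsphere carried by a laminar flow is arrested by a single
molecular bond, the distribution of arrest durations reports directly on
bond rupture under a constant, known force. Two robust features emerge in
such experiments: the dissociation rate grows exponentially with force
(Bell behaviour), and it *decreases with bond age* — newly formed bonds
mature on the sub-second timescale. `flowbond` implements a quantitative
framework for both effects and for the extra stability of divalent
attachments:

* **Bond law.** A single bond under force *F* dissociates at rate
  k(F, t) = k(F, 0) / (1 + a(F)·t), where k(F, 0) is the initial off-rate
  and a(F) the bond-strengthening rate. The survival curve is
  S(t) = (1 + a t)^(−k₀/a), reducing to exp(−k₀ t) when a = 0. Curves are
  fitted by minimizing the mean squared difference of log-survival on a
  19-point log-spaced grid covering 0–5.45 s, and both parameters are
  regressed on force in Bell (log-linear) form, allowing extrapolation to
  zero and half force.
* **Hydrodynamics.** Wall shear rate G maps to bead velocity
  (u_p ≈ 0.54 a G), near-wall Stokes drag, and bond tension through the
  tether lever arm T = (F + Γ/a)·√(a/2L); freely-jointed-chain stiffness
  and thermal-force estimates cover the force-free controls.
* **Observation.** Arrest detection in bead trajectories (displacement
  < 0.5 µm over a 200 ms window), the duration correction
  d_true = d_app + δt − 2δx/u_p, binomial/Poisson uncertainties, early-count
  extrapolation, and subtraction of the nonspecific arrest component
  measured with control beads.
* **Divalent simulation.** A fixed-step (1 ms) Monte Carlo of attachments
  holding 1–2 bonds with per-bond strengthening clocks, rebinding of the
  second bond at rate k_r, and optional equal force sharing; k_r is the
  single free parameter fitted against observed dimer survival curves.
* **Synthetic data.** A generator producing ground-truth arrest datasets
  and bead trajectories with the statistical structure the analysis
  assumes, so the entire pipeline is testable without external data.

## Worked example

The three flow-chamber conditions give bond-law parameters
(k₀, a) = (0.519, 1.171), (1.277, 2.270) and (4.934, 6.126) s⁻¹ at tensions
8.80, 15.84 and 26.4 pN. Regressing ln k₀ on force and evaluating:

```sh
$ flowbond bell --table k.csv --eval 13.2 --eval 0
zero-force value = 0.1683 s^-1, slope = 0.128 /pN
value(13.2 pN) = 0.9112 s^-1
value(0 pN) = 0.1683 s^-1
```

The zero-force initial off-rate is 0.168 s⁻¹, and at half the highest
tension (13.2 pN) a single bond starts dissociating at 0.911 s⁻¹ — the
parameters a bond inside a force-sharing divalent attachment experiences.
The tension itself comes from the hydrodynamic mapping:

```sh
$ flowbond force --shear 30.9 --tether dimer
tension = 26.431 pN (u_p = 37.54 um/s)
```

Simulating a divalent attachment at that highest force (one bond at time
zero, rebinding at k_r = 6 s⁻¹, force sharing, 5,000 replicates, seed 1):

```python
import numpy as np, flowbond as fb

levels = fb.ForceLevels(full=fb.BondLaw(4.934, 6.126),
                        half=fb.BondLaw(0.911, 1.772),
                        unloaded=fb.BondLaw(0.168, 0.512))
cfg = fb.DimerSimConfig(rebinding_rate=6.0, force_sharing=True,
                        initial_bonds=1, seed=1)
curve = fb.simulate_survival(cfg, levels,
                             grid=np.unique(np.append(fb.fit_grid(), 5.0)))
print(curve.evaluate(5.0))        # 0.4762
print(fb.survival(levels.full, 5.0))  # 0.0619
```

About 48% of divalent attachments survive 5 s under a force that leaves
only 6% of single bonds — an eightfold avidity premium produced jointly by
bond strengthening, rebinding and force sharing. Toggling the mechanisms
off one at a time (`flowbond decompose`) shows strengthening contributes
the most, then rebinding, then force sharing.

## Layout

| module | contents |
| --- | --- |
| `flowbond.kinetics` | bond law, survival/sampling, log-MSD fitting, Bell regression |
| `flowbond.hydrodynamics` | shear → velocity/drag/tension, FJC controls |
| `flowbond.observation` | arrest detection, duration correction, survival curves, nonspecific subtraction |
| `flowbond.dimer_sim` | divalent-attachment Monte Carlo, k_r fitting, mechanism decomposition |
| `flowbond.synthetic_data` | ground-truth arrest/trajectory generator |
| `flowbond.io`, `flowbond.cli` | TSV/JSON serialization and the `flowbond` command |

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
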