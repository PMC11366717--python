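# sacsim

Monodomain simulation of stretch-activated-channel (SAC) triggered
reentry at the papillary-muscle insertion.

In patients with mitral valve prolapse and mitral annulus disjunction,
systolic traction on the papillary muscles stretches the myocardium at
the insertion region. Stretch opens stretch-activated channels, and the
resulting current can trigger ectopy or reentrant arrhythmia. `sacsim`
is a desk-scale in-silico laboratory for this mechanism, aimed at
computational electrophysiologists: it couples a human ventricular
ionic model to an anisotropic monodomain tissue solver on synthetic
rod / sheet / wall-slab geometries, adds a transient SAC current in a
layered spherical "stretch region", and automates the
vulnerability-window protocols that map when in the cardiac cycle a
stretch pulse induces reentry.

## Model

Tissue propagation follows the monodomain equation

    div(sigma grad Vm) = chi Cm dVm/dt + I_ion,

with the effective conductivity tensor `sigma = sigma_t I + (sigma_l -
sigma_t) f f^T` assembled from the local fiber direction `f`. Membrane
kinetics are the ten Tusscher human ventricular model (2006
formulation); APD heterogeneity scales the slow delayed rectifier
current I_Ks by linear apicobasal x transmural ramps (factor 1 at the
basal endocardium to 4 at the apical epicardium, i.e. APD90 from 290 ms
down to 206 ms at BCL 500 ms). The SAC current is linear,

    I_SAC = g_SAC (Vm - E_SAC),        dg_SAC/dt = -(g_SAC - g_target)/tau,

with the target conductance switched from 0 to 0.1 mS/uF at stretch
onset and back to 0 once g_SAC comes within 1e-13 of the target; with
tau = 1.8 ms this yields the standard ~50 ms pulse. Reversal potentials
E_SAC from -10 mV (cation-nonselective, depolarizing) to -70 mV
(potassium-selective, repolarizing) select the arrhythmia mechanism.
Conductivities are calibrated on a 10 cm rod so planar-wave conduction
velocities hit 0.56 / 0.21 m/s (2 m/s in the fast endocardial layer);
fibrosis is modeled as 20-60 % conduction slowing (global or confined
to the stretch region) and as insulating inter-element clefts sampled
with probability `a |cos(theta)|` relative to the fiber-sheet normal,
denser toward the center of the stretch region.

See `docs/methods.md` for the numerical methods, calibrations and
protocol definitions.

## Worked example

Phase response of a single cell: a 50 ms SAC pulse is applied during
the plateau (150 ms) and at rest (330 ms) of a paced action potential
for a depolarizing (-10 mV) and a repolarizing (-70 mV) channel:

```python
from sacsim.cell.protocols import CellParams, run_phase_response
from sacsim.sac import SACParams

df = run_phase_response([-10.0, -70.0], [150.0, 330.0],
                        SACParams(), CellParams())
print(df[["e_sac", "onset", "secondary_ap", "delta_apd"]].to_string(index=False))
```

```
 e_sac  onset  secondary_ap  delta_apd
 -10.0  150.0         False     -15.36
 -70.0  150.0         False    -115.60
 -10.0  330.0          True       0.00
 -70.0  330.0         False       0.00
```

During the plateau both channels repolarize the cell and shorten the
APD (by 15 ms at -10 mV, by 116 ms at -70 mV — a near-complete early
repolarization). At rest the depolarizing channel fires a secondary
action potential (`secondary_ap = True`) while the potassium-selective
channel cannot; in tissue these two effects become the two reentry
mechanisms (ectopy on the T-wave downstroke vs. early repolarization at
the end of the QRS).

Tissue studies run through the model presets (`M1`-`M21` with radius /
slowing / fibrosis suffixes) and the CLI:

```
sacsim sweep --config m7.yaml --onsets 40:80 --out out/
```

which classifies each SAC onset as none / ectopy / unsustained or
sustained reentry and reports the vulnerability windows.

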