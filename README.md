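# dantespace

Extended-phase-graph (EPG) simulation of the **DANTE-SPACE** sequence for
intracranial vessel-wall MRI, including the physiological effects that shape
its contrast in vivo: intravoxel velocity spread, cardiac-pulsatile flow,
diffusion, vessel flow trajectories and transmit-field (B1+) variation.

## The problem

DANTE-SPACE images the arterial vessel wall while simultaneously
suppressing the blood inside the vessel and the CSF around it.  A DANTE
preparation — hundreds of small flip-angle RF pulses interleaved with
gradient blips — leaves stationary spins near equilibrium but saturates
moving spins, and is followed by a SPACE readout, a 3-D variable-flip-angle
turbo spin echo whose refocusing angles are designed so a reference tissue
traces a prescribed echo-amplitude evolution.  The achieved vessel-wall /
CSF / blood contrast depends delicately on sequence parameters and on slow
physiological motion; this package simulates those mechanisms so protocols
can be optimised and in-vivo signal levels interpreted — for example,
mapping an observed relative vessel-wall signal back to a mean wall
pulsation velocity.

The spin physics is the extended phase graph formalism: a dephased spin
ensemble is represented by configuration states `F_k` (transverse) and
`Z_k` (longitudinal); RF pulses mix states of equal `|k|`, gradients shift
the transverse orders, and relaxation, diffusion (`exp(-b_k D)`) and
coherent flow (a per-order phase `(k + s/2)·Δk·v·τ`) act on the orders.
The voxel signal is `F_0`; the scalar signal of a readout is the amplitude
of the point spread function (PSF) of its echo train, and tissue contrast
is the proton-density-corrected difference (`PD_wall = 0.72 × PD_fluid`).
An independent isochromat-ensemble Bloch simulator (1000 spins per
unit-phase distance) validates the EPG engine to < 1e-3 M0.

Simulated tissues at 7 T: vessel wall (T1/T2 = 1628/46 ms), CSF
(4019/311 ms, pulsating at 0.37 cm/s mean), arterial blood (2290/100 ms,
24 cm/s pulsatile inflow), free-water diffusion 3e-3 mm²/s for the fluids.

## Worked example

Simulate the default T2-weighted 7 T protocol (300 × 10° DANTE, 73
refocusing pulses, TE_equiv 165 ms, TR 2.62 s) for the three tissues in
their *basic* motion models (constant literature velocities, no spread or
pulsation):

```bash
dantespace simulate -c examples/basic_t2w_7t.toml -o out/
```

```
INFO dantespace: vw: PSF amplitude 0.0948 M0, FWHM 1.355 voxels
INFO dantespace: csf: PSF amplitude 0.0128 M0, FWHM 1.162 voxels
INFO dantespace: blood: PSF amplitude 0.0075 M0, FWHM 2.267 voxels
wrote out/summary.json
```

The wall retains 0.095 M0 while CSF and blood are suppressed to 0.013 and
0.008 M0 — the bright-wall / dark-lumen / dark-CSF contrast the sequence
exists for.  `summary.json` also reports the PD-weighted contrasts
(`vw − csf` = 0.055, `vw − blood` = 0.061 M0·PD) and per-repetition signal
levels; echo trains and PSF profiles are written as CSV.

The same protocol through the library, recovering a wall-pulsation
velocity from a relative signal level (the simulation side of the
signal-to-velocity mapping):

```python
import dantespace as ds

space, dante = ds.SpaceParams(), ds.DanteParams()
fa = ds.design_space_flip_angles(space, ds.VW)        # 73 angles, 31°-90°
ref = ds.run_protocol(ds.VW, ds.MotionModel.static(),
                      ds.DanteParams(n_pulses=0), space,
                      ds.ProtocolParams(), seed=1, flip_angles=fa)
prep = ds.run_protocol(ds.VW, ds.MotionModel.static(), dante, space,
                       ds.ProtocolParams(), seed=1, flip_angles=fa)
print(ref.psf_amplitude)                               # 0.133 M0
print(100 * prep.psf_amplitude / ref.psf_amplitude)    # 71.0 %
```

A static wall without preparation reads out 0.133 M0; adding DANTE leaves
71 % of that.  Sweeping the mean wall velocity
(`dantespace sweep`, or `run_protocol` with a `vw_like` waveform) gives a
strictly decreasing relative-signal curve that
`dantespace.velocity_from_relative_signal` inverts.

Other subcommands: `dantespace design-fa --t1 1628 --t2 46` prints the
variable flip-angle train for any tissue; `dantespace fixtures-make`
writes the synthetic waveform/trajectory CSVs.

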