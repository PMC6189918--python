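# depfield

Analytical dielectrophoretic (DEP) force fields of parallel planar
electrode arrays, with an independent finite-difference validation oracle.

## The problem

Microfluidic cell sorters steer cells across a channel with arrays of
strip electrodes on the channel walls.  Closing a feedback loop around
such a device — measure the cell position with a camera, pick the
electrode voltages that push it where it should go — requires evaluating
the force on a cell in well under a millisecond, which rules out solving
the electric field numerically at every control step.

`depfield` implements an analytical alternative for a rectangular channel
cross-section (width *L*, height *h*) with *N*⁺ electrodes on the top wall
and *N*⁻ on the bottom, each array laid out with electrode width equal to
the gap width, λ = L/(2N−1).  The electric potential is written as a
truncated Fourier series factored into three independent pieces,

```
φ(y, z, U) = te(y, z) · A · U
```

* **A** — a (2P+1) × N matrix of Fourier coefficients, a pure function of
  the electrode count.  Precomputed once per chip.
* **U** — the vector of electrode voltages: the control input.
* **te(y, z)** — harmonic basis terms cos(ωₚy)·Zₚ(z), with
  ωₚ = pπ/L and vertical profiles Zₚ that decay away from the array.
  Only this vector depends on the cell position.

Two facing arrays superpose: the top array's block is evaluated at
distance h/2 − z from the top wall, the bottom block at h/2 + z.  The DEP
force on a spherical particle of radius *r* then follows from the field
derivatives (all analytic, term by term):

```
F_DEP = 2π ε0 εm r³ Re(β) ∇(∇φ)²,     β = (εp* − εm*)/(εp* + 2εm*)
```

with Re(β) the real part of the Clausius–Mossotti factor (−0.5 ≤ Re β ≤ 1;
negative values push particles toward field minima, "negative DEP").

The analytical model rests on two boundary approximations — linear
potential across the inter-electrode gaps and mirror symmetry at the
lateral walls — so the package also ships an exact-boundary
finite-difference Laplace solver (`depfield.reference`) and a validation
suite (`depfield.validation`) that quantifies the model error against it:
pointwise force error maps, orientation-error benchmarks over random
voltage patterns, boundary-series convergence and the ‖F‖ ∝ h⁻³ height
power law.

## Worked example

With the bundled example configuration (150 × 80 µm channel, 8 electrodes
per wall, P = 2N = 16, a 4 µm bead with Re β = −0.5):

```sh
$ depfield force --config examples/chip.yaml --points "75,0;40,10;110,-20"
y_um,z_um,f_y_N,f_z_N,magnitude_N,angle_deg
75.0,0.0,-6.59868789859061e-28,4.2345920575860724e-14,4.2345920575860724e-14,90.0000000000009
40.0,10.0,-1.0777422186119677e-13,1.1625201464212075e-13,1.5852385879147125e-13,132.83279816430124
110.0,-20.0,-2.8720435478468607e-13,2.926545686877168e-12,2.940604699511079e-12,95.60492620696891
```

Forces are in newtons in the dual-array frame (y across the channel,
z = 0 at mid-height): tens to thousands of femtonewtons at ±1 V drive,
pointing away from the energized electrodes for this negative-DEP bead.
The same library call costs a few microseconds per point once the model is
built, against a fresh numerical field solve of order a second.

Scaling the whole cross-section up at fixed voltages weakens the force as
the inverse cube of the channel height:

```sh
$ depfield scan-height --config examples/chip.yaml --n-heights 5
log-log slope of mean |F| vs h: -3.0000
```

Other subcommands: `field-map` (gridded potential CSV), `validate` (error
maps and a JSON summary against the finite-difference reference),
`converge` (boundary-series convergence table), `simulate` (overdamped
particle trajectory under a voltage schedule).

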