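# Validation chip: 150 um wide, 80 um high, 8 electrodes per wall.
geometry: {width: 150 um, height: 80 um, n_top: 8, n_bottom: 8}
medium: {rel_permittivity: 78, wall_rel_permittivity: 4}
particle: {radius: 4 um, rel_permittivity: 2.5}
drive: {cm_real: -0.5}          # negative DEP
model: {p_harmonics: 16}        # P = 2N
voltages:
  top:    [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
  bottom: [0.5, 0.5, -0.5, -0.5, 0.5, 0.5, -0.5, -0.5]
seed: 1
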