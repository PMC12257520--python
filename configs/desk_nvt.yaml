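# Desk-scale profile: qualitative physics (orderings, band positions,
# hydrogen-bond statistics) in minutes on one core.
composition: H2O
ensemble: NVT
temperature: 300.0
molar_volume: 18.0
n_molecules: 32
n_beads: 8
dt: 2.5e-4
gamma0: 0.1
seed: 20240917
n_equil: 6000
n_prod: 6000
frame_stride: 10
velocity_stride: 4
bead_stride: 40
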