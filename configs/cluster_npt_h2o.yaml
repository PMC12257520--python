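# Study-scale constant-pressure profile (0.1 MPa).
composition: H2O
ensemble: NPT
temperature: 240.0
pressure: 0.1     # MPa
n_molecules: 512
n_beads: 32
dt: 2.5e-4
r_c: 1.0
eps_rf: 78.3
gamma0: 0.1
seed: 2024
n_equil: 4000000
n_prod: 40000000
frame_stride: 40
velocity_stride: 4
bead_stride: 400
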