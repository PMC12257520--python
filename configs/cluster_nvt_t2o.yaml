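# Study-scale constant-volume profile (per composition/temperature).
# Regenerates the headline observables when run on cluster hardware;
# a full temperature scan is a directory of these with T varied.
composition: T2O
ensemble: NVT
temperature: 240.0
molar_volume: 18.0
n_molecules: 512
n_beads: 32
dt: 2.5e-4        # ps (0.25 fs)
r_c: 1.0          # nm
eps_rf: 78.3
gamma0: 0.1       # ps^-1
seed: 2024
n_equil: 4000000  # 1 ns
n_prod: 40000000  # 10 ns
frame_stride: 40
velocity_stride: 4
bead_stride: 400
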