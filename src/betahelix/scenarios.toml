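# Named synthetic-data scenarios (versioned; bump on any parameter change).
version = 1

[cd_melt_paper]
generator = "melt"
seed = 101
[cd_melt_paper.params]
t_min = 20.0
t_max = 80.0
step = 1.0
t_m = 65.0
dh_vh = 400.0
a_f = -11000.0
b_f = 10.0
a_u = -3000.0
b_u = 5.0
noise_sd = 80.0

[ftir_melt_paper]
generator = "melt"
seed = 102
[ftir_melt_paper.params]
t_min = 25.0
t_max = 80.0
step = 5.0
t_m = 67.0
dh_vh = 400.0
a_f = 1.0
b_f = -0.001
a_u = 0.2
b_u = 0.0005
noise_sd = 0.002

[tht_paper]
generator = "titration"
seed = 103
[tht_paper.params]
c_min = 1.56
c_max = 100.0
fold = 2.0
breakpoint = 12.5
y0 = 50.0
slope_low = 1.0
slope_high = 40.0
noise_fraction = 0.02

[afm_pitch_paper]
generator = "profile"
seed = 104
[afm_pitch_paper.params]
length = 570.0
step = 0.5
period = 28.5
amplitude = 1.5
second_harmonic = 0.5
noise_sd = 0.2

[cd_isodichroic_paper]
generator = "spectra_family"
seed = 105
[cd_isodichroic_paper.params]
wl_min = 190.0
wl_max = 250.0
step = 1.0
crossing = 204.0
n_spectra = 7
tilt_slope = 0.6
noise_sd = 0.02
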