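# Annotated experiment configuration for `holorec run`.
# Every key is optional; omitted keys fall back to the documented defaults.

optics:
  wavelength: 514.5e-9      # argon-ion line [m]
  pixel_pitch: 0.55e-6      # EFFECTIVE pitch at the object plane [m]
                            # (sensor pitch / objective magnification)
  grid: 512                 # square grid size in pixels
  distance: 25.0e-6         # recording = reconstruction distance d0 [m]

# Exactly the first two classes are used: classes[0] is the reference,
# classes[1] the false input. A second, independently textured specimen of
# classes[0] serves as the true input.
classes:
  - class_label: filament        # curved ribbon (Oscillatoria-like)
    phase_dispersion: 0.3        # phase std inside the support [rad]
    mean_phase: 1.2              # mean optical phase delay [rad]
    shape_params:
      length: 100.0e-6
      width: 4.0e-6
      bend: 10.0e-6
      orientation_deg: 30.0
  - class_label: ellipse         # pore-patterned ellipse (diatom-like)
    phase_dispersion: 0.9
    mean_phase: 1.2
    shape_params:
      semi_major: 15.0e-6
      semi_minor: 7.5e-6
      pore_radius: 1.5e-6
      pore_spacing: 6.0e-6

n: 200                      # pixels per sampling segment
m: 100                      # trial segments per condition
alpha: 0.01                 # significance level of both tests
tests: [f, ks]              # parametric F and/or nonparametric ECDF test
sample_sizes: [50, 100, 150, 200]   # segment sizes for the ROC sweep
n_null_pairs: 999           # disjoint reference pairs forming the ECDF null
                            # (needs K >> 1/alpha for a well-calibrated
                            # add-one Monte-Carlo p-value)
channel_combiner: either_rejects    # how real/imag decisions combine
dc_suppression: subtract_mean       # zero-order handling at reconstruction
noise_sigma: 0.0            # additive Gaussian intensity noise (std)
reference_amplitude: 1.0    # plane reference wave amplitude A_r
seed: 1                     # master seed; all stages derive sub-seeds
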