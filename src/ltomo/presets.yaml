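# Named reconstruction presets: grid geometry, optics, calibration ratio C and
# FISTA parameters per scene.  gamma/tau are quoted on the BPM scale; the
# solver applies gamma/C and tau*C when the SSNP model is selected.
cylinders:
  size: [1024, 1, 256]
  dx: 0.15
  dz: 0.15
  wavelength: 0.6
  n0: 1.0
  ri: 1.05
  gamma: 1.0e-3
  C: 90.0
  iterations: 400
  tau_bpm: 0.16
  tau_ssnp: 0.04
  scheme: cylinders101
rbc:
  size: [512, 512, 180]
  dx: 0.15
  dz: 0.15
  wavelength: 0.6
  n0: 1.0
  ri: 1.05
  gamma: 1.0e-3
  C: 57.0
  iterations: 200
  tau_bpm: 0.2
  tau_ssnp: 0.025
  scheme: cone40_45deg
phantom:
  size: [350, 350, 128]
  dx: 0.15
  dz: 0.15
  wavelength: 0.6
  n0: 1.0
  ri:
    cytoplasm: 1.0248
    nucleus: 1.0210
    nucleolus: 1.0413
    lipids: 1.0886
  gamma: 1.0e-3
  C: 57.0
  iterations: 200
  tau_bpm: 0.1
  tau_ssnp: 0.025
  scheme: cone40_45deg
yeast:
  size: [150, 150, 80]
  dx: 0.1
  dz: 0.1
  wavelength: 0.532
  n0: 1.338
  gamma: 0.25e-3
  C: 163.0
  iterations: 200
  tau_bpm: 0.025
  tau_ssnp: 0.00625
  scheme: circle360_35deg
hct116:
  size: [256, 256, 170]
  dx: 0.1
  dz: 0.1
  wavelength: 0.532
  n0: 1.338
  gamma: 0.25e-3
  C: 160.0
  iterations: 200
  tau_bpm: 0.025
  tau_ssnp: 0.025
  scheme: circle360_35deg
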