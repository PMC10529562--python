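# Per-class beat morphology templates: five Gaussian bumps per beat
# modeling the P, Q, R, S and T waves. amp in mV, center in seconds
# relative to the R peak, width (Gaussian sigma) in seconds.
# Templates are synthetic and deliberately distinct per class (widened
# or inverted R for ventricular/escape-like classes, absent or early P
# for atrial classes); no claim of clinical fidelity. Editable.
default_jitter: {amp: 0.05, width: 0.05, time: 0.004}
classes:
  0:  # NB: textbook sinus beat
    P: {amp: 0.15, center: -0.200, width: 0.025}
    Q: {amp: -0.12, center: -0.045, width: 0.010}
    R: {amp: 1.20, center: 0.0, width: 0.012}
    S: {amp: -0.25, center: 0.040, width: 0.012}
    T: {amp: 0.35, center: 0.250, width: 0.055}
  1:  # FPNB: fusion of paced and normal - broadened, damped R
    P: {amp: 0.08, center: -0.190, width: 0.030}
    Q: {amp: -0.06, center: -0.050, width: 0.012}
    R: {amp: 0.90, center: 0.0, width: 0.020}
    S: {amp: -0.30, center: 0.050, width: 0.018}
    T: {amp: 0.25, center: 0.260, width: 0.065}
  2:  # AEB: inverted P, otherwise near-normal QRS
    P: {amp: -0.12, center: -0.160, width: 0.025}
    Q: {amp: -0.10, center: -0.045, width: 0.010}
    R: {amp: 1.00, center: 0.0, width: 0.013}
    S: {amp: -0.22, center: 0.040, width: 0.012}
    T: {amp: 0.30, center: 0.245, width: 0.055}
  3:  # PB: no P, wide QRS, discordant T
    P: {amp: 0.0, center: -0.200, width: 0.025}
    Q: {amp: -0.05, center: -0.060, width: 0.015}
    R: {amp: 1.10, center: 0.0, width: 0.028}
    S: {amp: -0.40, center: 0.070, width: 0.020}
    T: {amp: -0.25, center: 0.270, width: 0.060}
  4:  # NEB: junctional escape - absent P
    P: {amp: 0.0, center: -0.200, width: 0.025}
    Q: {amp: -0.10, center: -0.045, width: 0.010}
    R: {amp: 1.05, center: 0.0, width: 0.013}
    S: {amp: -0.24, center: 0.040, width: 0.012}
    T: {amp: 0.32, center: 0.250, width: 0.055}
  5:  # SEB: absent P, slightly damped narrow QRS, late T
    P: {amp: 0.0, center: -0.200, width: 0.025}
    Q: {amp: -0.08, center: -0.040, width: 0.010}
    R: {amp: 0.95, center: 0.0, width: 0.012}
    S: {amp: -0.20, center: 0.038, width: 0.011}
    T: {amp: 0.28, center: 0.280, width: 0.060}
  6:  # LBBB: wide notched-looking R, no Q, inverted T
    P: {amp: 0.14, center: -0.210, width: 0.025}
    Q: {amp: 0.0, center: -0.045, width: 0.010}
    R: {amp: 1.00, center: 0.0, width: 0.035}
    S: {amp: -0.15, center: 0.085, width: 0.030}
    T: {amp: -0.30, center: 0.280, width: 0.065}
  7:  # RBBB: narrow R with positive late deflection (rSR'-like), inverted T
    P: {amp: 0.14, center: -0.200, width: 0.025}
    Q: {amp: -0.10, center: -0.050, width: 0.010}
    R: {amp: 0.90, center: 0.0, width: 0.014}
    S: {amp: 0.45, center: 0.055, width: 0.013}
    T: {amp: -0.25, center: 0.255, width: 0.055}
  8:  # SP: early low P hugging the QRS
    P: {amp: 0.10, center: -0.140, width: 0.018}
    Q: {amp: -0.11, center: -0.045, width: 0.010}
    R: {amp: 1.10, center: 0.0, width: 0.012}
    S: {amp: -0.24, center: 0.040, width: 0.012}
    T: {amp: 0.30, center: 0.250, width: 0.055}
  9:  # APB: prominent early P
    P: {amp: 0.22, center: -0.170, width: 0.020}
    Q: {amp: -0.12, center: -0.045, width: 0.010}
    R: {amp: 1.15, center: 0.0, width: 0.012}
    S: {amp: -0.26, center: 0.040, width: 0.012}
    T: {amp: 0.33, center: 0.250, width: 0.055}
  10: # NPB: retrograde (inverted, late) P close to QRS
    P: {amp: -0.08, center: -0.100, width: 0.018}
    Q: {amp: -0.10, center: -0.045, width: 0.010}
    R: {amp: 1.10, center: 0.0, width: 0.012}
    S: {amp: -0.24, center: 0.040, width: 0.012}
    T: {amp: 0.30, center: 0.250, width: 0.055}
  11: # AAPB: early P with aberrant (taller, deeper-S) QRS
    P: {amp: 0.12, center: -0.180, width: 0.020}
    Q: {amp: -0.10, center: -0.048, width: 0.011}
    R: {amp: 1.30, center: 0.0, width: 0.016}
    S: {amp: -0.35, center: 0.045, width: 0.015}
    T: {amp: 0.20, center: 0.255, width: 0.055}
  12: # PVC: no P, very wide tall R, deep S, discordant T
    P: {amp: 0.0, center: -0.200, width: 0.025}
    Q: {amp: 0.0, center: -0.045, width: 0.010}
    R: {amp: 1.40, center: 0.0, width: 0.040}
    S: {amp: -0.50, center: 0.090, width: 0.025}
    T: {amp: -0.45, center: 0.290, width: 0.070}
  13: # VEB: inverted wide dominant R, upright T
    P: {amp: 0.0, center: -0.200, width: 0.025}
    Q: {amp: 0.0, center: -0.045, width: 0.010}
    R: {amp: -1.20, center: 0.0, width: 0.035}
    S: {amp: 0.30, center: 0.090, width: 0.020}
    T: {amp: 0.40, center: 0.285, width: 0.065}
  14: # FVNB: intermediate width/amplitude fusion morphology
    P: {amp: 0.08, center: -0.195, width: 0.025}
    Q: {amp: -0.06, center: -0.048, width: 0.011}
    R: {amp: 1.10, center: 0.0, width: 0.026}
    S: {amp: -0.35, center: 0.065, width: 0.018}
    T: {amp: 0.10, center: 0.265, width: 0.060}
  15: # UB: low-voltage smeared beat
    P: {amp: 0.05, center: -0.190, width: 0.030}
    Q: {amp: -0.05, center: -0.050, width: 0.014}
    R: {amp: 0.70, center: 0.0, width: 0.022}
    S: {amp: -0.10, center: 0.055, width: 0.020}
    T: {amp: 0.15, center: 0.260, width: 0.090}
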