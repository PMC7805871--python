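# Default controller configuration: published/tuned constants of the two
# virtual muscles, the ankle attachment geometry, and the per-stage
# square-wave activation presets for the two subject profiles.
sample_rate_hz: 500.0

muscle:
  anterior:
    P0: 1799.0        # peak isometric force, N
    kts: 159.0        # titin spring constant, N/cm
    kss: 1499.0       # series spring constant, N/cm
    Cce_l: 97.0       # CE damping, lengthening, N*s/cm
    Cce_s: 182.0      # CE damping, shortening, N*s/cm
    L0: null          # optimal length, cm; null = length at neutral ankle angle
    fl_width: 0.5     # force-length parabola half-width, fraction of L0
  posterior:
    P0: 1654.0
    kts: 205.0
    kss: 1559.0
    Cce_l: 102.0
    Cce_s: 57.0
    L0: null
    fl_width: 0.5

geometry:
  SAL_A: 29.0         # anterior shank attachment length, cm
  SAL_P: 33.0         # posterior shank attachment length, cm
  FMA_A: 4.0          # anterior foot moment arm, cm
  FMA_P: 5.5          # posterior foot moment arm, cm
  gamma0_A: 90.0      # included shank-foot angle at neutral, deg
  gamma0_P: 90.0
  constant_moment_arm: false

schedule:
  profile1:
    act_A: {2: 0.93, 3: 0.28, 4: 0.31, 5: 0.0, 6: 0.0}
    act_P: {2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.44}
  profile2:
    act_A: {2: 0.63, 3: 0.48, 4: 0.51, 5: 0.0, 6: 0.0}
    act_P: {2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.69}
  smoothing_s: 0.0    # linear activation ramp at stage changes, s (0 = square wave)

controller:
  profile: profile1
  resistance_gain: 0.0   # viscous compensation, N*m*s/deg
  mass_kg: 82.0
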