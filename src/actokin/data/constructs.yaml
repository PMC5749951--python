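# Published steady-state and transient-state kinetic constants for the human
# nonmuscle myosin-2C motor domain (NM2C) and its converter-hub mutants R788K
# and R788E.  Units: second-order constants in 1/(uM*s), first-order in 1/s,
# concentrations in uM.  Where several stopped-flow signals measured the same
# constant, every measurement is listed under `measurements` with its signal
# source; `precedence` records which source a derived ratio should use
# (chasing experiments isolate release rates and are preferred for
# like-vs-like rate ratios, the y-intercept of the mantADP concentration
# series for equilibrium constants).
#
# Signal keys: tryptophan (intrinsic W525 fluorescence), mant (d-mantATP or
# d-mantADP FRET), pyrene (pyrene-actin quench), light_scattering, nadh
# (NADH-coupled steady-state ATPase).  Qualifier keys: intercept (from the
# y-intercept of a k_obs series), chase (from a chasing/displacement
# experiment).

defaults:
  # Values the experiments do not resolve; configurable per construct.
  hydrolysis_equilibrium: 10.0   # K3 = k+3/k-3, favours M.ADP.Pi
  k_pi_basal: 0.02               # basal phosphate release, 1/s
  collision_on_acto_atp: 100.0   # diffusion-limited collision step, 1/(uM*s)
  collision_on_actin_weak: 10.0  # weak actin binding of M.ADP.Pi, 1/(uM*s)
  dead_time: 0.0015              # stopped-flow mixing dead time, s

constructs:
  NM2C:
    kcat: 0.37
    Kapp: 129.4
    k1k2_myosin:
      mant: 0.48
      tryptophan: 0.39
    inv_K05: 46.23
    k3_plus_kminus3: 24.2
    k1k2_acto:
      pyrene: 1.86
      mant: 1.64
    k2_acto: 643.06
    inv_K1_acto: 318.0
    kD_on: 0.39
    kD_off:
      intercept: 0.94
      chase_mant: 0.39
      chase_tryptophan: 0.47
    kAD_on: 2.54
    kAD_off:
      mant: 0.65
      chase_light_scattering: 0.39
      chase_mant: 0.68
      chase_pyrene: 0.48
    kA_on: 2.49
    kA_off: 0.15
    kDA_on: 0.53
    kDA_off: 0.004
  R788K:
    kcat: 0.26
    Kapp: 110.5
    k1k2_myosin:
      mant: 0.22
      tryptophan: 0.18
    inv_K05: 158.03
    k3_plus_kminus3: 37.31
    k1k2_acto:
      pyrene: 1.03
      mant: 0.73
    k2_acto: 767.43
    inv_K1_acto: 826.0
    kD_on: 0.21
    kD_off:
      intercept: 0.58
      chase_mant: 0.51
      chase_tryptophan: 0.24
    kAD_on: null          # small amplitudes preclude direct measurement
    kAD_off:
      chase_light_scattering: 0.42
      chase_mant: 0.59
      chase_pyrene: 0.46
    kA_on: 1.65
    kA_off: 0.055         # printed band ~0.04-0.07; midpoint
    kDA_on: 2.53
    kDA_off: 0.0885       # printed band ~0.067-0.11; midpoint
  R788E:
    kcat: 0.2
    Kapp: 45.9
    k1k2_myosin:
      mant: 0.09
      tryptophan: null    # no nucleotide-induced tryptophan signal
    inv_K05: null
    k3_plus_kminus3: null
    k1k2_acto:
      pyrene: 2.11
      mant: 1.37
    k2_acto: 579.27
    inv_K1_acto: 380.0
    kD_on: 0.12
    kD_off:
      intercept: 0.06
      chase_mant: 0.05
    kAD_on: 0.03
    kAD_off:
      mant: 0.09
      chase_light_scattering: 0.15
      chase_mant: 0.19
      chase_pyrene: 0.14
    kA_on: 0.66
    kA_off: 0.031
    kDA_on: 0.21
    kDA_off: 0.002

# Which measurement of a multiply-measured constant feeds each derived
# quantity.  Kinetic coupling divides two release rates, so chase-derived
# values are used for the numerator throughout and for the denominator where
# a chase measurement exists alongside the intercept (the intercept k-D is
# retained for NM2C, whose coupling was reported against it).
precedence:
  simulate:
    k1k2_myosin: mant
    kD_off: intercept
    kAD_off: chase_mant
    k1k2_acto: pyrene
  kinetic_coupling:
    NM2C:  {kAD_off: chase_mant, kD_off: intercept}
    R788K: {kAD_off: chase_mant, kD_off: chase_mant}
    R788E: {kAD_off: chase_mant, kD_off: chase_mant}
  thermo_coupling:
    kAD_off: mant
    kD_off: intercept
  duty_ratio:
    kAD_off: chase_mant
  nucleotide_selectivity:
    # like-vs-like: k+AD is a mant measurement, so divide by the mant K1k+2
    k1k2_acto: mant
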