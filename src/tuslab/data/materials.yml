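# Acoustic and thermal material properties per tissue label.
#
# These are literature-typical values at a 500 kHz carrier, shipped as
# editable substitutes for a study-specific property table; edit freely.
# absorption is in Np/m AT the carrier frequency (no dispersion model).
# perfusion_rate is the Pennes blood-perfusion rate w in 1/s.
water:
  sound_speed: 1482.0        # m/s
  density: 1000.0            # kg/m^3
  absorption: 0.025          # Np/m
  thermal_conductivity: 0.6  # W/(m K)
  specific_heat: 4180.0      # J/(kg K)
  perfusion_rate: 0.0        # 1/s
soft_tissue_csf:
  sound_speed: 1540.0
  density: 1040.0
  absorption: 3.5
  thermal_conductivity: 0.5
  specific_heat: 3600.0
  perfusion_rate: 0.002
bone:
  sound_speed: 2800.0
  density: 1900.0
  absorption: 80.0
  thermal_conductivity: 0.32
  specific_heat: 1300.0
  perfusion_rate: 0.0005
brain:
  sound_speed: 1546.0
  density: 1046.0
  absorption: 4.0
  thermal_conductivity: 0.51
  specific_heat: 3630.0
  perfusion_rate: 0.008
electrode:
  sound_speed: 3260.0
  density: 20000.0
  absorption: 20.0
  thermal_conductivity: 20.0
  specific_heat: 500.0
  perfusion_rate: 0.0
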