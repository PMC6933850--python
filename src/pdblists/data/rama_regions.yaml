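# Favored phi/psi regions as axis-aligned rectangles [phi_min, phi_max, psi_min, psi_max]
# in degrees. Coarse masks: alpha and beta basins plus the left-handed alpha
# basin; glycine adds the mirror-image basins; proline is restricted around
# phi ~ -65. A residue is "favored" when (phi, psi) falls in any rectangle of
# its class.
general:
  - [-160.0, -20.0, -120.0, 50.0]    # alpha basin
  - [-180.0, -45.0, 60.0, 180.0]     # beta / polyproline basin
  - [-180.0, -45.0, -180.0, -170.0]  # beta basin wrapped across psi = 180
  - [30.0, 90.0, -20.0, 80.0]        # left-handed alpha
glycine:
  - [-180.0, -20.0, -120.0, 50.0]
  - [-180.0, -45.0, 60.0, 180.0]
  - [-180.0, -45.0, -180.0, -170.0]
  - [20.0, 180.0, -50.0, 120.0]
  - [45.0, 180.0, -180.0, -60.0]
  - [45.0, 180.0, 120.0, 180.0]
proline:
  - [-110.0, -40.0, 100.0, 180.0]
  - [-110.0, -40.0, -70.0, 10.0]
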