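# Vendor calibration printout for the 1920x1080 acquisition system, shipped
# verbatim as published.  The intrinsic/distortion rows were printed in a
# collapsed layout whose column boundaries are ambiguous, so they are kept
# as raw strings and are NOT interpreted by any computation; use a proper
# CameraModel YAML (see reconstruction.CameraModel) for actual processing.
camera_internal_parameters_raw: "4891.001333.504109.9613.5001"
radial_distortion_factor_raw: "-222.8795212.6786268.8869"
tangential_distortion_factor_raw: "-0.3769-0.6711"
rotating_vector_raw: "-0.0521-1.58550.0929"
translating_vector_raw: "-1.08522.5743159.7867"
frame_rate: 30.0
conveyor_speed: 20.0
image_width: 1920
image_height: 1080
laser_wavelength_nm: 520
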