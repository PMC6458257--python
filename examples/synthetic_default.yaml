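# Default synthetic-city run: 200 zones, MSU base at the central ECR hub,
# second hub 20 km out, six thrombolysis-only hospitals.
seed: 7
output_dir: out
city:
  synthetic:
    n_zones: 200
    city_radius_km: 40.0
    base_offset_km: 2.0
    second_hub_offset_km: 20.0
    n_tpa_only_sites: 6
    circuity_factor: 1.3
    speed_center_kmh: 25.0
    speed_edge_kmh: 60.0
    speed_scale_km: 20.0
    noise_sigma: 0.1
    seed: 7
    center_lat: -37.81
    center_lon: 144.96
msu:
  scene_min: 30.0
  cta_min: 10.0
  ctp_min: 0.0
  tele_min: 0.0
  hub_proc_min: 30.0
usual:
  dispatch_min: 15.0
  scene_min: 20.0
  door_to_needle_min: 60.0
  door_to_groin_min: 90.0
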