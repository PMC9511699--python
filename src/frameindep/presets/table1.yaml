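# Liver-disease-scale phantom preset: group mean echo intensities and
# within-ROI speckle spreads on the scale reported for rat liver B-mode
# texture (normal / steatosis / fibrosis), with the unbalanced case counts
# of that cohort and a 35-frame (4.5 s) respiratory modulation.
groups:
  normal:    {mu: 25.4, sigma_within: 13.2, sigma_structure: 6.0, sigma_between: 0.5}
  steatosis: {mu: 34.7, sigma_within: 12.0, sigma_structure: 7.0, sigma_between: 0.5}
  fibrosis:  {mu: 55.9, sigma_within: 16.3, sigma_structure: 10.0, sigma_between: 0.5}
cases_per_group:
  normal: 4
  steatosis: 4
  fibrosis: 6
frames_per_case: 30
frame_size: [96, 96]
rois_per_frame: 5
roi_size: [24, 24]
rho: 0.9
breath_period_frames: 35
breath_amplitude: 4.0
amp_growth: 1.15
drift_per_frame: 0.02
gamma_shape: 4.0
frame_rate_hz: 7.7777777778
seed: 0
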