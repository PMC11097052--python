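# Default and wrist-optimized parameter banks for the registered detectors.
# Thresholds are in g; durations in seconds.

paraschiv2019:
  default:
    th: 0.1           # lower-back variant B; variant C uses 0.15
  gsdc:
    th: 0.15
  optimized:
    th: 0.35          # wrist

paraschiv2020:
  # data-adaptive threshold: no tuned parameters, default == optimized
  default:
    n_smooth_iters: 2
    adapt_quantile: 0.1
    adapt_floor_g: 0.12
  optimized:
    n_smooth_iters: 2
    adapt_quantile: 0.1
    adapt_floor_g: 0.12

iluz:
  default:
    activity_thres: 0.01
    min_bout_length: 5
    template_len: 0.5
    cm_norm_thres: 0.4
  optimized:
    activity_thres: 0.04
    min_bout_length: 10
    template_len: 1
    cm_norm_thres: 2.5

gu:
  default:
    verisense_k: 3
    sim_thres: -0.5
    cont_thres: 4
    mag_thres: 1.2
  optimized:
    verisense_k: 2
    sim_thres: -0.8
    cont_thres: 4
    mag_thres: 1.2

karas:
  default:
    sim_MIN: 0.85
    dur_MIN: 0.8
    dur_MAX: 1.4
    ptp_r_MIN: 0.2
    ptp_r_MAX: 2.0
    mean_abs_diff_med_p_MAX: 0.5
    mean_abs_diff_med_t_MAX: 0.2
    mean_abs_diff_dur_MAX: 0.2
  optimized:
    sim_MIN: 0.3
    dur_MIN: 0.2
    dur_MAX: 3.0
    ptp_r_MIN: 0.2
    ptp_r_MAX: 3.0
    mean_abs_diff_med_p_MAX: 0.5
    mean_abs_diff_med_t_MAX: 0.5
    mean_abs_diff_dur_MAX: 0.5

hickey:
  default:
    ThresholdStill: 0.2
    ThresholdUpright: -0.5
  optimized:
    ThresholdStill: 0.2
    ThresholdUpright: -0.5

kheirkhahan:
  default:
    walking_threshold: 0.75
  optimized:
    walking_threshold: 0.6
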