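measure,mean,sd
grooming_given_min_h,9.2,8.4
grooming_received_min_h,5.9,3.5
pct_time_grooming,19.5,11.1
groom_bout_duration_min,6.6,5.6
approach_rate_per_h,8.8,8.1
attack_rate_per_h,0.55,0.87
aggressive_signal_rate_per_h,1.46,1.96
movement_bout_distance_m,6.5,3.5
pct_time_scanning,4.4,2.3
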